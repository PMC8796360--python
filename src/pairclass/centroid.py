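"""Nearest-centroid subtype classifiers on raw or row-centered expression.

Two variants share one gene-selection procedure:

* **raw mode** ("single-sample centroid"): class centroids are mean raw
  log-scale expression values.  A new sample is compared to the centroids by
  Pearson correlation of its own raw values, so the prediction depends only
  on the sample itself (invariant to per-sample affine rescaling).
* **centered mode** (conventional nearest centroid): centroids are computed
  from per-gene mean-centered training data; the stored training row means
  are subtracted from new samples before correlating, so each sample is
  still predicted independently of the batch it arrives with.

Gene selection per class: a moderated t-test (empirical-Bayes variance
shrinkage across genes) at p < 0.05 combined with a class-vs-rest AUC gate,
then ranking the survivors by mean log fold change and taking the top m
up- and top m down-regulated genes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats

from .core_data import LabeledCohort, ExpressionMatrix
from .pair_rules import rule_auc
from .results import PredictionResult


# ---------------------------------------------------------------------------
# Moderated t-test (empirical-Bayes variance shrinkage)
# ---------------------------------------------------------------------------

def _trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y for x > 0 (Newton iteration)."""
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    if y < 1e-6:
        return 1.0 / y
    x = 0.5 + 1.0 / y
    for _ in range(50):
        tri = special.polygamma(1, x)
        dif = tri * (1.0 - tri / y) / special.polygamma(2, x)
        x += dif
        if abs(dif) < 1e-10 * x:
            break
    return float(x)


def squeeze_variances(s2: np.ndarray, df: float) -> tuple[np.ndarray, float, float]:
    """Shrink per-gene variances toward a pooled prior.

    Fits a scaled F distribution to the observed gene-wise sample variances
    ``s2`` (residual degrees of freedom ``df``) by matching moments of
    ``log(s2)``, yielding a prior variance ``s0^2`` with prior degrees of
    freedom ``d0``; returns the posterior variances
    ``(d0 s0^2 + df s2) / (d0 + df)`` together with ``d0`` and ``s0^2``.
    """
    s2 = np.asarray(s2, dtype=float)
    floor = 1e-10 * np.median(s2[s2 > 0]) if np.any(s2 > 0) else 1e-10
    s2_safe = np.maximum(s2, floor)
    z = np.log(s2_safe)
    e = z - special.digamma(df / 2.0) + np.log(df / 2.0)
    emean = e.mean()
    evar = e.var(ddof=1) - special.polygamma(1, df / 2.0)
    if evar > 0:
        d0 = 2.0 * _trigamma_inverse(evar)
        s0_sq = np.exp(emean + special.digamma(d0 / 2.0) - np.log(d0 / 2.0))
        post = (d0 * s0_sq + df * s2_safe) / (d0 + df)
    else:
        # no excess dispersion beyond sampling noise: completely pool variances
        d0 = np.inf
        s0_sq = float(s2_safe.mean())
        post = np.full_like(s2_safe, s0_sq)
    return post, d0, s0_sq


def moderated_ttest(values: np.ndarray, positive: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Two-group moderated t-test per gene (rows of ``values``).

    Uses the pooled two-sample variance per gene, shrinks variances across
    genes with :func:`squeeze_variances`, and tests on ``df + d0`` degrees
    of freedom.  Returns (t statistics, two-sided p-values).
    """
    values = np.asarray(values, dtype=float)
    positive = np.asarray(positive, dtype=bool)
    n1, n0 = int(positive.sum()), int((~positive).sum())
    if n1 < 2 or n0 < 2:
        raise ValueError("moderated t-test needs >= 2 samples per group")
    x1, x0 = values[:, positive], values[:, ~positive]
    m1, m0 = x1.mean(axis=1), x0.mean(axis=1)
    df = n1 + n0 - 2
    s2 = (x1.var(axis=1, ddof=1) * (n1 - 1) + x0.var(axis=1, ddof=1) * (n0 - 1)) / df
    s2_post, d0, _ = squeeze_variances(s2, df)
    se = np.sqrt(s2_post * (1.0 / n1 + 1.0 / n0))
    t = (m1 - m0) / se
    # total df capped at the summed residual df across genes
    df_total = min(df + d0, df * values.shape[0])
    p = 2.0 * stats.t.sf(np.abs(t), df_total)
    return t, p


def welch_ttest(values: np.ndarray, positive: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Plain Welch t-test per gene (no variance shrinkage)."""
    positive = np.asarray(positive, dtype=bool)
    t, p = stats.ttest_ind(values[:, positive], values[:, ~positive], axis=1, equal_var=False)
    return t, p


# ---------------------------------------------------------------------------
# Gene selection and model construction
# ---------------------------------------------------------------------------

@dataclass
class CentroidModel:
    """Trained nearest-centroid classifier (raw or centered mode)."""

    mode: str  # "raw" | "centered"
    m: int
    gene_lists: dict  # class -> {"up": [...], "down": [...]}
    union_genes: list
    centroids: pd.DataFrame  # union genes × classes
    row_means: pd.Series | None = None  # centered mode only

    @property
    def classes(self) -> list:
        return self.centroids.columns.tolist()


def select_centroid_genes(
    cohort: LabeledCohort,
    m: int,
    *,
    p_threshold: float = 0.05,
    auc_threshold: float = 0.6,
    test: str = "moderated",
) -> tuple[dict, dict]:
    """Per-class differential genes for centroid construction.

    For each class (one-vs-rest): keep genes with moderated-t p below
    ``p_threshold`` and folded AUC strictly above ``auc_threshold`` (the AUC
    gate admits discrimination in either direction, so downregulated marker
    genes qualify symmetrically), rank survivors by mean log fold change and
    take the top ``m`` up- and ``m`` down-regulated.

    Returns ``(stats, gene_lists)`` where ``stats[cls]`` is a per-gene
    DataFrame (p_value, auc, fold_change) and ``gene_lists[cls]`` holds the
    selected up/down gene lists.
    """
    if m < 1:
        raise ValueError("m must be >= 1")
    values = cohort.expression.values.to_numpy()
    genes = cohort.expression.values.index
    labels = cohort.labels.to_numpy()
    test_fn = {"moderated": moderated_ttest, "welch": welch_ttest}[test]
    stats_out: dict = {}
    gene_lists: dict = {}
    for cls in cohort.classes:
        pos = labels == cls
        _, p = test_fn(values, pos)
        auc = rule_auc(values, pos)
        auc = np.maximum(auc, 1.0 - auc)
        fc = values[:, pos].mean(axis=1) - values[:, ~pos].mean(axis=1)
        df = pd.DataFrame({"p_value": p, "auc": auc, "fold_change": fc}, index=genes)
        stats_out[cls] = df
        keep = df[(df["p_value"] < p_threshold) & (df["auc"] > auc_threshold)]
        up = keep[keep["fold_change"] > 0].sort_values("fold_change", ascending=False)
        down = keep[keep["fold_change"] < 0].sort_values("fold_change", ascending=True)
        if len(up) < m or len(down) < m:
            warnings.warn(
                f"class {cls}: only {len(up)} up / {len(down)} down genes pass the "
                f"selection gates (m={m} requested)",
                stacklevel=2,
            )
        gene_lists[cls] = {"up": up.index[:m].tolist(), "down": down.index[:m].tolist()}
    return stats_out, gene_lists


def build_centroids(cohort: LabeledCohort, gene_lists: dict, mode: str = "raw", m: int | None = None) -> CentroidModel:
    """Class-mean centroids over the union of all selected genes.

    Raw mode averages the raw values; centered mode first subtracts each
    gene's mean across the training samples (the training row means are
    stored so new samples can be centered identically).  Raw and centered
    centroids therefore differ by exactly the per-gene training means.
    """
    if mode not in ("raw", "centered"):
        raise ValueError("mode must be 'raw' or 'centered'")
    union: list = []
    seen = set()
    for cls in sorted(gene_lists):
        for direction in ("up", "down"):
            for g in gene_lists[cls][direction]:
                if g not in seen:
                    seen.add(g)
                    union.append(g)
    values = cohort.expression.values.loc[union]
    row_means = values.mean(axis=1)
    work = values.sub(row_means, axis=0) if mode == "centered" else values
    centroids = pd.DataFrame(
        {cls: work.loc[:, (cohort.labels == cls).to_numpy()].mean(axis=1) for cls in cohort.classes}
    )
    inferred_m = max(
        (len(gene_lists[c][d]) for c in gene_lists for d in ("up", "down")), default=0
    )
    return CentroidModel(
        mode=mode,
        m=m if m is not None else inferred_m,
        gene_lists=gene_lists,
        union_genes=union,
        centroids=centroids,
        row_means=row_means if mode == "centered" else None,
    )


def train_centroid(cohort: LabeledCohort, m: int = 10, mode: str = "raw", **kwargs) -> CentroidModel:
    """Gene selection + centroid construction in one call."""
    _, gene_lists = select_centroid_genes(cohort, m, **kwargs)
    return build_centroids(cohort, gene_lists, mode, m=m)


def predict_nearest_centroid(
    x: ExpressionMatrix, model: CentroidModel, *, max_missing_fraction: float = 0.2
) -> PredictionResult:
    """Pearson-correlation nearest-centroid prediction, one sample at a time.

    Missing centroid genes are dropped from both the sample and the
    centroids (with a warning) up to ``max_missing_fraction``; each class
    score is the Pearson r between the (optionally centered) sample vector
    and the class centroid.
    """
    present = [g for g in model.union_genes if g in x.values.index]
    n_missing = len(model.union_genes) - len(present)
    if n_missing:
        frac = n_missing / len(model.union_genes)
        if frac > max_missing_fraction:
            raise ValueError(
                f"{n_missing}/{len(model.union_genes)} centroid genes missing "
                f"({frac:.0%} > {max_missing_fraction:.0%} allowed)"
            )
        warnings.warn(f"dropping {n_missing} centroid genes absent from the input", stacklevel=2)
    sample_vals = x.values.loc[present].to_numpy(dtype=float)
    if model.mode == "centered":
        sample_vals = sample_vals - model.row_means.loc[present].to_numpy()[:, None]
    cent = model.centroids.loc[present].to_numpy(dtype=float)

    sv = sample_vals - sample_vals.mean(axis=0, keepdims=True)
    cv = cent - cent.mean(axis=0, keepdims=True)
    s_norm = np.linalg.norm(sv, axis=0)
    zero_var = s_norm == 0
    if zero_var.any():
        bad = np.asarray(x.sample_ids)[zero_var].tolist()
        raise ValueError(f"zero variance over centroid genes for sample(s) {bad}: correlation undefined")
    c_norm = np.linalg.norm(cv, axis=0)
    r = (sv.T @ cv) / np.outer(s_norm, c_norm)
    scores = pd.DataFrame(r, index=x.sample_ids, columns=model.centroids.columns)
    return PredictionResult.from_scores(scores)


def centroid_size_sweep(
    cohort: LabeledCohort, m_values, mode: str = "raw", **kwargs
) -> tuple[pd.DataFrame, list[CentroidModel]]:
    """Train one centroid model per size m and profile it on the training data.

    Returns a table of (m, union size, training accuracy, mean margin) plus
    the models themselves.  Gene statistics are computed once and reused
    across the sweep.
    """
    m_values = sorted(m_values)
    stats_out, full_lists = select_centroid_genes(cohort, max(m_values), **kwargs)
    rows = []
    models = []
    labels = cohort.labels
    for m in m_values:
        lists_m = {
            cls: {d: full_lists[cls][d][:m] for d in ("up", "down")} for cls in full_lists
        }
        model = build_centroids(cohort, lists_m, mode, m=m)
        pred = predict_nearest_centroid(cohort.expression, model)
        acc = float((pred.predicted == labels).mean())
        rows.append(
            {
                "m": m,
                "union_size": len(model.union_genes),
                "training_accuracy": acc,
                "mean_margin": float(pred.margin.mean()),
            }
        )
        models.append(model)
    return pd.DataFrame(rows), models
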