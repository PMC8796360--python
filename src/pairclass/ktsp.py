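"""Multiclass k-Top-Scoring-Pairs classifier built from one-vs-rest voters.

For every class a binary k-TSP classifier is trained: Wilcoxon-type gene
selection (top n up- and downregulated genes versus the rest), exhaustive
scoring of candidate gene pairs by the TSP delta (frequency difference of
the rule being TRUE between class and rest) with the rank-difference gamma
as tie-break, greedy selection of gene-disjoint top pairs, and choice of the
number of rules k by variance optimization — maximizing the standardized
separation of the per-sample vote sums between class and rest — unless a
fixed k is requested.  At prediction time each classifier emits the
fraction of its rules that are TRUE; the class with the highest fraction
wins, with exact ties flagged.

Optional modifications: pivot genes (pairing selected genes with all other
training genes), one-vs-one gene selection and rule scoring (worst-case
aggregation across opposing classes), and platform-wise selection/scoring
(intersecting top gene sets and taking the minimum delta across platforms).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .core_data import ExpressionMatrix, LabeledCohort, rank_transform
from .pair_rules import GenePairRule, binarize, rule_auc, tsp_scores
from .results import PredictionResult


@dataclass(frozen=True)
class KTSPConfig:
    n_genes_per_direction: int = 50
    k_range: tuple[int, int] = (2, 10)
    fixed_k: int | None = None
    pivot_genes: bool = False
    gene_selection_mode: str = "one_vs_rest"  # or "one_vs_one"
    rule_scoring_mode: str = "one_vs_rest"  # or "one_vs_one"
    platform_wise: bool = False

    def __post_init__(self) -> None:
        if self.k_range[0] < 1 or self.k_range[1] < self.k_range[0]:
            raise ValueError("invalid k_range")
        if self.fixed_k is not None and self.fixed_k < 1:
            raise ValueError("fixed_k must be >= 1")


@dataclass
class BinaryKTSP:
    """One class's voter: an ordered, gene-disjoint rule list of length k."""

    target_class: str
    rules: list[GenePairRule]
    k: int
    gene_pool: dict  # {"up": [...], "down": [...]}
    k_criterion: pd.Series | None = None  # variance-optimization curve over k


@dataclass
class KTSPModel:
    classifiers: dict  # class -> BinaryKTSP
    config: KTSPConfig

    @property
    def classes(self) -> list:
        return sorted(self.classifiers)

    def rules_frame(self) -> pd.DataFrame:
        rows = []
        for cls in self.classes:
            for rank, r in enumerate(self.classifiers[cls].rules, start=1):
                rows.append(
                    {
                        "class": cls,
                        "rank": rank,
                        "gene_a": r.gene_a,
                        "gene_b": r.gene_b,
                        "delta": r.delta,
                        "gamma": r.gamma,
                    }
                )
        return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Gene selection
# ---------------------------------------------------------------------------

def _direction_scores(
    values: np.ndarray, labels: np.ndarray, target, mode: str
) -> tuple[np.ndarray, np.ndarray]:
    """Per-gene (up_score, down_score) from the AUC - 0.5 form of the Wilcoxon test.

    Higher up_score = more upregulated in the target group; higher
    down_score = more downregulated.  In one-vs-one mode each score is the
    worst case (minimum) across all opposing classes, so a gene must be
    consistently up (or down) against every other class to score high.
    """
    pos = labels == target
    if mode == "one_vs_rest":
        s = rule_auc(values, pos) - 0.5
        return s, -s
    if mode == "one_vs_one":
        others = [c for c in np.unique(labels) if c != target]
        per_other = []
        for o in others:
            sel = pos | (labels == o)
            per_other.append(rule_auc(values[:, sel], pos[sel]) - 0.5)
        per_other = np.vstack(per_other)
        return per_other.min(axis=0), (-per_other).min(axis=0)
    raise ValueError(f"unknown gene selection mode: {mode!r}")


def select_genes_wilcoxon(
    cohort: LabeledCohort,
    target,
    n: int,
    *,
    mode: str = "one_vs_rest",
    platform_wise: bool = False,
) -> dict:
    """Top n up- and top n down-regulated genes for one class.

    Genes are ranked by a Wilcoxon rank-sum (Mann-Whitney AUC) statistic of
    the target class versus the rest (or the worst case across one-vs-one
    comparisons).  With ``platform_wise`` the ranking is done within each
    platform and genes must be in the top set on every platform; if that
    intersection is smaller than requested, the remainder is filled by the
    best worst-case (max across platforms) rank.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    labels = cohort.labels.to_numpy()
    if target not in labels:
        raise ValueError(f"target class {target!r} absent from cohort")
    values = cohort.expression.values.to_numpy()
    genes = cohort.expression.values.index.to_numpy()

    platforms = cohort.expression.platform
    if platform_wise and platforms is not None and platforms.nunique() > 1:
        up_sets, down_sets = [], []
        for plat in sorted(platforms.unique()):
            on = (platforms == plat).to_numpy()
            up_s, down_s = _direction_scores(values[:, on], labels[on], target, mode)
            up_sets.append(up_s)
            down_sets.append(down_s)
        out = {}
        for direction, score_sets in (("up", up_sets), ("down", down_sets)):
            directed = np.vstack(score_sets)  # platforms × genes, higher = better
            ranks = np.vstack([(-row).argsort(kind="stable").argsort() for row in directed])
            top_all = np.all(ranks < n, axis=0)
            chosen = list(np.nonzero(top_all)[0])
            if len(chosen) < n:
                worst = ranks.max(axis=0)
                order = np.argsort(worst, kind="stable")
                taken = set(chosen)
                for gi in order:
                    if len(chosen) >= n:
                        break
                    if int(gi) not in taken:
                        chosen.append(int(gi))
                        taken.add(int(gi))
            out[direction] = genes[chosen[:n]].tolist()
        return out

    up_s, down_s = _direction_scores(values, labels, target, mode)
    order_up = np.argsort(-up_s, kind="stable")
    order_down = np.argsort(-down_s, kind="stable")
    return {
        "up": genes[order_up[:n]].tolist(),
        "down": genes[order_down[:n]].tolist(),
    }


# ---------------------------------------------------------------------------
# Rule scoring and per-class classifier construction
# ---------------------------------------------------------------------------

def _candidate_pairs(pool: list, all_genes: list, pivot: bool) -> list[tuple]:
    pool_sorted = sorted(set(pool))
    pairs = [(a, b) for i, a in enumerate(pool_sorted) for b in pool_sorted[i + 1:]]
    if pivot:
        pool_set = set(pool_sorted)
        extra = sorted(g for g in all_genes if g not in pool_set)
        pairs += [(min(a, b), max(a, b)) for a in pool_sorted for b in extra]
    return pairs


def _score_candidates(
    rule_vals: np.ndarray,
    rank_diffs: np.ndarray,
    labels: np.ndarray,
    target,
    config: KTSPConfig,
    platforms: np.ndarray | None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Signed delta (positive = TRUE indicates target), gamma, and orientation flips."""
    pos = labels == target

    def signed_delta(vals, lab, grp_pos):
        return vals[:, grp_pos].mean(axis=1) - vals[:, ~grp_pos].mean(axis=1)

    # orient rules so that TRUE indicates the target class (one-vs-rest sense)
    base = signed_delta(rule_vals.astype(float), labels, pos)
    flip = base < 0
    vals = np.where(flip[:, None], ~rule_vals, rule_vals).astype(float)
    rdiffs = np.where(flip[:, None], -rank_diffs, rank_diffs)

    def block_scores(vals_b, rdiffs_b, labels_b):
        pos_b = labels_b == target
        if config.rule_scoring_mode == "one_vs_one":
            others = [c for c in np.unique(labels_b) if c != target]
            deltas, gammas = [], []
            for o in others:
                sel = pos_b | (labels_b == o)
                d, g = tsp_scores(
                    vals_b[:, sel], labels_b[sel], target, mode="one_vs_one", other=o,
                    rank_diffs=rdiffs_b[:, sel],
                )
                p_t = vals_b[:, pos_b].mean(axis=1)
                p_o = vals_b[:, labels_b == o].mean(axis=1)
                deltas.append(p_t - p_o)  # signed: consistency across opponents required
                gammas.append(g)
            return np.vstack(deltas).min(axis=0), np.vstack(gammas).min(axis=0)
        d = vals_b[:, pos_b].mean(axis=1) - vals_b[:, ~pos_b].mean(axis=1)
        _, g = tsp_scores(vals_b, labels_b, target, rank_diffs=rdiffs_b)
        return d, g

    if config.platform_wise and platforms is not None and len(np.unique(platforms)) > 1:
        deltas, gammas = [], []
        for plat in sorted(np.unique(platforms).tolist()):
            on = platforms == plat
            d, g = block_scores(vals[:, on], rdiffs[:, on], labels[on])
            deltas.append(d)
            gammas.append(g)
        delta = np.vstack(deltas).min(axis=0)
        gamma = np.vstack(gammas).min(axis=0)
    else:
        delta, gamma = block_scores(vals, rdiffs, labels)
    return delta, gamma, flip


def build_binary_ktsp(
    cohort: LabeledCohort,
    target,
    config: KTSPConfig = KTSPConfig(),
    *,
    ranked: ExpressionMatrix | None = None,
    gene_pool: dict | None = None,
) -> BinaryKTSP:
    """Train one class's binary k-TSP voter."""
    if gene_pool is None:
        gene_pool = select_genes_wilcoxon(
            cohort,
            target,
            config.n_genes_per_direction,
            mode=config.gene_selection_mode,
            platform_wise=config.platform_wise,
        )
    pool = gene_pool["up"] + gene_pool["down"]
    all_genes = cohort.expression.gene_ids
    pairs = _candidate_pairs(pool, all_genes if config.pivot_genes else pool, config.pivot_genes)

    if ranked is None:
        ranked = rank_transform(cohort.expression)
    gene_pos = {g: i for i, g in enumerate(cohort.expression.values.index)}
    ia = np.array([gene_pos[a] for a, _ in pairs])
    ib = np.array([gene_pos[b] for _, b in pairs])
    arr = cohort.expression.values.to_numpy()
    rarr = ranked.values.to_numpy()
    rule_vals = arr[ia, :] > arr[ib, :]
    rank_diffs = rarr[ia, :] - rarr[ib, :]

    labels = cohort.labels.to_numpy()
    platforms = (
        cohort.expression.platform.to_numpy() if cohort.expression.platform is not None else None
    )
    delta, gamma, flip = _score_candidates(rule_vals, rank_diffs, labels, target, config, platforms)

    # order: delta desc, gamma desc, then label for determinism
    labels_str = [f"{b}>{a}" if f else f"{a}>{b}" for (a, b), f in zip(pairs, flip)]
    order = sorted(range(len(pairs)), key=lambda i: (-delta[i], -gamma[i], labels_str[i]))

    k_max = config.fixed_k if config.fixed_k is not None else config.k_range[1]
    chosen: list[int] = []
    used_genes: set = set()
    for i in order:
        a, b = pairs[i]
        if a in used_genes or b in used_genes:
            continue
        chosen.append(i)
        used_genes.update((a, b))
        if len(chosen) >= k_max:
            break
    if len(chosen) < (config.fixed_k or config.k_range[0]):
        warnings.warn(
            f"class {target}: only {len(chosen)} disjoint candidate pairs available",
            stacklevel=2,
        )

    oriented_vals = np.where(flip[:, None], ~rule_vals, rule_vals)
    votes = np.cumsum(oriented_vals[chosen].astype(float), axis=0)
    pos = labels == target
    criterion = None
    if config.fixed_k is not None:
        k = min(config.fixed_k, len(chosen))
    else:
        lo, hi = config.k_range
        hi = min(hi, len(chosen))
        ks, crits = [], []
        for k_try in range(lo, hi + 1):
            v = votes[k_try - 1]
            diff = abs(v[pos].mean() - v[~pos].mean())
            n1, n0 = pos.sum(), (~pos).sum()
            pooled = np.sqrt(
                ((n1 - 1) * v[pos].var(ddof=1) + (n0 - 1) * v[~pos].var(ddof=1)) / (n1 + n0 - 2)
            )
            crits.append(diff / pooled if pooled > 0 else (np.inf if diff > 0 else 0.0))
            ks.append(k_try)
        criterion = pd.Series(crits, index=pd.Index(ks, name="k"), name="separation")
        k = ks[int(np.argmax(crits))] if ks else len(chosen)

    rules = []
    for i in chosen[:k]:
        a, b = pairs[i]
        ga, gb = (b, a) if flip[i] else (a, b)
        rules.append(GenePairRule(ga, gb, str(target), float(delta[i]), float(gamma[i])))
    return BinaryKTSP(str(target), rules, k, gene_pool, criterion)


def train_ktsp(cohort: LabeledCohort, config: KTSPConfig = KTSPConfig()) -> KTSPModel:
    """One binary k-TSP classifier per class; k may differ between classes."""
    ranked = rank_transform(cohort.expression)
    classifiers = {
        cls: build_binary_ktsp(cohort, cls, config, ranked=ranked) for cls in cohort.classes
    }
    return KTSPModel(classifiers, config)


def predict_ktsp(x: ExpressionMatrix, model: KTSPModel) -> PredictionResult:
    """Score each sample as the fraction of TRUE rules per class voter."""
    scores = {}
    for cls in model.classes:
        clf = model.classifiers[cls]
        rm = binarize(x, clf.rules)
        scores[cls] = rm.values.mean(axis=0)
    frame = pd.DataFrame(scores, index=x.sample_ids)
    return PredictionResult.from_scores(frame)


def tie_prevalence_experiment(
    cohort: LabeledCohort,
    k_values,
    reps: int = 3,
    *,
    config: KTSPConfig = KTSPConfig(),
    train_fraction: float = 0.8,
    seed: int = 0,
) -> pd.DataFrame:
    """Tie rate of fixed-k multiclass k-TSP across a grid of k values.

    For each repetition the cohort is split stratified train/test; for each
    fixed k a model is trained and the fraction of test samples with tied
    top scores is recorded.  Returns the per-k mean tie rate.
    """
    from .core_data import stratified_split

    rows = []
    for rep in range(reps):
        train, test = stratified_split(cohort, train_fraction, seed + rep)
        for k in k_values:
            cfg = replace(config, fixed_k=int(k))
            model = train_ktsp(train, cfg)
            pred = predict_ktsp(test.expression, model)
            rows.append({"k": int(k), "rep": rep, "tie_rate": float(pred.tie.mean())})
    df = pd.DataFrame(rows)
    return df.groupby("k", as_index=False)["tie_rate"].mean()
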