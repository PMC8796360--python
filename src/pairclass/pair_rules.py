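"""Gene-pair rule machinery shared by all rule-based predictors.

A gene-pair rule is the binary statement "expression of gene A exceeds
expression of gene B within one sample".  Because the comparison happens
inside a sample, rule values are invariant to any per-sample strictly
increasing transform of the expression values — the property that makes
rule-based classifiers single-sample predictors.

This module provides rule enumeration, binarization of expression matrices,
top-scoring-pair (TSP) scoring in one-vs-rest and one-vs-one form, and the
per-rule platform-specificity diagnostic (AUC + constancy screen).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations, product

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .core_data import ExpressionMatrix


@dataclass
class GenePairRule:
    """The rule ``expr(gene_a) > expr(gene_b)`` indicating ``target_class``."""

    gene_a: str
    gene_b: str
    target_class: str = "all"
    delta: float | None = None  # primary TSP score in [0, 1]
    gamma: float | None = None  # secondary (rank-difference) tie-break score
    importance: float | None = None

    def __post_init__(self) -> None:
        if self.gene_a == self.gene_b:
            raise ValueError(f"rule cannot pair a gene with itself: {self.gene_a}")

    @property
    def label(self) -> str:
        return f"{self.gene_a}>{self.gene_b}"

    def genes(self) -> tuple[str, str]:
        return (self.gene_a, self.gene_b)


@dataclass
class RuleMatrix:
    """Binary rules × samples matrix; entry is 1 iff expr(A) > expr(B) (ties → 0)."""

    rules: list[GenePairRule]
    sample_ids: list
    values: np.ndarray  # bool, shape (n_rules, n_samples)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=bool)
        if self.values.shape != (len(self.rules), len(self.sample_ids)):
            raise ValueError("rule matrix shape does not match rule/sample lists")

    @property
    def n_rules(self) -> int:
        return len(self.rules)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values.astype(int),
            index=[r.label for r in self.rules],
            columns=self.sample_ids,
        )


def rules_to_frame(rules: list[GenePairRule]) -> pd.DataFrame:
    """Serialize rules as a TSV-ready table."""
    return pd.DataFrame(
        {
            "gene_a": [r.gene_a for r in rules],
            "gene_b": [r.gene_b for r in rules],
            "target_class": [r.target_class for r in rules],
            "delta": [r.delta for r in rules],
            "gamma": [r.gamma for r in rules],
            "importance": [r.importance for r in rules],
        }
    )


def rules_from_frame(df: pd.DataFrame) -> list[GenePairRule]:
    def _opt(v):
        return None if pd.isna(v) else float(v)

    return [
        GenePairRule(
            row.gene_a,
            row.gene_b,
            row.target_class,
            _opt(row.delta),
            _opt(row.gamma),
            _opt(row.importance),
        )
        for row in df.itertuples(index=False)
    ]


# ---------------------------------------------------------------------------
# Enumeration and binarization
# ---------------------------------------------------------------------------

def enumerate_rules(genes_left, genes_right, target_class: str = "all") -> list[GenePairRule]:
    """All gene pairs (a, b) with a from the left list and b from the right.

    When both lists contain the same genes, exactly n(n-1)/2 unordered pairs
    are emitted with the orientation canonicalized lexicographically
    (flipping a rule's orientation complements its value, so delta is
    unaffected by the convention).
    """
    left, right = list(genes_left), list(genes_right)
    if not left or not right:
        raise ValueError("gene lists must be non-empty")
    if set(left) == set(right):
        return [GenePairRule(a, b, target_class) for a, b in combinations(sorted(left), 2)]
    return [GenePairRule(a, b, target_class) for a, b in product(left, right) if a != b]


def binarize(x: ExpressionMatrix, rules: list[GenePairRule]) -> RuleMatrix:
    """Evaluate each rule on each sample: 1 iff expr(A) > expr(B), ties → 0."""
    gene_pos = {g: i for i, g in enumerate(x.values.index)}
    ia, ib = [], []
    for r in rules:
        for g in (r.gene_a, r.gene_b):
            if g not in gene_pos:
                raise KeyError(f"gene {g!r} required by rule {r.label} is absent from the matrix")
        ia.append(gene_pos[r.gene_a])
        ib.append(gene_pos[r.gene_b])
    arr = x.values.to_numpy()
    values = arr[ia, :] > arr[ib, :]
    return RuleMatrix(list(rules), x.sample_ids, values)


# ---------------------------------------------------------------------------
# TSP scoring
# ---------------------------------------------------------------------------

def tsp_scores(
    rule_values: np.ndarray,
    labels: pd.Series | np.ndarray,
    target,
    *,
    mode: str = "one_vs_rest",
    other=None,
    rank_diffs: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray | None]:
    """Vectorized TSP scores for a (rules × samples) binary matrix.

    delta is the absolute difference in empirical frequency of the rule
    being TRUE between the target class and the comparison group (all other
    samples in one-vs-rest mode, class ``other`` in one-vs-one mode).  gamma,
    computed when ``rank_diffs`` (per-rule within-sample rank differences
    rank(A) - rank(B)) is supplied, is the absolute difference in mean rank
    difference between the two groups — the classical secondary score used
    to order rules of equal delta.
    """
    labels = np.asarray(labels)
    vals = np.atleast_2d(np.asarray(rule_values, dtype=float))
    pos = labels == target
    if mode == "one_vs_rest":
        neg = ~pos
    elif mode == "one_vs_one":
        if other is None:
            raise ValueError("one_vs_one mode requires `other`")
        neg = labels == other
    else:
        raise ValueError(f"unknown mode: {mode!r}")
    if pos.sum() == 0 or neg.sum() == 0:
        raise ValueError("empty class group in TSP scoring")
    delta = np.abs(vals[:, pos].mean(axis=1) - vals[:, neg].mean(axis=1))
    gamma = None
    if rank_diffs is not None:
        rd = np.atleast_2d(np.asarray(rank_diffs, dtype=float))
        gamma = np.abs(rd[:, pos].mean(axis=1) - rd[:, neg].mean(axis=1))
    return delta, gamma


def tsp_score(
    rule_values,
    labels,
    target,
    *,
    mode: str = "one_vs_rest",
    other=None,
    rank_diffs=None,
) -> tuple[float, float | None]:
    """Scalar convenience wrapper of :func:`tsp_scores` for a single rule."""
    delta, gamma = tsp_scores(
        np.asarray(rule_values)[None, :],
        labels,
        target,
        mode=mode,
        other=other,
        rank_diffs=None if rank_diffs is None else np.asarray(rank_diffs)[None, :],
    )
    return float(delta[0]), None if gamma is None else float(gamma[0])


def rule_rank_diffs(ranked_values: np.ndarray, ia: np.ndarray, ib: np.ndarray) -> np.ndarray:
    """Within-sample rank differences rank(A) - rank(B) for a set of pairs."""
    return ranked_values[ia, :] - ranked_values[ib, :]


# ---------------------------------------------------------------------------
# AUC and platform specificity
# ---------------------------------------------------------------------------

def rule_auc(values: np.ndarray, positive: np.ndarray) -> np.ndarray:
    """Mann-Whitney AUC of each row of ``values`` against a binary grouping.

    Ties are handled through average ranks, so for binary rule values the
    result equals P(pos > neg) + 0.5 P(pos == neg).
    """
    vals = np.atleast_2d(np.asarray(values, dtype=float))
    positive = np.asarray(positive, dtype=bool)
    n1 = int(positive.sum())
    n0 = int((~positive).sum())
    if n1 == 0 or n0 == 0:
        return np.full(vals.shape[0], np.nan)
    ranks = rankdata(vals, method="average", axis=1)
    r1 = ranks[:, positive].sum(axis=1)
    return (r1 - n1 * (n1 + 1) / 2.0) / (n1 * n0)


def platform_specificity(
    rule_matrix: RuleMatrix,
    labels: pd.Series,
    platforms: pd.Series,
    *,
    auc_high: float = 0.7,
    auc_low: float = 0.55,
    constancy_high: float = 0.95,
) -> pd.DataFrame:
    """Per-rule, per-platform discrimination report with a specificity flag.

    For every rule (scored against its own target class) and every platform,
    the report carries the within-platform Mann-Whitney AUC of the binary
    rule value against target-class membership, and the constancy fraction
    (max of the fraction TRUE and the fraction FALSE).  A rule is flagged
    ``platform_specific`` when it discriminates on some platform
    (AUC >= ``auc_high``) while on another platform it is either
    uninformative (AUC <= ``auc_low``) or nearly constant
    (constancy >= ``constancy_high``).  Platforms with no target-class
    samples yield an undefined (NaN) AUC and are excluded from flagging.
    """
    labels = np.asarray(labels)
    platforms = np.asarray(platforms)
    plat_names = sorted(pd.unique(platforms).tolist())
    if len(plat_names) < 2:
        raise ValueError("platform specificity requires >= 2 platforms")
    vals = rule_matrix.values
    targets = np.array([r.target_class for r in rule_matrix.rules])
    auc_by_plat: dict[str, np.ndarray] = {}
    const_by_plat: dict[str, np.ndarray] = {}
    for plat in plat_names:
        on = platforms == plat
        sub = vals[:, on].astype(float)
        const_by_plat[plat] = np.maximum(sub.mean(axis=1), 1.0 - sub.mean(axis=1))
        aucs = np.empty(vals.shape[0])
        for target in np.unique(targets):
            sel = targets == target
            pos = labels[on] == target
            if pos.sum() == 0 or (~pos).sum() == 0:
                aucs[sel] = np.nan
            else:
                # AUC folded so that either orientation of discrimination counts
                raw = rule_auc(sub[sel], pos)
                aucs[sel] = np.maximum(raw, 1.0 - raw)
        auc_by_plat[plat] = aucs

    n_rules = vals.shape[0]
    flagged = np.zeros(n_rules, dtype=bool)
    for i in range(n_rules):
        discriminates = [p for p in plat_names if auc_by_plat[p][i] >= auc_high]
        if not discriminates:
            continue
        for p in plat_names:
            if p in discriminates or np.isnan(auc_by_plat[p][i]):
                continue
            if auc_by_plat[p][i] <= auc_low or const_by_plat[p][i] >= constancy_high:
                flagged[i] = True
                break

    out = pd.DataFrame(index=pd.Index([r.label for r in rule_matrix.rules], name="rule"))
    out["target_class"] = targets
    for p in plat_names:
        out[f"auc_{p}"] = auc_by_plat[p]
        out[f"constancy_{p}"] = const_by_plat[p]
    out["platform_specific"] = flagged
    return out
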