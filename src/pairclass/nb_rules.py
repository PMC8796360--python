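"""Naive Bayes over gene-pair rules (AIMS-style multiclass classifier).

All candidate gene pairs are scored per class by the one-vs-rest TSP delta
(optionally computed per training dataset and combined as a weighted
average, which damps rules that only discriminate in the largest dataset).
The same number k of top rules per class is used for every class; k is
chosen as the peak mean overall accuracy of a stratified 20-fold
cross-validation over a grid (default 1..50), with ties resolved toward the
smallest k.  The final model is a Bernoulli Naive Bayes over the selected
binary rules with class-proportion priors and additive (Laplace) smoothing.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold
from sklearn.naive_bayes import BernoulliNB

from .core_data import ExpressionMatrix, LabeledCohort
from .pair_rules import GenePairRule, binarize, rule_auc
from .results import PredictionResult


@dataclass(frozen=True)
class NBRulesConfig:
    k_range: tuple[int, int] = (1, 50)
    cv_folds: int = 20
    dataset_weights: dict | None = None  # dataset name -> positive weight
    candidate_gene_cap: int = 300  # guard on exhaustive pair enumeration
    smoothing_alpha: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.cv_folds < 2:
            raise ValueError("cv_folds must be >= 2")
        if self.k_range[0] < 1 or self.k_range[1] < self.k_range[0]:
            raise ValueError("invalid k_range")
        if self.dataset_weights is not None and any(w <= 0 for w in self.dataset_weights.values()):
            raise ValueError("dataset weights must be positive")


@dataclass
class NBRulesModel:
    rules: list[GenePairRule]  # k per class, concatenated in class order
    k: int
    classes: list
    log_priors: pd.Series
    conditionals: pd.DataFrame  # P(rule=1 | class), rules × classes
    cv_curve: pd.Series  # mean CV accuracy over k
    config: NBRulesConfig
    _nb: BernoulliNB | None = None


def _prefilter_genes(cohort: LabeledCohort, cap: int) -> list:
    """Top genes by folded one-vs-rest AUC across classes (applied only above the cap)."""
    values = cohort.expression.values.to_numpy()
    labels = cohort.labels.to_numpy()
    best = np.zeros(values.shape[0])
    for cls in cohort.classes:
        auc = rule_auc(values, labels == cls)
        best = np.maximum(best, np.maximum(auc, 1.0 - auc))
    order = np.argsort(-best, kind="stable")[:cap]
    genes = cohort.expression.values.index.to_numpy()
    return sorted(genes[order].tolist())


def _rank_rules_per_class(
    rule_vals: np.ndarray,
    labels: np.ndarray,
    classes: list,
    datasets: np.ndarray | None,
    weights: dict | None,
) -> dict:
    """Per class: candidate rule indices sorted by descending (weighted) delta."""
    out = {}
    vals = rule_vals.astype(float)
    for cls in classes:
        if weights is not None and datasets is not None:
            num = np.zeros(vals.shape[0])
            den = 0.0
            for ds, w in weights.items():
                on = datasets == ds
                pos = labels[on] == cls
                if pos.sum() == 0 or (~pos).sum() == 0:
                    continue
                sub = vals[:, on]
                num += w * np.abs(sub[:, pos].mean(axis=1) - sub[:, ~pos].mean(axis=1))
                den += w
            delta = num / den if den > 0 else np.zeros(vals.shape[0])
        else:
            pos = labels == cls
            delta = np.abs(vals[:, pos].mean(axis=1) - vals[:, ~pos].mean(axis=1))
        out[cls] = (np.argsort(-delta, kind="stable"), delta)
    return out


def _top_k_union(rankings: dict, classes: list, k: int) -> np.ndarray:
    idx: list[int] = []
    seen: set[int] = set()
    for cls in classes:
        order, _ = rankings[cls]
        for i in order[:k]:
            if int(i) not in seen:
                seen.add(int(i))
                idx.append(int(i))
    return np.array(idx, dtype=int)


def train_nb_rules(cohort: LabeledCohort, config: NBRulesConfig = NBRulesConfig()) -> NBRulesModel:
    """Exhaustive rule scoring + CV choice of k + Bernoulli NB fit."""
    genes = cohort.expression.gene_ids
    if len(genes) > config.candidate_gene_cap:
        warnings.warn(
            f"{len(genes)} genes exceed candidate_gene_cap={config.candidate_gene_cap}; "
            "pre-filtering by one-vs-rest AUC before exhaustive pair enumeration",
            stacklevel=2,
        )
        genes = _prefilter_genes(cohort, config.candidate_gene_cap)
        expr = cohort.expression.subset_genes(genes)
    else:
        expr = cohort.expression

    pairs = [(a, b) for i, a in enumerate(sorted(genes)) for b in sorted(genes)[i + 1:]]
    gene_pos = {g: i for i, g in enumerate(expr.values.index)}
    ia = np.array([gene_pos[a] for a, _ in pairs])
    ib = np.array([gene_pos[b] for _, b in pairs])
    arr = expr.values.to_numpy()
    rule_vals = arr[ia, :] > arr[ib, :]

    labels = cohort.labels.to_numpy()
    classes = cohort.classes
    datasets = expr.dataset.to_numpy() if expr.dataset is not None else None
    weights = config.dataset_weights

    lo, hi = config.k_range
    hi = min(hi, len(pairs))
    n_folds = min(config.cv_folds, int(cohort.class_counts().min()))
    if n_folds < config.cv_folds:
        warnings.warn(
            f"smallest class supports only {n_folds}-fold CV (requested {config.cv_folds})",
            stacklevel=2,
        )
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=config.seed)
    ks = list(range(lo, hi + 1))
    acc = np.zeros((len(ks), n_folds))
    X_all = rule_vals.T  # samples × rules
    for f, (tr, te) in enumerate(skf.split(X_all, labels)):
        rankings = _rank_rules_per_class(
            rule_vals[:, tr], labels[tr], classes,
            None if datasets is None else datasets[tr], weights,
        )
        for ki, k in enumerate(ks):
            sel = _top_k_union(rankings, classes, k)
            nb = BernoulliNB(alpha=config.smoothing_alpha)
            nb.fit(X_all[np.ix_(tr, sel)], labels[tr])
            acc[ki, f] = (nb.predict(X_all[np.ix_(te, sel)]) == labels[te]).mean()
    cv_curve = pd.Series(acc.mean(axis=1), index=pd.Index(ks, name="k"), name="cv_accuracy")
    k_best = int(cv_curve.index[np.argmax(cv_curve.to_numpy())])  # argmax → smallest k on ties

    rankings = _rank_rules_per_class(rule_vals, labels, classes, datasets, weights)
    sel = _top_k_union(rankings, classes, k_best)
    nb = BernoulliNB(alpha=config.smoothing_alpha)
    nb.fit(X_all[:, sel], labels)

    # deduplicated rule list in exactly the order the NB model consumes it
    nb_rules = []
    seen: set[int] = set()
    for cls in classes:
        order, delta = rankings[cls]
        for i in order[:k_best]:
            if int(i) not in seen:
                seen.add(int(i))
                a, b = pairs[int(i)]
                nb_rules.append(GenePairRule(a, b, str(cls), float(delta[int(i)])))

    conditionals = pd.DataFrame(
        np.exp(nb.feature_log_prob_).T,
        index=[r.label for r in nb_rules],
        columns=nb.classes_,
    )
    log_priors = pd.Series(nb.class_log_prior_, index=nb.classes_)
    return NBRulesModel(
        rules=nb_rules,
        k=k_best,
        classes=list(nb.classes_),
        log_priors=log_priors,
        conditionals=conditionals,
        cv_curve=cv_curve,
        config=config,
        _nb=nb,
    )


def predict_nb_rules(x: ExpressionMatrix, model: NBRulesModel) -> PredictionResult:
    """Posterior class probabilities under the Bernoulli NB over the model's rules."""
    rm = binarize(x, model.rules)
    X = rm.values.T.astype(float)
    if model._nb is not None:
        proba = model._nb.predict_proba(X)
        classes = list(model._nb.classes_)
    else:  # reconstruct from stored parameters (deserialized models)
        logp = np.log(model.conditionals.to_numpy())  # rules × classes
        log1m = np.log1p(-model.conditionals.to_numpy())
        joint = X @ logp + (1.0 - X) @ log1m + model.log_priors.to_numpy()[None, :]
        joint -= joint.max(axis=1, keepdims=True)
        proba = np.exp(joint)
        proba /= proba.sum(axis=1, keepdims=True)
        classes = model.log_priors.index.tolist()
    scores = pd.DataFrame(proba, index=x.sample_ids, columns=classes)
    return PredictionResult.from_scores(scores)
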