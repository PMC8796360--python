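"""Three-stage rule-based Random Forest single-sample predictor.

Stage 1 ranks genes by Random Forest impurity importance on within-sample
*ranked* raw data — one all-classes model plus one one-vs-rest model per
class (genes that identify smaller classes may not reach the very top of
the all-classes ranking, so the per-class models supplement the union).
Stage 2 enumerates all gene pairs of the selected union, binarizes them and
repeats the importance ranking with rules as features.  Stage 3 filters the
per-model rule rankings so that each gene is used by at most
``gene_repetition`` retained rules (diversification), takes the top R
filtered rules per model, and trains a final probability forest on the
deduplicated rule set.

The forest is a bagging ensemble of fully grown CART trees on binary rule
features.  Bootstrap membership is stored per tree, enabling out-of-bag
(OOB) accuracy, per-sample OOB class scores, and the OOB proximity matrix
(co-terminal-node frequency over trees where both samples are out-of-bag).
Rules unevaluable at prediction time because of missing genes are imputed
by k-nearest-neighbour over Hamming similarity to the retained training
rule matrix.  Boruta-style pruning compares each rule's importance against
permuted shadow copies and discards rules that never beat them.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import binom
from sklearn.tree import DecisionTreeClassifier

from .core_data import ExpressionMatrix, LabeledCohort, rank_transform
from .pair_rules import GenePairRule, RuleMatrix, binarize
from .results import PredictionResult


@dataclass(frozen=True)
class RFConfig:
    """Hyperparameters of the three-stage pipeline.

    ``genes_per_model`` (G) and ``rules_per_model`` (R) are the per-model
    selection budgets (the evaluated grids are {10, 20, 50, 100, 200}).
    Selection forests use ``mtry = mtry_selection_fraction`` of the feature
    count; the final probability forest uses ``mtry = floor(sqrt(#rules))``.
    Trees are grown to ``node_size`` = 1 with Gini impurity importance.
    """

    genes_per_model: int = 50
    rules_per_model: int = 50
    n_trees_selection: int = 5000
    n_trees_final: int = 5000
    node_size: int = 1
    mtry_selection_fraction: float = 0.10
    gene_repetition: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.genes_per_model < 1 or self.rules_per_model < 1:
            raise ValueError("G and R must be >= 1")
        if not 0 < self.mtry_selection_fraction <= 1:
            raise ValueError("mtry_selection_fraction must be in (0, 1]")
        if self.gene_repetition < 1:
            raise ValueError("gene_repetition must be >= 1")


def bootstrap_indices(rng: np.random.Generator, n: int) -> np.ndarray:
    """One bootstrap resample of size n (with replacement)."""
    return rng.integers(0, n, n)


class BaggedForest:
    """Bagging ensemble of fully grown CART trees with OOB bookkeeping.

    A split on a binary rule feature *is* a rule truth test, so trees over
    the binarized matrix are rule-decision trees.  Per-tree bootstrap
    membership is retained to compute OOB scores and OOB proximities.
    """

    def __init__(self, n_trees: int, mtry: int, node_size: int = 1, seed: int = 0):
        self.n_trees = int(n_trees)
        self.mtry = int(mtry)
        self.node_size = int(node_size)
        self.seed = int(seed)

    def fit(self, X: np.ndarray, y: np.ndarray) -> "BaggedForest":
        X = np.asarray(X)
        y = np.asarray(y)
        n, p = X.shape
        self.classes_ = np.array(sorted(pd.unique(y)))
        class_index = {c: i for i, c in enumerate(self.classes_)}
        rng = np.random.default_rng(np.random.SeedSequence(entropy=self.seed, spawn_key=(11,)))
        self.trees_: list[DecisionTreeClassifier] = []
        self.oob_mask_ = np.zeros((self.n_trees, n), dtype=bool)
        importances = np.zeros(p)
        oob_sum = np.zeros((n, len(self.classes_)))
        oob_count = np.zeros(n)
        for t in range(self.n_trees):
            idx = bootstrap_indices(rng, n)
            oob = np.ones(n, dtype=bool)
            oob[idx] = False
            self.oob_mask_[t] = oob
            tree = DecisionTreeClassifier(
                max_features=min(self.mtry, p),
                min_samples_leaf=self.node_size,
                criterion="gini",
                random_state=int(rng.integers(0, 2**31 - 1)),
            )
            tree.fit(X[idx], y[idx])
            self.trees_.append(tree)
            importances += tree.feature_importances_
            if oob.any():
                proba = tree.predict_proba(X[oob])
                cols = [class_index[c] for c in tree.classes_]
                oob_sum[np.ix_(oob, cols)] += proba
                oob_count[oob] += 1
        self.feature_importances_ = importances / self.n_trees
        with np.errstate(invalid="ignore"):
            self.oob_proba_ = oob_sum / oob_count[:, None]
        self.oob_count_ = oob_count
        self._y = y
        self._X_train = X
        return self

    @property
    def oob_accuracy_(self) -> float:
        valid = self.oob_count_ > 0
        pred = self.classes_[np.nanargmax(self.oob_proba_[valid], axis=1)]
        return float((pred == self._y[valid]).mean())

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X)
        out = np.zeros((X.shape[0], len(self.classes_)))
        class_index = {c: i for i, c in enumerate(self.classes_)}
        for tree in self.trees_:
            proba = tree.predict_proba(X)
            cols = [class_index[c] for c in tree.classes_]
            out[:, cols] += proba
        return out / self.n_trees

    def proximity(self) -> np.ndarray:
        """OOB proximity: co-terminal-node frequency over jointly OOB trees.

        Entries with no jointly OOB tree are NaN; the diagonal is 1 by
        convention.
        """
        n = self._X_train.shape[0]
        same = np.zeros((n, n))
        both = np.zeros((n, n))
        for t, tree in enumerate(self.trees_):
            oob = self.oob_mask_[t]
            if oob.sum() < 2:
                continue
            leaves = tree.apply(self._X_train[oob])
            co = oob[:, None] & oob[None, :]
            eq = leaves[:, None] == leaves[None, :]
            both[co] += 1
            same[np.ix_(oob, oob)] += eq
        with np.errstate(invalid="ignore"):
            prox = same / both
        np.fill_diagonal(prox, 1.0)
        return prox


@dataclass
class RFRuleModel:
    """Trained stage-3 probability forest plus everything needed to audit it."""

    rules: list[GenePairRule]
    forest: BaggedForest
    training_rules: RuleMatrix  # retained binary training matrix
    training_labels: pd.Series
    gene_union: list
    gene_importances: dict  # model name -> pd.Series
    rule_importances: pd.DataFrame  # rules × models
    oob_scores: pd.DataFrame  # samples × classes
    oob_accuracy: float
    config: RFConfig

    @property
    def classes(self) -> list:
        return list(self.forest.classes_)


# ---------------------------------------------------------------------------
# Stage 1: gene selection
# ---------------------------------------------------------------------------

def _model_targets(classes: list) -> list:
    return ["all"] + [f"ovr:{c}" for c in classes]


def _labels_for(target: str, labels: np.ndarray) -> np.ndarray:
    if target == "all":
        return labels
    cls = target.split(":", 1)[1]
    return np.where(labels == cls, cls, "__rest__")


def stage1_select_genes(cohort: LabeledCohort, config: RFConfig = RFConfig()) -> tuple[list, dict]:
    """Gene union from the all-classes and one-vs-rest importance rankings.

    Expression is rank-transformed within each sample before training, so
    the selection (like everything downstream) is invariant to per-sample
    monotone transforms.  Returns (gene union with all-classes provenance
    first, per-model importance Series).
    """
    ranked = rank_transform(cohort.expression)
    X = ranked.values.to_numpy().T  # samples × genes
    genes = ranked.values.index.to_numpy()
    labels = cohort.labels.to_numpy()
    G = config.genes_per_model
    if G > len(genes):
        warnings.warn(f"G={G} exceeds gene count {len(genes)}; using all genes", stacklevel=2)
        G = len(genes)
    mtry = max(1, round(config.mtry_selection_fraction * X.shape[1]))
    importances: dict = {}
    union: list = []
    seen: set = set()
    for mi, target in enumerate(_model_targets(cohort.classes)):
        forest = BaggedForest(
            config.n_trees_selection, mtry, config.node_size, seed=config.seed * 1000 + mi
        ).fit(X, _labels_for(target, labels))
        imp = pd.Series(forest.feature_importances_, index=genes, name=target)
        importances[target] = imp
        top = imp.sort_values(ascending=False, kind="stable").index[:G]
        for g in top:
            if g not in seen:
                seen.add(g)
                union.append(g)
    return union, importances


# ---------------------------------------------------------------------------
# Stage 2: rule ranking
# ---------------------------------------------------------------------------

def stage2_rank_rules(
    cohort: LabeledCohort, gene_union: list, config: RFConfig = RFConfig()
) -> tuple[list[GenePairRule], pd.DataFrame]:
    """Importance of every pairwise rule of the union, per RF model."""
    union_sorted = sorted(gene_union)
    rules = [
        GenePairRule(a, b)
        for i, a in enumerate(union_sorted)
        for b in union_sorted[i + 1:]
    ]
    rm = binarize(cohort.expression, rules)
    X = rm.values.T.astype(np.float32)
    labels = cohort.labels.to_numpy()
    mtry = max(1, round(config.mtry_selection_fraction * X.shape[1]))
    cols = {}
    for mi, target in enumerate(_model_targets(cohort.classes)):
        forest = BaggedForest(
            config.n_trees_selection, mtry, config.node_size, seed=config.seed * 1000 + 100 + mi
        ).fit(X, _labels_for(target, labels))
        cols[target] = forest.feature_importances_
    imp = pd.DataFrame(cols, index=[r.label for r in rules])
    return rules, imp


# ---------------------------------------------------------------------------
# Stage 3: diversification + final forest
# ---------------------------------------------------------------------------

def diversify_rules(
    rules: list[GenePairRule],
    rule_importances: pd.DataFrame,
    gene_repetition: int = 1,
) -> dict:
    """Per-model top-down scan keeping each gene at most ``gene_repetition`` times.

    Returns {model name: list of retained rule indices in rank order}.
    """
    out: dict = {}
    for model_name in rule_importances.columns:
        imp = rule_importances[model_name].to_numpy()
        order = np.argsort(-imp, kind="stable")
        gene_used: dict = {}
        kept: list[int] = []
        for i in order:
            r = rules[int(i)]
            if gene_used.get(r.gene_a, 0) >= gene_repetition:
                continue
            if gene_used.get(r.gene_b, 0) >= gene_repetition:
                continue
            kept.append(int(i))
            gene_used[r.gene_a] = gene_used.get(r.gene_a, 0) + 1
            gene_used[r.gene_b] = gene_used.get(r.gene_b, 0) + 1
        out[model_name] = kept
    return out


def train_final_forest(
    cohort: LabeledCohort,
    rules: list[GenePairRule],
    kept_per_model: dict,
    config: RFConfig = RFConfig(),
    *,
    gene_union: list | None = None,
    gene_importances: dict | None = None,
    rule_importances: pd.DataFrame | None = None,
) -> RFRuleModel:
    """Top-R filtered rules per model, deduplicated, into a probability forest."""
    R = config.rules_per_model
    final_idx: list[int] = []
    seen: set[int] = set()
    for model_name, kept in kept_per_model.items():
        if len(kept) < R:
            warnings.warn(
                f"model {model_name}: only {len(kept)} filtered rules (R={R} requested)",
                stacklevel=2,
            )
        for i in kept[:R]:
            if i not in seen:
                seen.add(i)
                final_idx.append(i)
    final_rules = []
    for i in final_idx:
        r = rules[i]
        imp = None
        if rule_importances is not None:
            imp = float(rule_importances.iloc[i].max())
        final_rules.append(GenePairRule(r.gene_a, r.gene_b, r.target_class, r.delta, r.gamma, imp))

    rm = binarize(cohort.expression, final_rules)
    X = rm.values.T.astype(np.float32)
    mtry = max(1, int(np.sqrt(len(final_rules))))
    forest = BaggedForest(
        config.n_trees_final, mtry, config.node_size, seed=config.seed * 1000 + 500
    ).fit(X, cohort.labels.to_numpy())
    oob = pd.DataFrame(forest.oob_proba_, index=cohort.expression.sample_ids, columns=forest.classes_)
    return RFRuleModel(
        rules=final_rules,
        forest=forest,
        training_rules=rm,
        training_labels=cohort.labels.copy(),
        gene_union=gene_union or sorted({g for r in final_rules for g in r.genes()}),
        gene_importances=gene_importances or {},
        rule_importances=rule_importances if rule_importances is not None else pd.DataFrame(),
        oob_scores=oob,
        oob_accuracy=forest.oob_accuracy_,
        config=config,
    )


def train_rf_rules(cohort: LabeledCohort, config: RFConfig = RFConfig()) -> RFRuleModel:
    """The full three-stage pipeline."""
    gene_union, gene_imp = stage1_select_genes(cohort, config)
    rules, rule_imp = stage2_rank_rules(cohort, gene_union, config)
    kept = diversify_rules(rules, rule_imp, config.gene_repetition)
    return train_final_forest(
        cohort,
        rules,
        kept,
        config,
        gene_union=gene_union,
        gene_importances=gene_imp,
        rule_importances=rule_imp,
    )


# ---------------------------------------------------------------------------
# Prediction with kNN rule imputation
# ---------------------------------------------------------------------------

def impute_missing_rules(x: ExpressionMatrix, model: RFRuleModel, k: int = 5) -> np.ndarray:
    """Rule matrix for new samples, imputing rules whose genes are absent.

    Evaluable rules are computed directly.  For each sample, Hamming
    similarity to the retained training samples is computed over the
    evaluable rules only (pairwise-complete); each missing rule is filled
    with the modal value among the k most similar training samples, with
    mode ties broken by the single most similar neighbour's value.
    """
    present_genes = set(x.values.index)
    evaluable = np.array([set(r.genes()) <= present_genes for r in model.rules])
    n_rules = len(model.rules)
    n_samples = x.n_samples
    values = np.zeros((n_rules, n_samples), dtype=bool)
    if evaluable.any():
        sub_rules = [model.rules[i] for i in np.nonzero(evaluable)[0]]
        values[evaluable] = binarize(x, sub_rules).values
    if evaluable.all():
        return values
    if not evaluable.any():
        raise ValueError("no evaluable rules: cannot impute")
    train = model.training_rules.values  # rules × training samples
    missing_idx = np.nonzero(~evaluable)[0]
    agree = (values[evaluable][:, :, None] == train[evaluable][:, None, :]).mean(axis=0)
    # agree: new samples × training samples Hamming similarity
    for j in range(n_samples):
        order = np.argsort(-agree[j], kind="stable")
        nn = order[:k]
        votes = train[np.ix_(missing_idx, nn)]
        n_true = votes.sum(axis=1)
        fill = n_true * 2 > len(nn)
        tied = n_true * 2 == len(nn)
        if tied.any():
            fill[tied] = train[np.ix_(missing_idx[tied], [order[0]])].ravel()
        values[missing_idx, j] = fill
    return values


def predict_rf(
    x: ExpressionMatrix, model: RFRuleModel, *, impute_k: int = 5, max_missing_fraction: float = 0.5
) -> PredictionResult:
    """Forest-averaged class probabilities for new samples."""
    present_genes = set(x.values.index)
    evaluable = np.array([set(r.genes()) <= present_genes for r in model.rules])
    missing_frac = 1.0 - evaluable.mean()
    if missing_frac > max_missing_fraction:
        raise ValueError(
            f"{missing_frac:.0%} of rules unevaluable (> {max_missing_fraction:.0%}): refusing to predict"
        )
    values = impute_missing_rules(x, model, k=impute_k) if missing_frac > 0 else binarize(x, model.rules).values
    proba = model.forest.predict_proba(values.T.astype(np.float32))
    scores = pd.DataFrame(proba, index=x.sample_ids, columns=model.forest.classes_)
    return PredictionResult.from_scores(scores)


# ---------------------------------------------------------------------------
# Boruta-style pruning
# ---------------------------------------------------------------------------

@dataclass
class BorutaResult:
    status: pd.Series  # rule label -> confirmed | tentative | rejected
    hits: pd.Series
    trials: int

    def counts(self) -> pd.Series:
        return self.status.value_counts()


def boruta_prune(
    model: RFRuleModel,
    cohort: LabeledCohort | None = None,
    *,
    alpha: float = 0.01,
    max_iter: int = 100,
    n_trees: int = 300,
    keep_tentative: bool = False,
    seed: int | None = None,
) -> tuple[BorutaResult, RFRuleModel]:
    """Shadow-feature pruning of the final rule set.

    Each iteration trains a forest on the active rules plus per-rule
    permuted shadow copies and scores a *hit* for every rule whose
    importance exceeds the maximum shadow importance.  A two-sided binomial
    test over iterations labels rules confirmed (significantly more hits
    than chance) or rejected (significantly fewer, then removed from the
    active set); rules undecided after ``max_iter`` iterations stay
    tentative.  The final forest is rebuilt on the confirmed (optionally
    + tentative) rules.
    """
    X = model.training_rules.values.T.astype(np.float32)  # samples × rules
    y = model.training_labels.to_numpy()
    n, p = X.shape
    labels_idx = pd.Index([r.label for r in model.rules])
    rng = np.random.default_rng(model.config.seed * 1000 + 900 if seed is None else seed)

    active = np.ones(p, dtype=bool)
    hits = np.zeros(p, dtype=int)
    trials = np.zeros(p, dtype=int)
    status = np.array(["tentative"] * p, dtype=object)
    for it in range(1, max_iter + 1):
        act_idx = np.nonzero(active)[0]
        if len(act_idx) == 0:
            break
        Xa = X[:, act_idx]
        shadows = np.empty_like(Xa)
        for j in range(Xa.shape[1]):
            shadows[:, j] = Xa[rng.permutation(n), j]
        Xfull = np.hstack([Xa, shadows])
        mtry = max(1, int(np.sqrt(Xfull.shape[1])))
        forest = BaggedForest(n_trees, mtry, model.config.node_size, seed=int(rng.integers(0, 2**31 - 1))).fit(
            Xfull, y
        )
        imp = forest.feature_importances_
        shadow_max = imp[len(act_idx):].max()
        hits[act_idx] += imp[: len(act_idx)] > shadow_max
        trials[act_idx] += 1
        # two-sided binomial decision at level alpha
        for i in act_idx:
            p_more = binom.sf(hits[i] - 1, trials[i], 0.5)
            p_less = binom.cdf(hits[i], trials[i], 0.5)
            if p_more < alpha:
                status[i] = "confirmed"
                active[i] = False
            elif p_less < alpha:
                status[i] = "rejected"
                active[i] = False
        if not active.any():
            break

    result = BorutaResult(
        status=pd.Series(status, index=labels_idx, name="status"),
        hits=pd.Series(hits, index=labels_idx, name="hits"),
        trials=int(trials.max(initial=0)),
    )
    keep_status = {"confirmed"} | ({"tentative"} if keep_tentative else set())
    keep_mask = np.array([s in keep_status for s in status])
    if not keep_mask.any():
        warnings.warn("Boruta confirmed no rules; keeping the tentative set", stacklevel=2)
        keep_mask = status == "tentative"
    kept_rules = [r for r, k in zip(model.rules, keep_mask) if k]

    X_kept = model.training_rules.values[keep_mask].T.astype(np.float32)
    mtry = max(1, int(np.sqrt(len(kept_rules))))
    forest = BaggedForest(
        model.config.n_trees_final, mtry, model.config.node_size, seed=model.config.seed * 1000 + 501
    ).fit(X_kept, y)
    sample_ids = model.training_rules.sample_ids
    pruned = RFRuleModel(
        rules=kept_rules,
        forest=forest,
        training_rules=RuleMatrix(kept_rules, sample_ids, model.training_rules.values[keep_mask]),
        training_labels=model.training_labels,
        gene_union=sorted({g for r in kept_rules for g in r.genes()}),
        gene_importances=model.gene_importances,
        rule_importances=model.rule_importances,
        oob_scores=pd.DataFrame(forest.oob_proba_, index=sample_ids, columns=forest.classes_),
        oob_accuracy=forest.oob_accuracy_,
        config=model.config,
    )
    return result, pruned


def extract_proximity(model: RFRuleModel) -> pd.DataFrame:
    """OOB proximity matrix of the training samples (NaN where never jointly OOB)."""
    prox = model.forest.proximity()
    ids = model.training_rules.sample_ids
    return pd.DataFrame(prox, index=ids, columns=ids)
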