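"""Rule-based Random Forest pipeline: stages, OOB bookkeeping, pruning,
imputation and proximity."""

from dataclasses import replace

import numpy as np
import pandas as pd
import pytest

from pairclass import (
    ExpressionMatrix,
    GenePairRule,
    LabeledCohort,
    RFConfig,
    boruta_prune,
    diversify_rules,
    extract_proximity,
    impute_missing_rules,
    predict_rf,
    stage1_select_genes,
    stage2_rank_rules,
    train_rf_rules,
)
from pairclass.rf_rules import BaggedForest, bootstrap_indices

FAST = RFConfig(
    genes_per_model=10,
    rules_per_model=10,
    n_trees_selection=100,
    n_trees_final=300,
    seed=7,
)


@pytest.fixture(scope="module")
def trained(clean_cohort):
    cohort, truth, _ = clean_cohort
    return train_rf_rules(cohort, FAST)


class TestBaggedForest:
    def test_oob_masks_match_bootstrap_size(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(50, 5))
        y = rng.choice(["a", "b"], 50)
        f = BaggedForest(n_trees=20, mtry=2, seed=1).fit(X, y)
        assert f.oob_mask_.shape == (20, 50)
        # each bootstrap leaves out a positive fraction of samples
        assert (f.oob_mask_.sum(axis=1) > 0).all()

    def test_expected_oob_fraction_is_one_over_e(self):
        rng = np.random.default_rng(1)
        n, trees = 300, 400
        fracs = []
        for _ in range(trees):
            idx = bootstrap_indices(rng, n)
            mask = np.ones(n, dtype=bool)
            mask[idx] = False
            fracs.append(mask.mean())
        assert np.mean(fracs) == pytest.approx(np.exp(-1), abs=0.01)

    def test_predict_proba_rows_sum_to_one(self, trained, clean_cohort):
        cohort, _, _ = clean_cohort
        pred = predict_rf(cohort.expression, trained)
        np.testing.assert_allclose(pred.scores.sum(axis=1).to_numpy(), 1.0, atol=1e-9)


class TestStage1:
    def test_union_bounded_and_recovers_informative_genes(self, clean_cohort):
        cohort, truth, _ = clean_cohort
        union, importances = stage1_select_genes(cohort, FAST)
        C = len(cohort.classes)
        assert len(union) <= (C + 1) * FAST.genes_per_model
        informative = truth.informative_genes()
        assert len(set(union) & informative) / len(union) >= 0.9

    def test_g_larger_than_gene_count_uses_all(self, noise_free_cohort):
        cohort, _, _ = noise_free_cohort
        cfg = replace(FAST, genes_per_model=10_000, n_trees_selection=30)
        with pytest.warns(UserWarning, match="using all genes"):
            union, _ = stage1_select_genes(cohort, cfg)
        assert set(union) == set(cohort.expression.gene_ids)

    def test_rare_class_gene_enters_via_one_vs_rest_model(self):
        """A gene that only identifies a rare class reaches the union through
        that class's one-vs-rest model even if the all-classes model misses it."""
        rng = np.random.default_rng(6)
        n_major, n_rare = 60, 8
        n = 2 * n_major + n_rare
        values = pd.DataFrame(
            rng.normal(5, 1, (60, n)),
            index=[f"g{i}" for i in range(60)],
            columns=[f"s{j}" for j in range(n)],
        )
        labels = ["A"] * n_major + ["B"] * n_major + ["rare"] * n_rare
        # strong major-split genes
        values.iloc[0:20, :n_major] += 3.0
        values.iloc[20:40, n_major: 2 * n_major] += 3.0
        # one gene marking the rare class
        values.iloc[59, 2 * n_major:] += 6.0
        cohort = LabeledCohort(ExpressionMatrix(values), pd.Series(labels, index=values.columns))
        cfg = RFConfig(genes_per_model=5, rules_per_model=5, n_trees_selection=200,
                       n_trees_final=100, seed=3)
        union, importances = stage1_select_genes(cohort, cfg)
        all_top = importances["all"].sort_values(ascending=False).index[: cfg.genes_per_model]
        rare_top = importances["ovr:rare"].sort_values(ascending=False).index[: cfg.genes_per_model]
        assert "g59" in rare_top
        assert "g59" in union


class TestStage2AndDiversify:
    def test_rule_count_is_n_choose_2(self, clean_cohort):
        cohort, _, _ = clean_cohort
        genes = cohort.expression.gene_ids[:20]
        rules, imp = stage2_rank_rules(cohort, genes, replace(FAST, n_trees_selection=30))
        assert len(rules) == 190
        assert (imp.to_numpy() >= 0).all()

    def test_informative_pair_outranks_noise_pairs(self, clean_cohort):
        cohort, truth, _ = clean_cohort
        cls = cohort.classes[0]
        # pick an up/down pair whose expression ratio actually crosses over:
        # up above down within the class, below it in the rest
        up = down = None
        for u in truth.informative[cls]["up"]:
            for d in truth.informative[cls]["down"]:
                in_cls = truth.class_means.loc[u, cls] - truth.class_means.loc[d, cls]
                in_rest = truth.baseline[u] - truth.baseline[d]
                if in_cls > 1.0 and in_rest < -1.0:
                    up, down = u, d
                    break
            if up:
                break
        assert up is not None
        noise = [g for g in cohort.expression.gene_ids if g not in truth.informative_genes()][:6]
        genes = [up, down] + noise
        rules, imp = stage2_rank_rules(cohort, genes, replace(FAST, n_trees_selection=200))
        col = f"ovr:{cls}"  # the model where this pair carries the signal
        pair_imp = imp[col].loc[f"{min(up, down)}>{max(up, down)}"]
        noise_set = set(noise)
        noise_pair_imps = [
            imp[col].iloc[i]
            for i, r in enumerate(rules)
            if set(r.genes()) <= noise_set
        ]
        assert pair_imp > max(noise_pair_imps)

    def test_diversify_definition_case(self):
        rules = [GenePairRule("A", "B"), GenePairRule("A", "C"), GenePairRule("D", "E")]
        imp = pd.DataFrame({"all": [0.9, 0.8, 0.1]}, index=[r.label for r in rules])
        kept = diversify_rules(rules, imp, gene_repetition=1)
        assert kept["all"] == [0, 2]  # (A,C) dropped: A already used

    def test_diversify_unbounded_repetition_is_identity(self):
        rules = [GenePairRule("A", "B"), GenePairRule("A", "C"), GenePairRule("B", "C")]
        imp = pd.DataFrame({"all": [0.5, 0.4, 0.3]}, index=[r.label for r in rules])
        kept = diversify_rules(rules, imp, gene_repetition=10**9)
        assert kept["all"] == [0, 1, 2]

    @pytest.mark.parametrize("seed", range(5))
    def test_dropped_rules_always_blocked_by_better_kept_rule(self, seed):
        rng = np.random.default_rng(seed)
        genes = [f"g{i}" for i in range(8)]
        rules = [GenePairRule(a, b) for i, a in enumerate(genes) for b in genes[i + 1:]]
        imp = pd.DataFrame({"m": rng.uniform(size=len(rules))}, index=[r.label for r in rules])
        kept = diversify_rules(rules, imp, gene_repetition=1)["m"]
        kept_set = set(kept)
        imps = imp["m"].to_numpy()
        for i, r in enumerate(rules):
            if i in kept_set:
                continue
            blockers = [
                j for j in kept_set
                if set(rules[j].genes()) & set(r.genes()) and imps[j] >= imps[i]
            ]
            assert blockers


class TestFinalForestAndPrediction:
    def test_oob_accuracy_high_on_separable_data(self, trained):
        assert trained.oob_accuracy >= 0.95

    def test_deterministic_given_seed(self, clean_cohort):
        cohort, _, _ = clean_cohort
        m1 = train_rf_rules(cohort, FAST)
        m2 = train_rf_rules(cohort, FAST)
        assert [r.label for r in m1.rules] == [r.label for r in m2.rules]
        p1 = predict_rf(cohort.expression, m1)
        p2 = predict_rf(cohort.expression, m2)
        np.testing.assert_array_equal(p1.scores.to_numpy(), p2.scores.to_numpy())

    @pytest.mark.parametrize(
        "transform",
        [np.log1p, lambda v: v**3, lambda v: 1.5 * v + 4.0],
        ids=["log1p", "cube", "affine"],
    )
    def test_prediction_invariant_to_monotone_transform(self, trained, clean_cohort, transform):
        cohort, _, _ = clean_cohort
        pred = predict_rf(cohort.expression, trained)
        fx = ExpressionMatrix(cohort.expression.values.apply(transform))
        pred2 = predict_rf(fx, trained)
        np.testing.assert_array_equal(pred.scores.to_numpy(), pred2.scores.to_numpy())

    def test_training_samples_predicted_correctly(self, trained, clean_cohort):
        cohort, _, _ = clean_cohort
        pred = predict_rf(cohort.expression, trained)
        assert (pred.predicted == cohort.labels).mean() >= 0.99

    def test_refuses_when_most_rules_unevaluable(self, trained, clean_cohort):
        cohort, _, _ = clean_cohort
        used = sorted({g for r in trained.rules for g in r.genes()})
        keep = [g for g in cohort.expression.gene_ids if g not in used[: int(len(used) * 0.9)]]
        with pytest.raises(ValueError, match="refusing to predict"):
            predict_rf(cohort.expression.subset_genes(keep), trained)


class TestImputation:
    def test_sample_identical_to_training_sample_copies_it(self, trained, clean_cohort):
        cohort, _, _ = clean_cohort
        sid = cohort.expression.sample_ids[0]
        used = sorted({g for r in trained.rules for g in r.genes()})
        masked_genes = set(used[:3])
        keep = [g for g in cohort.expression.gene_ids if g not in masked_genes]
        x = cohort.expression.subset_samples([sid]).subset_genes(keep)
        completed = impute_missing_rules(x, trained, k=5)
        train_col = trained.training_rules.values[:, 0]
        np.testing.assert_array_equal(completed[:, 0], train_col)

    def test_k1_copies_nearest_neighbour(self, trained, clean_cohort):
        cohort, _, _ = clean_cohort
        sid = cohort.expression.sample_ids[5]
        used = sorted({g for r in trained.rules for g in r.genes()})
        keep = [g for g in cohort.expression.gene_ids if g not in set(used[:4])]
        x = cohort.expression.subset_samples([sid]).subset_genes(keep)
        completed = impute_missing_rules(x, trained, k=1)
        # the nearest neighbour is the sample itself (distance 0)
        col = trained.training_rules.sample_ids.index(sid)
        np.testing.assert_array_equal(completed[:, 0], trained.training_rules.values[:, col])

    def test_masking_genes_rarely_changes_confident_predictions(self, trained, clean_cohort):
        cohort, _, _ = clean_cohort
        full = predict_rf(cohort.expression, trained)
        rng = np.random.default_rng(4)
        genes = cohort.expression.gene_ids
        masked = rng.choice(genes, size=len(genes) // 10, replace=False)
        reduced = cohort.expression.subset_genes([g for g in genes if g not in set(masked)])
        part = predict_rf(reduced, trained)
        confident = full.margin > 0.3
        changed = (full.predicted != part.predicted) & confident
        assert changed.sum() / max(confident.sum(), 1) < 0.05


class TestBoruta:
    def test_planted_noise_rules_rejected_and_signal_confirmed(self, clean_cohort):
        cohort, truth, _ = clean_cohort
        model = train_rf_rules(cohort, FAST)
        # plant pure-noise rules among background genes
        background = [g for g in cohort.expression.gene_ids if g not in truth.informative_genes()]
        noise_rules = [GenePairRule(a, b) for a, b in zip(background[:10], background[10:20])]
        from pairclass.pair_rules import binarize

        all_rules = model.rules + noise_rules
        rm = binarize(cohort.expression, all_rules)
        augmented = replace_training(model, rm, cohort)
        result, pruned = boruta_prune(augmented, alpha=0.01, max_iter=25, n_trees=150)
        noise_status = result.status.iloc[len(model.rules):]
        assert (noise_status == "rejected").mean() >= 0.9
        signal_status = result.status.iloc[: len(model.rules)]
        assert (signal_status == "confirmed").mean() > 0.5
        assert pruned.oob_accuracy >= model.oob_accuracy - 0.02


def replace_training(model, rm, cohort):
    """Rebuild the final forest on an explicit rule matrix (test helper)."""
    from pairclass.rf_rules import BaggedForest, RFRuleModel

    X = rm.values.T.astype(np.float32)
    forest = BaggedForest(
        model.config.n_trees_final, max(1, int(np.sqrt(rm.n_rules))),
        model.config.node_size, seed=model.config.seed * 1000 + 500,
    ).fit(X, cohort.labels.to_numpy())
    return RFRuleModel(
        rules=rm.rules,
        forest=forest,
        training_rules=rm,
        training_labels=model.training_labels,
        gene_union=model.gene_union,
        gene_importances=model.gene_importances,
        rule_importances=model.rule_importances,
        oob_scores=model.oob_scores,
        oob_accuracy=forest.oob_accuracy_,
        config=model.config,
    )


class TestProximity:
    def test_invariants_and_separation(self, trained, clean_cohort):
        cohort, _, _ = clean_cohort
        prox = extract_proximity(trained)
        arr = prox.to_numpy()
        np.testing.assert_allclose(np.diag(arr), 1.0)
        finite = np.isfinite(arr)
        assert ((arr[finite] >= 0) & (arr[finite] <= 1)).all()
        np.testing.assert_allclose(arr, arr.T, equal_nan=True)
        labels = cohort.labels.to_numpy()
        same = labels[:, None] == labels[None, :]
        off_diag = ~np.eye(len(labels), dtype=bool)
        within = np.nanmean(arr[same & off_diag])
        between = np.nanmean(arr[~same])
        assert within > between + 0.3

    def test_duplicate_samples_have_high_proximity(self, clean_cohort):
        cohort, _, _ = clean_cohort
        # duplicate the first sample under a new name
        values = cohort.expression.values.copy()
        values["dup"] = values.iloc[:, 0]
        labels = pd.concat(
            [cohort.labels, pd.Series({"dup": cohort.labels.iloc[0]})]
        )
        dup_cohort = LabeledCohort(ExpressionMatrix(values), labels)
        model = train_rf_rules(dup_cohort, replace(FAST, n_trees_final=500))
        prox = extract_proximity(model)
        assert prox.loc["dup", cohort.expression.sample_ids[0]] > 0.95
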