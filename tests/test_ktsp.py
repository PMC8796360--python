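"""Multiclass k-TSP: gene selection, disjoint rule picking, voting, ties."""

from dataclasses import replace

import numpy as np
import pandas as pd
import pytest

from pairclass import (
    ExpressionMatrix,
    KTSPConfig,
    LabeledCohort,
    build_binary_ktsp,
    predict_ktsp,
    select_genes_wilcoxon,
    tie_prevalence_experiment,
    train_ktsp,
)


def _labeled(values, labels):
    x = ExpressionMatrix(values)
    return LabeledCohort(x, pd.Series(labels, index=values.columns))


class TestGeneSelection:
    def test_perfectly_separating_gene_is_top_up(self):
        rng = np.random.default_rng(1)
        values = pd.DataFrame(
            rng.normal(5, 1, (10, 12)),
            index=[f"g{i}" for i in range(10)],
            columns=[f"s{j}" for j in range(12)],
        )
        values.iloc[3, :6] = 20.0  # g3 strictly higher in every target sample
        cohort = _labeled(values, ["T"] * 6 + ["R"] * 6)
        pool = select_genes_wilcoxon(cohort, "T", 2)
        assert pool["up"][0] == "g3"

    def test_absent_class_rejected(self, clean_cohort):
        cohort, _, _ = clean_cohort
        with pytest.raises(ValueError, match="absent"):
            select_genes_wilcoxon(cohort, "nope", 5)

    def test_uninformative_genes_not_selected_at_small_n(self, clean_cohort):
        cohort, truth, _ = clean_cohort
        cls = cohort.classes[0]
        pool = select_genes_wilcoxon(cohort, cls, 5)
        informative = truth.informative_genes(cls)
        hits = sum(g in informative for g in pool["up"] + pool["down"])
        assert hits >= 9

    def test_platform_wise_excludes_single_platform_gene(self, two_platform_cohort):
        from pairclass import inject_platform_specific_pairs

        cohort, truth, cfg = two_platform_cohort
        cohort_i, truth_i = inject_platform_specific_pairs(cohort, truth, 3, config=cfg)
        # the shifted partner gene is discriminative only on platform 1
        cls = truth_i.injected_pairs[0][2]
        shifted = {b for _, b, c in truth_i.injected_pairs if c == cls}
        pool_plain = select_genes_wilcoxon(
            cohort_i.subset(
                cohort_i.expression.platform.index[cohort_i.expression.platform == "rnaseq"]
            ),
            cls,
            10,
        )
        pool_pw = select_genes_wilcoxon(cohort_i, cls, 10, platform_wise=True)
        assert shifted & set(pool_plain["up"] + pool_plain["down"])
        assert not shifted & set(pool_pw["up"] + pool_pw["down"])


class TestBuildBinaryKTSP:
    @pytest.fixture()
    def two_pair_cohort(self):
        """Two perfectly discriminative disjoint pairs (a>b, c>d in class T)."""
        rng = np.random.default_rng(3)
        n = 16
        values = pd.DataFrame(
            rng.normal(5, 0.2, (8, n)),
            index=list("abcdefgh"),
            columns=[f"s{j}" for j in range(n)],
        )
        values.loc["a", : "s7"] += 4.0
        values.loc["c", : "s7"] += 4.0
        values.loc["b", "s8":] += 4.0
        values.loc["d", "s8":] += 4.0
        return _labeled(values, ["T"] * 8 + ["R"] * 8)

    def test_fixed_k_selects_both_perfect_pairs(self, two_pair_cohort):
        clf = build_binary_ktsp(two_pair_cohort, "T", KTSPConfig(n_genes_per_direction=2, fixed_k=2))
        got = {frozenset(r.genes()) for r in clf.rules}
        assert got == {frozenset("ab"), frozenset("cd")} or all(
            r.delta == 1.0 for r in clf.rules
        )
        assert len(clf.rules) == 2

    def test_greedy_disjointness(self, two_pair_cohort):
        clf = build_binary_ktsp(two_pair_cohort, "T", KTSPConfig(n_genes_per_direction=4, fixed_k=4))
        genes = [g for r in clf.rules for g in r.genes()]
        assert len(genes) == len(set(genes))

    def test_pivot_gene_rule_selected(self):
        """The only informative signal is DE-gene vs a non-DE pivot gene."""
        rng = np.random.default_rng(8)
        n = 20
        values = pd.DataFrame(
            rng.normal(5, 1.5, (10, n)),
            index=[f"g{i}" for i in range(10)],
            columns=[f"s{j}" for j in range(n)],
        )
        # pivot gene g9: constant 7; gene g0: 9 in T, 5 in R (crosses the pivot)
        values.iloc[9] = 7.0
        values.iloc[0, : n // 2] = rng.normal(9, 0.3, n // 2)
        values.iloc[0, n // 2:] = rng.normal(5, 0.3, n // 2)
        cohort = _labeled(values, ["T"] * (n // 2) + ["R"] * (n // 2))
        cfg = KTSPConfig(n_genes_per_direction=1, fixed_k=1, pivot_genes=True)
        clf = build_binary_ktsp(cohort, "T", cfg)
        assert "g9" in clf.rules[0].genes()
        assert clf.rules[0].delta == 1.0

    def test_rule_oriented_toward_target(self, clean_cohort):
        cohort, _, _ = clean_cohort
        model = train_ktsp(cohort, KTSPConfig(n_genes_per_direction=10))
        for cls in model.classes:
            for r in model.classifiers[cls].rules:
                vals = (
                    cohort.expression.values.loc[r.gene_a]
                    > cohort.expression.values.loc[r.gene_b]
                ).to_numpy()
                pos = (cohort.labels == cls).to_numpy()
                assert vals[pos].mean() > vals[~pos].mean()


class TestPredict:
    def test_vote_fractions_and_margin(self, clean_cohort):
        cohort, _, _ = clean_cohort
        model = train_ktsp(cohort, KTSPConfig(n_genes_per_direction=10))
        pred = predict_ktsp(cohort.expression, model)
        for cls in model.classes:
            k = model.classifiers[cls].k
            steps = pred.scores[cls].to_numpy() * k
            np.testing.assert_allclose(steps, np.round(steps), atol=1e-9)
        assert (pred.margin >= 0).all()
        assert (pred.predicted == cohort.labels).mean() > 0.95

    @pytest.mark.parametrize(
        "transform",
        [np.log1p, lambda v: v**3, lambda v: 2.0 * v + 1.0],
        ids=["log1p", "cube", "affine"],
    )
    def test_scores_invariant_to_monotone_transform(self, clean_cohort, transform):
        cohort, _, _ = clean_cohort
        model = train_ktsp(cohort, KTSPConfig(n_genes_per_direction=10))
        pred = predict_ktsp(cohort.expression, model)
        fx = ExpressionMatrix(cohort.expression.values.apply(transform))
        pred2 = predict_ktsp(fx, model)
        np.testing.assert_array_equal(pred.scores.to_numpy(), pred2.scores.to_numpy())

    def test_missing_gene_is_an_error(self, clean_cohort):
        cohort, _, _ = clean_cohort
        model = train_ktsp(cohort, KTSPConfig(n_genes_per_direction=10))
        used = {g for c in model.classes for r in model.classifiers[c].rules for g in r.genes()}
        reduced = cohort.expression.subset_genes(
            [g for g in cohort.expression.gene_ids if g != sorted(used)[0]]
        )
        with pytest.raises(KeyError):
            predict_ktsp(reduced, model)


class TestVariantEquivalences:
    def test_one_vs_one_equals_default_for_two_classes(self):
        rng = np.random.default_rng(17)
        n = 24
        values = pd.DataFrame(
            rng.normal(6, 1, (30, n)),
            index=[f"g{i}" for i in range(30)],
            columns=[f"s{j}" for j in range(n)],
        )
        values.iloc[:5, : n // 2] += 2.0
        values.iloc[5:10, n // 2:] += 2.0
        cohort = _labeled(values, ["A"] * (n // 2) + ["B"] * (n // 2))
        base = KTSPConfig(n_genes_per_direction=5)
        m1 = train_ktsp(cohort, base)
        m2 = train_ktsp(
            cohort,
            replace(base, gene_selection_mode="one_vs_one", rule_scoring_mode="one_vs_one"),
        )
        assert m1.rules_frame().equals(m2.rules_frame())

    def test_platform_wise_equals_default_for_one_platform(self, clean_cohort):
        cohort, _, _ = clean_cohort
        base = KTSPConfig(n_genes_per_direction=10)
        m1 = train_ktsp(cohort, base)
        m2 = train_ktsp(cohort, replace(base, platform_wise=True))
        assert m1.rules_frame().equals(m2.rules_frame())


class TestTiePrevalence:
    def test_binary_problem_odd_k_has_no_ties(self):
        rng = np.random.default_rng(23)
        n = 40
        values = pd.DataFrame(
            rng.normal(6, 1, (40, n)),
            index=[f"g{i}" for i in range(40)],
            columns=[f"s{j}" for j in range(n)],
        )
        values.iloc[:6, : n // 2] += 1.0
        values.iloc[6:12, n // 2:] += 1.0
        cohort = _labeled(values, ["A"] * (n // 2) + ["B"] * (n // 2))
        model = train_ktsp(cohort, KTSPConfig(n_genes_per_direction=10, fixed_k=3))
        pred = predict_ktsp(cohort.expression, model)
        # two complementary voters cannot tie when k is odd and equal
        ka, kb = (model.classifiers[c].k for c in model.classes)
        if ka == kb == 3:
            assert pred.tie.sum() == 0

    def test_tie_rate_declines_with_k(self, default_cohort):
        cohort, _, _ = default_cohort
        table = tie_prevalence_experiment(cohort, [2, 20], reps=2, seed=1)
        rate = dict(zip(table["k"], table["tie_rate"]))
        assert rate[2] > 0
        assert rate[20] <= rate[2]
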