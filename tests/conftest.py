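"""Shared fixtures: small synthetic cohorts reused across test modules."""

import pandas as pd
import pytest

from pairclass import (
    ExpressionMatrix,
    LabeledCohort,
    SyntheticConfig,
    simulate_cohort,
)


@pytest.fixture(scope="session")
def clean_cohort():
    """Pure (purity 1), single-platform, well-separated 5-class cohort."""
    cfg = SyntheticConfig(
        n_genes=300,
        n_informative_per_class=20,
        effect_size=2.0,
        noise_sd=0.5,
        purity_beta=0.0,
        n_samples_per_class_per_platform=20,
        seed=11,
    )
    cohort, truth = simulate_cohort(cfg)
    return cohort, truth, cfg


@pytest.fixture(scope="session")
def noise_free_cohort():
    """Zero noise, purity 1: all samples of a class are identical."""
    cfg = SyntheticConfig(
        n_genes=200,
        n_informative_per_class=16,
        noise_sd=0.0,
        purity_beta=0.0,
        n_samples_per_class_per_platform=6,
        n_classes=3,
        seed=5,
    )
    cohort, truth = simulate_cohort(cfg)
    return cohort, truth, cfg


@pytest.fixture(scope="session")
def two_platform_cohort():
    """Two platforms (RNA-seq-like + compressed array-like), purity 1."""
    cfg = SyntheticConfig(
        n_genes=300,
        n_informative_per_class=20,
        noise_sd=0.5,
        purity_beta=0.0,
        platforms=(("rnaseq", 1.0, 0.0), ("array", 0.7, 0.25)),
        n_samples_per_class_per_platform=15,
        seed=21,
    )
    cohort, truth = simulate_cohort(cfg)
    return cohort, truth, cfg


@pytest.fixture(scope="session")
def default_cohort():
    """5-class cohort at the generator's default (realistically noisy) settings."""
    cfg = SyntheticConfig(
        n_genes=300,
        n_informative_per_class=20,
        n_samples_per_class_per_platform=25,
        seed=17,
    )
    cohort, truth = simulate_cohort(cfg)
    return cohort, truth, cfg


@pytest.fixture()
def tiny_matrix():
    values = pd.DataFrame(
        [[5.0, 2.0], [1.0, 2.0], [3.0, 7.0]],
        index=["GA", "GB", "GC"],
        columns=["s1", "s2"],
    )
    return ExpressionMatrix(values)


def random_labeled_matrix(rng, n_genes=8, n_samples=12, n_classes=3):
    values = pd.DataFrame(
        rng.normal(5, 2, (n_genes, n_samples)),
        index=[f"g{i}" for i in range(n_genes)],
        columns=[f"s{j}" for j in range(n_samples)],
    )
    labels = pd.Series(
        rng.choice([f"c{k}" for k in range(n_classes)], n_samples), index=values.columns
    )
    # guarantee every class appears twice
    for k in range(n_classes):
        labels.iloc[2 * k] = f"c{k}"
        labels.iloc[2 * k + 1] = f"c{k}"
    return LabeledCohort(ExpressionMatrix(values), labels)
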