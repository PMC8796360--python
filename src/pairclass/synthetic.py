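"""Synthetic multi-class, multi-platform, variable-purity expression cohorts.

The generator emulates the structure of real bulk tumor cohorts at the
summarized-matrix level:

* class-specific differentially expressed genes on a log2 baseline,
* a stromal/immune background profile mixed in according to per-sample
  tumor purity (mixing happens on the natural scale — dilution is additive
  in transcript abundance, not in log space),
* per-platform monotone signal distortion modelled as power-law dynamic
  range compression plus a per-gene log-normal offset (the two failure
  modes that break gene-pair rules across platforms: reduced dynamic range
  and expression-ratio crossover loss).

All randomness flows from a single seed through independent per-stage,
per-sample streams, so the same seed reproduces a cohort bitwise and adding
samples does not perturb earlier draws.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .core_data import ExpressionMatrix, LabeledCohort


def _rng(seed: int, stage: int, unit: int = 0) -> np.random.Generator:
    """Independent stream for (seed, stage, unit)."""
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(stage, unit)))


@dataclass(frozen=True)
class SyntheticConfig:
    """Generative parameters for a synthetic labeled cohort.

    Attributes
    ----------
    n_classes, n_genes, n_informative_per_class
        Cohort dimensions; informative gene sets are disjoint across classes
        (half upregulated, half downregulated per class).
    effect_size
        Mean log2-scale shift of informative genes; per-gene effects are
        drawn uniformly in ``[0.5, 1.5] * effect_size`` so that ranking
        genes by fold change is meaningful.
    noise_sd
        Per-gene Gaussian noise (log2 scale) added to both the tumor and the
        background component of each sample.
    platforms
        Tuples ``(name, compression_exponent, offset_sd)``.  The exponent
        compresses (< 1) or expands (> 1) dynamic range on the natural
        scale; ``offset_sd`` is the standard deviation of a per-gene log2
        offset, emulating probe effects.
    purity_alpha, purity_beta
        Beta-distribution parameters for per-sample tumor purity;
        ``purity_beta = 0`` degenerates to purity 1 for every sample, and
        ``purity_fixed`` (if set) overrides the Beta draw with a constant.
    stromal_effect_size, n_stromal_genes, stromal_like_class
        The background profile shifts a designated stromal gene set up/down
        by ``stromal_effect_size``; when ``stromal_like_class`` is set
        (default: the last class), the background additionally mirrors that
        class's informative profile — emulating the real-world confound in
        which highly infiltrated biopsies resemble the mesenchymal-like
        subtype.
    """

    n_classes: int = 5
    n_genes: int = 600
    n_informative_per_class: int = 30
    effect_size: float = 2.0
    noise_sd: float = 1.0
    platforms: tuple = (("rnaseq", 1.0, 0.0),)
    purity_alpha: float = 8.0
    purity_beta: float = 2.0
    purity_fixed: float | None = None
    # the stromal-like class is systematically infiltrated (lower purity),
    # mirroring cohorts where mesenchymal-like tumors are stroma-rich;
    # its purity is drawn from Beta(infiltrated_alpha, infiltrated_beta)
    infiltrated_purity_alpha: float = 3.0
    infiltrated_purity_beta: float = 3.0
    stromal_effect_size: float = 4.0
    n_stromal_genes: int = 40
    # the background is a bulk average over many stromal/immune cells and is
    # therefore far less variable between biopsies than the tumor component;
    # None -> noise_sd / 4
    background_noise_sd: float | None = None
    stromal_like_class: str | None = "auto"
    n_samples_per_class_per_platform: int = 40
    baseline_low: float = 3.0
    baseline_high: float = 10.0
    seed: int = 0
    # offset of the per-sample random streams: cohorts generated with the
    # same seed but different offsets share the gene-level ground truth
    # (baselines, informative sets, platform offsets) while drawing fresh
    # samples — e.g. an independent test cohort from the training model
    sample_seed_offset: int = 0

    def __post_init__(self) -> None:
        if self.n_classes < 2:
            raise ValueError("n_classes must be >= 2")
        if self.n_informative_per_class * self.n_classes + self.n_stromal_genes > self.n_genes:
            raise ValueError("informative + stromal gene sets exceed n_genes")
        for name, kappa, osd in self.platforms:
            if kappa <= 0:
                raise ValueError(f"compression_exponent must be > 0 (platform {name})")
            if osd < 0:
                raise ValueError(f"offset sd must be >= 0 (platform {name})")
        if self.purity_fixed is not None and not 0.0 < self.purity_fixed <= 1.0:
            raise ValueError("purity_fixed must be in (0, 1]")

    @property
    def class_names(self) -> list[str]:
        return [f"C{i + 1}" for i in range(self.n_classes)]


@dataclass
class GroundTruth:
    """Exact record of what the generator did, for recovery tests."""

    informative: dict  # class -> {"up": [genes], "down": [genes]}
    stromal_genes: dict  # {"up": [...], "down": [...]}
    baseline: pd.Series  # per-gene log2 baseline mean
    effects: pd.Series  # per-gene log2 shift magnitude (0 for uninformative)
    class_means: pd.DataFrame  # genes × classes log2 profile
    stromal_profile: pd.Series  # per-gene log2 background profile
    purity: pd.Series  # per-sample tumor purity
    platform: pd.Series  # per-sample platform name
    injected_pairs: list = field(default_factory=list)  # (gene_a, gene_b, target_class)

    def informative_genes(self, cls=None) -> set:
        if cls is not None:
            return set(self.informative[cls]["up"]) | set(self.informative[cls]["down"])
        out: set = set()
        for c in self.informative:
            out |= self.informative_genes(c)
        return out


def simulate_cohort(config: SyntheticConfig) -> tuple[LabeledCohort, GroundTruth]:
    """Generate a labeled cohort plus its exact ground truth.

    The generative model, applied in order: (1) per-gene log2 baselines
    ``b_g ~ U(low, high)``; (2) class profiles ``m_gc = b_g ± e_g`` on each
    class's informative genes; (3) a background (stromal/immune) profile
    ``s_g``; (4) per-sample tumor signal ``t_gi = m_g,label(i) + N(0, sd)``;
    (5) purity mixing on the natural scale,
    ``x_gi = p_i 2^t_gi + (1 - p_i) 2^(s_g + noise)``; (6) per-platform
    distortion ``y = x^kappa * 2^offset_g``; the returned matrix is
    ``log2(y + 1)``.
    """
    cfg = config
    genes = np.array([f"G{i + 1:05d}" for i in range(cfg.n_genes)])
    classes = cfg.class_names

    # stage 0: baselines
    baseline = _rng(cfg.seed, 0).uniform(cfg.baseline_low, cfg.baseline_high, cfg.n_genes)

    # stage 1: informative sets, directions and per-gene effect magnitudes
    rng1 = _rng(cfg.seed, 1)
    order = rng1.permutation(cfg.n_genes)
    effects = np.zeros(cfg.n_genes)
    class_means = np.tile(baseline[:, None], (1, cfg.n_classes))
    informative: dict = {}
    pos = 0
    for ci, cls in enumerate(classes):
        idx = order[pos: pos + cfg.n_informative_per_class]
        pos += cfg.n_informative_per_class
        half = len(idx) // 2
        up, down = idx[:half], idx[half:]
        eff = cfg.effect_size * rng1.uniform(0.5, 1.5, len(idx))
        effects[idx] = eff
        class_means[up, ci] += eff[:half]
        class_means[down, ci] -= eff[half:]
        informative[cls] = {"up": genes[up].tolist(), "down": genes[down].tolist()}

    # stage 2: stromal/immune background profile
    rng2 = _rng(cfg.seed, 2)
    stromal_idx = order[pos: pos + cfg.n_stromal_genes]
    half = len(stromal_idx) // 2
    s_up, s_down = stromal_idx[:half], stromal_idx[half:]
    stromal = baseline.copy()
    stromal[s_up] += cfg.stromal_effect_size * rng2.uniform(0.5, 1.5, len(s_up))
    stromal[s_down] -= cfg.stromal_effect_size * rng2.uniform(0.5, 1.5, len(s_down))
    stromal_genes = {"up": genes[s_up].tolist(), "down": genes[s_down].tolist()}
    like = cfg.stromal_like_class
    if like == "auto":
        like = classes[-1]
    if like is not None:
        ci = classes.index(like)
        mask = class_means[:, ci] != baseline
        stromal[mask] = class_means[mask, ci]

    # samples: class-major, then platform, then replicate — stable ordering
    sample_ids, labels, platform_of = [], [], []
    for cls in classes:
        for pname, _, _ in cfg.platforms:
            for r in range(cfg.n_samples_per_class_per_platform):
                sample_ids.append(f"{cls}_{pname}_{r + 1:03d}")
                labels.append(cls)
                platform_of.append(pname)
    n_samples = len(sample_ids)

    # stage 3: purity (the stromal-like class is drawn infiltrated)
    if cfg.purity_fixed is not None:
        purity = np.full(n_samples, cfg.purity_fixed)
    elif cfg.purity_beta <= 0:
        purity = np.ones(n_samples)
    else:
        rng3 = _rng(cfg.seed, 3, cfg.sample_seed_offset)
        purity = rng3.beta(cfg.purity_alpha, cfg.purity_beta, n_samples)
        if like is not None:
            infiltrated = np.array(labels) == like
            purity[infiltrated] = rng3.beta(
                cfg.infiltrated_purity_alpha, cfg.infiltrated_purity_beta, int(infiltrated.sum())
            )
        purity = np.clip(purity, 1e-3, 1.0)

    # stage 4: per-gene per-platform offsets
    offsets = {}
    for pi, (pname, _, osd) in enumerate(cfg.platforms):
        offsets[pname] = _rng(cfg.seed, 4, pi).normal(0.0, osd, cfg.n_genes) if osd > 0 else np.zeros(cfg.n_genes)
    kappa = {pname: k for pname, k, _ in cfg.platforms}

    # stage 5: per-sample noise + mixing + distortion
    class_index = {c: i for i, c in enumerate(classes)}
    out = np.empty((cfg.n_genes, n_samples))
    bg_sd = cfg.background_noise_sd if cfg.background_noise_sd is not None else cfg.noise_sd / 4.0
    for i, sid in enumerate(sample_ids):
        rng_i = _rng(cfg.seed, 5, cfg.sample_seed_offset + i)
        t = class_means[:, class_index[labels[i]]] + rng_i.normal(0.0, cfg.noise_sd, cfg.n_genes)
        bg = stromal + rng_i.normal(0.0, bg_sd, cfg.n_genes)
        x = purity[i] * np.exp2(t) + (1.0 - purity[i]) * np.exp2(bg)
        pname = platform_of[i]
        y = np.power(x, kappa[pname]) * np.exp2(offsets[pname])
        out[:, i] = np.log2(y + 1.0)

    index = pd.Index(genes, name="gene_id")
    cols = pd.Index(sample_ids, name="sample_id")
    expr = ExpressionMatrix(
        pd.DataFrame(out, index=index, columns=cols),
        platform=pd.Series(platform_of, index=cols),
        dataset=pd.Series([platform_of[i] for i in range(n_samples)], index=cols),
    )
    cohort = LabeledCohort(expr, pd.Series(labels, index=cols, name="class"))
    truth = GroundTruth(
        informative=informative,
        stromal_genes=stromal_genes,
        baseline=pd.Series(baseline, index=index),
        effects=pd.Series(effects, index=index),
        class_means=pd.DataFrame(class_means, index=index, columns=classes),
        stromal_profile=pd.Series(stromal, index=index),
        purity=pd.Series(purity, index=cols),
        platform=pd.Series(platform_of, index=cols),
    )
    return cohort, truth


def inject_platform_specific_pairs(
    cohort: LabeledCohort,
    truth: GroundTruth,
    n_pairs: int,
    *,
    config: SyntheticConfig | None = None,
) -> tuple[LabeledCohort, GroundTruth]:
    """Plant gene pairs that discriminate on platform 1 but are constant elsewhere.

    For each planted pair (A = an up-gene, B = a down-gene of the same
    class), gene B receives a per-platform offset: on the first platform its
    rest-class level is moved midway between A's rest level and A's
    target-class level (so the rule ``A > B`` flips with class membership —
    the informative expression-ratio crossover), while on every other
    platform B is shifted far above A's range so the rule is constant FALSE.
    The affected pairs are recorded in the returned ground truth.
    """
    platforms = pd.unique(truth.platform)
    if len(platforms) < 2:
        raise ValueError("need >= 2 platforms to inject platform-specific pairs")
    if n_pairs == 0:
        return cohort, truth

    used = {g for a, b, _ in truth.injected_pairs for g in (a, b)}
    eligible = []
    classes = list(truth.informative)
    k = 0
    while True:
        added = False
        for cls in classes:
            ups = [g for g in truth.informative[cls]["up"] if g not in used]
            downs = [g for g in truth.informative[cls]["down"] if g not in used]
            if k < len(ups) and k < len(downs):
                eligible.append((ups[k], downs[k], cls))
                added = True
        if not added or len(eligible) >= n_pairs:
            break
        k += 1
    if len(eligible) < n_pairs:
        raise ValueError(f"only {len(eligible)} eligible pairs available, {n_pairs} requested")

    values = cohort.expression.values.copy()
    plat = truth.platform
    main = platforms[0]
    new_pairs = list(truth.injected_pairs)
    for gene_a, gene_b, cls in eligible[:n_pairs]:
        rest = cohort.labels != cls
        on_main = plat == main
        a_rest = values.loc[gene_a, (rest & on_main).to_numpy()].mean()
        a_cls = values.loc[gene_a, (~rest & on_main).to_numpy()].mean()
        b_rest = values.loc[gene_b, (rest & on_main).to_numpy()].mean()
        values.loc[gene_b, on_main.to_numpy()] += (a_rest + a_cls) / 2.0 - b_rest
        for other in platforms[1:]:
            # saturate B on the other platform: no crossover with A and no
            # class signal of its own (probe failure / dynamic-range loss)
            on_other = (plat == other).to_numpy()
            values.loc[gene_b, on_other] = values.loc[gene_a, on_other].max() + 5.0
        new_pairs.append((gene_a, gene_b, cls))

    expr = ExpressionMatrix(values, cohort.expression.platform, cohort.expression.dataset)
    new_truth = replace(truth, injected_pairs=new_pairs)
    return LabeledCohort(expr, cohort.labels), new_truth
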