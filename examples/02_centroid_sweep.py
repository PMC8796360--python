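"""Raw (single-sample) vs centered nearest-centroid classifiers.

Reproduces the characteristic margin behavior: as more genes are added to
the centroids, the raw-data centroid's score separation between the best
and second-best class shrinks (correlations become dominated by shared
baseline expression), while centered centroids keep a stable separation.
"""

from pairclass import SyntheticConfig, centroid_size_sweep, simulate_cohort

config = SyntheticConfig(n_genes=1600, n_informative_per_class=250,
                         n_samples_per_class_per_platform=50, seed=301)
cohort, _ = simulate_cohort(config)

grid = [10, 25, 50, 75, 100, 125]
for mode in ("raw", "centered"):
    table, _ = centroid_size_sweep(cohort, grid, mode=mode)
    print(f"\n{mode} centroids (m = genes per class per direction):")
    print(table.to_string(index=False, float_format=lambda v: f"{v:.3f}"))

print("\nThe mean margin is the top-vs-second correlation difference: "
      "it decays with centroid size in raw mode but not in centered mode.")
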