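"""Multiclass k-TSP: train one-vs-rest voters and examine tied scores.

Each class gets a small set of gene-disjoint rules ("expr(A) > expr(B)");
the class whose voter has the highest fraction of TRUE rules wins.  With
very few rules per class, several voters can reach the same fraction and
the call is ambiguous — forcing a fixed small k makes this visible.
"""

from pairclass import (KTSPConfig, SyntheticConfig, predict_ktsp, simulate_cohort,
                       stratified_split, tie_prevalence_experiment, train_ktsp)

config = SyntheticConfig(n_genes=300, n_informative_per_class=20,
                         n_samples_per_class_per_platform=40, seed=17)
cohort, _ = simulate_cohort(config)
train, test = stratified_split(cohort, 0.8, seed=0)

model = train_ktsp(train, KTSPConfig(n_genes_per_direction=25))
pred = predict_ktsp(test.expression, model)
acc = (pred.predicted == test.labels).mean()
print(f"variance-optimized k per class: {[model.classifiers[c].k for c in model.classes]}")
print(f"test accuracy: {acc:.3f}, ties: {int(pred.tie.sum())}, mean margin {pred.margin.mean():.3f}")
print("\ntop rule per class:")
for cls in model.classes:
    r = model.classifiers[cls].rules[0]
    print(f"  {cls}: {r.label}  (delta={r.delta:.2f})")

ties = tie_prevalence_experiment(cohort, [2, 5, 10, 25, 50], reps=2, seed=1)
print("\ntie rate vs fixed k (ties are prevalent when few rules vote):")
print(ties.to_string(index=False, float_format=lambda v: f"{v:.3f}"))
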