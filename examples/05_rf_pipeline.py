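"""The three-stage rule-based Random Forest pipeline, end to end.

Stage 1 selects genes by forest importance on within-sample ranked data;
stage 2 ranks all pairwise rules of the gene union the same way; stage 3
diversifies (one rule per gene per ranking) and trains a probability
forest.  Out-of-bag (OOB) scores estimate generalization without a test
set, the OOB proximity matrix exposes reference-label cohesion, and Boruta
pruning discards rules that never beat their own permuted shadows.
"""

import numpy as np

from pairclass import (RFConfig, SyntheticConfig, boruta_prune, extract_proximity,
                       predict_rf, simulate_cohort, stratified_split, train_rf_rules)

config = SyntheticConfig(n_genes=300, n_informative_per_class=20,
                         n_samples_per_class_per_platform=40, seed=31)
cohort, truth = simulate_cohort(config)
train, test = stratified_split(cohort, 0.8, seed=0)

rf_config = RFConfig(genes_per_model=10, rules_per_model=10,
                     n_trees_selection=150, n_trees_final=400, seed=2)
model = train_rf_rules(train, rf_config)
print(f"gene union: {len(model.gene_union)} genes "
      f"({len(set(model.gene_union) & truth.informative_genes())} ground-truth informative)")
print(f"final rules: {len(model.rules)}; OOB accuracy: {model.oob_accuracy:.3f}")

pred = predict_rf(test.expression, model)
print(f"held-out accuracy: {(pred.predicted == test.labels).mean():.3f}, "
      f"ties: {int(pred.tie.sum())}")

prox = extract_proximity(model).to_numpy()
labels = train.labels.to_numpy()
same = labels[:, None] == labels[None, :]
off = ~np.eye(len(labels), dtype=bool)
print(f"OOB proximity: within-class {np.nanmean(prox[same & off]):.2f} "
      f"vs between-class {np.nanmean(prox[~same]):.2f} "
      "(higher within-class = cohesive reference labels)")

result, pruned = boruta_prune(model, n_trees=150, max_iter=25)
counts = {k: int(v) for k, v in result.counts().items()}
print(f"Boruta: {counts}; pruned model OOB accuracy {pruned.oob_accuracy:.3f}")
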