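"""Train the MLKNN ensemble on a planted synthetic corpus and evaluate it.

Simulates a 200-drug corpus in which the probability that a drug truly
treats a disease rises with its druggability-weighted targeting of that
disease's genes, tunes the four feature weights by internal 5-fold
cross-validated AUPR, and reports ranking metrics for the out-of-fold
ensemble predictions.
"""

import numpy as np

from genedrug import ensemble as ens
from genedrug.druggability import score_all
from genedrug.features import build_feature_matrices
from genedrug.metrics import multilabel_metrics, pr_curve_aupr
from genedrug.synthetic_data import SimulationConfig, generate

ds, truth = generate(SimulationConfig(seed=1))
print(f"corpus: {ds.n} drugs x {ds.q} diseases, {len(truth)} eligible pairs, "
      f"{truth.indicated.sum()} indicated")

mats = build_feature_matrices(ds, score_all(ds))
Y, mask = ens.label_matrix(ds), ens.eligible_mask(ds)
model = ens.tune_weights(mats, Y, mask, k=10, s=1.0, grid_step=0.1, seed=1)

names = ["f1 score-sum", "f2 norm-avg", "f3 ohnolog-count", "f4 ohnolog-ratio"]
print("\ntuned simplex weights (internal 5-CV AUPR as fitness):")
for name, w in zip(names, model.weights):
    print(f"  {name:18s} {w:.2f}")
print(f"internal 5-CV AUPR = {model.fitness:.4f} "
      f"(prevalence over eligible pairs = {Y[mask].mean():.4f})")

rows = ens.predict(model, ds, threshold=0.5, feature_matrices=mats)
n_called = sum(1 for *_, call in rows if call)
print(f"\n{len(rows)} eligible pairs scored; {n_called} called at threshold 0.5")
print("top 5 predictions (drug, disease, score, cross-fold sd):")
for drug, disease, score, sd, _ in rows[:5]:
    print(f"  {drug} {disease}  {score:.3f} +/- {sd:.3f}")

mean, _ = model.score_matrices(mats)
ml = multilabel_metrics(np.where(mask, mean, 0.0), Y)
print("\nmulti-label metrics on the training corpus:")
for key, value in ml.items():
    print(f"  {key:18s} {value:.4f}")
# an AUPR several-fold above prevalence shows the ensemble has recovered
# the planted genetics-activity relationship rather than the base rate
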