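"""Train the RBF network on a synthetic cohort and evaluate the training set.

Builds the six classifier inputs per limb (GSV SV/FFV/ASV/MF plus the
GSV/PV ratios of SD and MF), standardizes them, trains the network with 16
k-means hidden units and NLMS output weights, and scores all 41 limbs with
the 0.5 decision threshold.
"""

from veinflow import (build_features, confusion, feature_matrix, fit,
                      fit_standardizer, metrics)
from veinflow.qflow import batch_qflow
from veinflow.simulate import CohortConfig, generate_cohort

cohort = generate_cohort(CohortConfig(), seed=1)
qflow = batch_qflow(cohort)
feats, _ = build_features(qflow, cohort.labels())
X, d = feature_matrix(feats)
Z = fit_standardizer(X).transform(X)

model = fit(Z, d, k=16, seed=1, threshold=0.5)
pred = model.classify(Z)
cm = confusion(d, pred)
rep = metrics(cm)

print(f"confusion: TP {cm.tp}  FN {cm.fn}  TN {cm.tn}  FP {cm.fp}")
print(f"sensitivity {rep.sensitivity:.2f}%  precision {rep.precision:.2f}%  "
      f"accuracy {rep.accuracy:.2f}%  F-measure {rep.f_measure:.2f}%")
print("Sensitivity is the fraction of reflux limbs caught; precision the "
      "fraction of reflux calls that are correct, on the 41 training limbs.")
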