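"""Predict each cell's fate from its initial protein levels (ROC analysis).

After simulating a heterogeneous population, every cell's apoptotic fate is
known; the 19 candidate predictors are the 16 sampled initial
concentrations plus [XIAP]/[PARP], [PARP]/[XIAP] and |[PARP]-[XIAP]|.
Single-feature AUCs quantify how well each one anticipates the fate before
TSP1 is even added.
"""

import numpy as np

from tsp1apop import (
    Protocol,
    assemble_network,
    build_feature_table,
    rank_predictors,
    run_population,
)

model = assemble_network()
pop = run_population(
    model,
    Protocol(tsp1_dose=0.01, horizon=1440.0,
             output_times=tuple(np.arange(0.0, 1441.0, 120.0))),
    n=250, seed=3,
)
table = build_feature_table(pop)
ranking = rank_predictors(table, method="hanley")

print("predictor       AUC    95% CI           direction")
for _, r in ranking.head(8).iterrows():
    direction = "high -> apoptotic" if r.orientation > 0 else "low -> apoptotic"
    print(f"{r.predictor:14s} {r.auc:5.2f}  [{r.ci_lo:.2f}, {r.ci_hi:.2f}]  {direction}")

print()
print("|PARP-XIAP| and PARP alone are strong predictors; XIAP predicts with")
print("low values; the receptor levels carry no information (AUC ~ 0.5).")
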