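"""Recover kinetic parameters from synthetic fold-change time courses.

Generates noisy training data (multiplicative lognormal noise, CV 0.1) from
the bundled model, perturbs two rate constants, and runs the step-wise
eFAST-screen + multi-start trust-region fit until the training curves are
matched again.  The printed factors compare recovered values with truth.
"""

from tsp1apop import assemble_network, stepwise_pipeline
from tsp1apop.estimation import wssr
from tsp1apop.synthetic import SyntheticSpec, generate_training_dataset

model = assemble_network()
grids = (
    ("complex", (0.0, 5.0, 10.0, 20.0, 30.0)),
    ("pp59", (0.0, 5.0, 10.0, 20.0, 30.0)),
    ("pp38", (0.0, 10.0, 20.0, 40.0, 60.0)),
)
dataset = generate_training_dataset(
    model, SyntheticSpec(cv=0.1, grids=grids, seed=4)
)
noise_floor = wssr(model, {}, dataset)

start = model.copy()
start.set_parameter("k_phos_fyn", model.parameters["k_phos_fyn"] * 5)
start.set_parameter("k_deg_pFyn", model.parameters["k_deg_pFyn"] * 0.3)

result = stepwise_pipeline(
    start, dataset,
    candidate_params=["k_phos_fyn", "k_deg_pFyn", "kon_dephos_fyn"],
    n_iterations=2, n_starts=6, seed=0, ensemble_size=4,
    efast_samples=65, efast_resamples=3,
)

print(f"final WSSR {result.wssr:.2f}  (noise floor {noise_floor:.2f})")
print("parameter     truth      recovered   factor")
for name, value in result.best.items():
    truth = model.parameters[name]
    print(f"{name:12s}  {truth:9.3g}  {value:9.3g}  {value / truth:6.2f}")
print()
print("The strongly identifiable rates (p59fyn activation and turnover)")
print("return to within a small factor of truth; weakly identifiable ones")
print("can drift along sloppy directions without hurting the fit. A WSSR")
print("near the noise floor means the fit explains everything the noise")
print("allows.")
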