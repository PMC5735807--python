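"""Simulate a heterogeneous population and classify apoptotic cells.

Each cell draws its 16 nonzero initial protein concentrations from gamma
distributions (shape 5.5, mean = baseline), then the full 53-species model
is solved per cell.  A cell is apoptotic when cPARP at 24 h reaches the
1.05 uM threshold.  Run with n=2000 for full-scale results; n=200 here
keeps the example fast.
"""

import numpy as np

from tsp1apop import Protocol, assemble_network, population_summary, run_population

model = assemble_network()
pop = run_population(
    model,
    Protocol(tsp1_dose=0.01, horizon=1440.0,
             output_times=tuple(np.arange(0.0, 1441.0, 120.0))),
    n=200, seed=1,
)

print(f"apoptotic at 24 h: {100 * pop.apoptotic_fraction:.1f}% of {pop.n_cells} cells")
tt = pop.t_threshold[np.isfinite(pop.t_threshold)]
print(f"median time to threshold: {np.median(tt) / 60:.1f} h")
print(f"median peak cPARP: {np.median(pop.max_cparp):.2f} uM")

summary = population_summary(pop)
print("\napoptotic fraction over time:")
for _, row in summary["fractions"].iterrows():
    bar = "#" * int(40 * row.apoptotic_fraction)
    print(f"  {row.time_min / 60:5.0f} h  {100 * row.apoptotic_fraction:5.1f}%  {bar}")

print("\nThe fraction grows through the day as slower cells cross the")
print("threshold; cell-to-cell timing differences come entirely from the")
print("sampled protein levels (extrinsic noise).")
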