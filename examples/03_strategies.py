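"""Compare intervention strategies on the population response.

The seven built-in perturbations mimic candidate ways to sensitize
endothelial cells to TSP1: XIAP knock-down, low-dose doxorubicin (DXR),
phosphatase inhibition (Ptase), a pan-kinase promoter (Kp), procaspase-3 or
Fas upregulation, and faster nuclear translocation (Ktrsp).  n=150 per
condition for speed (the full analysis uses 2000).
"""

import numpy as np

from tsp1apop import (
    BUILTIN_SPECS,
    Protocol,
    apply_perturbation,
    assemble_network,
    run_population,
)

model = assemble_network()
protocol = Protocol(tsp1_dose=0.01, horizon=1440.0,
                    output_times=tuple(np.arange(0.0, 1441.0, 120.0)))

print("strategy   apoptotic%   median T_t (h)")
for name in ("baseline", "XIAP", "DXR", "Ptase", "Kp", "pro3", "Fas", "Ktrsp"):
    edited = (model if name == "baseline"
              else apply_perturbation(model, BUILTIN_SPECS[name]))
    pop = run_population(edited, protocol, n=150, seed=11)
    tt = pop.t_threshold[np.isfinite(pop.t_threshold)]
    print(f"{name:9s}  {100 * pop.apoptotic_fraction:9.1f}   "
          f"{np.median(tt) / 60 if tt.size else float('nan'):13.1f}")

print()
print("XIAP knock-down is the most effective enhancer; faster nuclear")
print("translocation paradoxically weakens the response by draining the")
print("cytosolic pp38 pool that feeds caspase-8 activation.")
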