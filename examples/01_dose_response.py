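"""Simulate one average cell at several TSP1 doses and print the cPARP response.

cPARP (cleaved PARP) is the model's apoptosis readout: TSP1 binding to CD36
triggers the caspase cascade, caspase-3 cleaves PARP, and the cell counts as
apoptotic once cPARP reaches 1.05 uM at 24 h.  The response saturates at
sub-nanomolar TSP1, so the four doses differ only slightly.
"""

import numpy as np

from tsp1apop import Protocol, assemble_network, simulate

model = assemble_network()

print("dose (nM)   cPARP at 24 h (uM)   time to half-final (h)")
for dose_nM in (0.1, 1.0, 10.0, 100.0):
    traj = simulate(
        model, Protocol(tsp1_dose=dose_nM * 1e-3, horizon=1440.0)
    )
    cp = traj["cPARP"]
    t_half = traj.times[np.searchsorted(cp, 0.5 * cp[-1])] / 60.0
    print(f"{dose_nM:8.1f}   {cp[-1]:18.3f}   {t_half:20.1f}")

print()
print("The 24-h cPARP level is nearly dose-independent (receptor-level")
print("saturation); what changes with stimulation strength is timing.")
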