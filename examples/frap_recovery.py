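"""In-silico FRAP of droplets with partially immobilized molecules.

Seven droplets sit in a 20 x 8 um periodic box at 100-fold enrichment;
0.5-um-radius regions centered in a large, a medium and a small droplet are
bleached, and the unbleached fraction re-entering each region is recorded.
With 90% of condensed molecules permanently immobilized the recovery
plateaus near the 10% mobile ratio regardless of droplet size.
"""

import numpy as np

import phasetrack as pt

cfg = pt.FrapConfig(
    mobile_ratio=0.1,
    confined_lifetime=np.inf,      # permanently immobilized confined state
    ef=100.0, D_d=1.0, D_m=0.1,
    dt=5e-4, n_molecules=10_000, T=30.0, seed=5,
)
res = pt.simulate_frap(cfg)
labels = ["large droplet (r=2 um)", "medium droplet (r=1 um)",
          "small droplet (r=0.5 um)"]
for name, plateau in zip(labels, res.plateau(window=5.0)):
    print(f"ROI in {name}: recovery plateau {plateau:.1f} %")
print("Only the mobile 10% exchanges with the unbleached pool, so recovery")
print("saturates at the mobile ratio - a FRAP plateau measures confinement,")
print("not viscosity.")
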