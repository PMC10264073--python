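"""Steady-state enrichment of a two-phase box versus the kinetic relation.

Molecules diffuse in a periodic box containing stationary condensed
droplets; inside a droplet they switch between a stationary confined state
and a mobile state (D_m), outside they diffuse freely (D_d).  The kinetic
relation predicts the equilibrium enrichment fold EF = D_d / (eta * D_m).
"""

import phasetrack as pt
from phasetrack.pipeline import default_suite_droplets

world = pt.SimWorld(
    geometry=default_suite_droplets(),
    D_d=0.6, D_m=0.2,            # um^2/s, dilute and condensed-mobile
    mobile_ratio=0.05,           # 5% of condensed molecules mobile
    mobile_lifetime=0.1,         # s
    dt=5e-4, n_molecules=5000, T=30.0, seed=1,
)

trace, _ = pt.simulate_equilibrium(world, init="enriched")
ef = pt.steady_state_EF(trace, window=10.0)

print(f"kinetic prediction  EF = {world.ef_theory():.1f}")
print(f"simulated steady state EF = {ef:.1f}  (mean over the last 10 s)")
print("A molecule leaves the condensed phase only while mobile, so a 5%")
print("mobile ratio at a 3x slower mobile D sustains a ~60-fold enrichment.")
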