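"""Model-free classification of condensed-phase steps into L and H states.

Scans the demarcation d_b that minimizes the overlap (OVL) between the two
conditional next-step distributions P(d_{i+1} | d_i < d_b) and
P(d_{i+1} | d_i > d_b); for simple diffusion the conditionals coincide, so
a clear interior OVL minimum is direct evidence of two motion states.
"""

import phasetrack as pt
from phasetrack.geometry import CONDENSED

acq = pt.AcquisitionParams(frame_interval=0.03)
rates = pt.SwitchRates(P_cm=0.09, P_mc=0.59)       # per frame
gt, _ = pt.simulate_two_state(400, 60, D_m=0.044, rates=rates,
                              psf_scatter=0.0136, acquisition=acq, seed=21)
tracks = pt.TrackSet(gt.tracks, acq)
for tr in tracks:
    tr.phase[:] = CONDENSED

scan = pt.scan_demarcation(tracks)
print(f"OVL minimum at d_b* = {scan.d_b_star * 1000:.0f} nm (flat: {scan.flat})")

res = pt.classify_steps(tracks, scan.d_b_star)
fits = pt.fit_components(res, acq.frame_interval)
print(f"confinement ratio P_c = {res.P_c:.3f}, mobile ratio P_m = {res.P_m:.3f}")
print(f"switching: P_cm = {res.P_cm:.2f}/frame, P_mc = {res.P_mc:.2f}/frame")
print(f"L-component scale s = {fits['s_L_nm']:.1f} nm (detection-error form)")
print(f"H-component D = {fits['D_H']:.3f} um^2/s (truncation-aware fit)")
print("L steps are localization jitter around a bound position; H steps are")
print("genuine mobile diffusion between trapping events.")
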