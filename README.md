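# phasetrack

Single-molecule tracking and motion-state analysis for biomolecular
condensates, with Monte Carlo simulators for validation.

Localization microscopy of a phase-separated system (a membraneless
condensate on a supported bilayer, say) produces per-frame point detections
at wildly different densities and mobilities in the condensed and dilute
phases, which breaks single-gate track linking and single-state diffusion
fits.  `phasetrack` provides the full analysis path for such data, for
researchers quantifying condensate dynamics from SMLM/dSTORM localization
tables:

* **Phase segmentation** from local localization densities, with the
  enrichment fold (partition coefficient) `EF = sigma_c / sigma_d`.
* **Adaptive two-pass track linking.**  The total link error at
  dimensionless search range `X = R / sqrt(4 D t)` is
  `E(X) = exp(-X^2) + 2 c X` (missed links plus spurious links,
  `c ∝ sigma D t`); its admissible minimum solves `X e^{-X^2} = c` and stays
  near `X = 2.5` across realistic conditions, so the tracker links once with
  a default 500-nm gate, estimates per-phase diffusivities, and relinks with
  per-phase gates `R = 2.5 sqrt(4 D t)`.
* **Two-state motion analysis** in the condensed phase: a hidden Markov
  model with Brownian displacement-magnitude emissions (state diffusivities
  `D_c <= D_m`, per-frame switching `P_cm`, `P_mc`, confinement ratio
  `P_c = P_mc/(P_mc + P_cm)`), plus a model-free classifier that splits
  steps into low/high-mobility states at the demarcation minimizing the
  overlap coefficient of the two conditional next-step distributions.
* **The kinetic-equilibrium bridge** `EF = D_d / (P_m D_m)`: motion
  statistics predict the equilibrium enrichment, cross-validated against the
  enrichment measured directly from localization densities.
* **Monte Carlo engines**: ground-truth localization scenes for tracker
  benchmarking, a two-phase equilibrium simulator (periodic box, stationary
  condensed regions, start-side-D step rule), and an in-silico FRAP
  experiment.

## A worked example

```bash
python examples/equilibrium_enrichment.py
```

```
kinetic prediction  EF = 60.0
simulated steady state EF = 61.9  (mean over the last 10 s)
A molecule leaves the condensed phase only while mobile, so a 5%
mobile ratio at a 3x slower mobile D sustains a ~60-fold enrichment.
```

Five thousand molecules diffuse in a periodic 15 x 30 um box containing
eight droplets; in the condensed phase only 5% of molecules are mobile
(D = 0.2 um^2/s, mobile lifetime 0.1 s) while the dilute phase diffuses at
0.6 um^2/s.  The measured steady-state density ratio matches the kinetic
prediction `D_d / (eta D_m) = 60`: enrichment is sustained dynamically by
the mobility contrast.

The other example scripts each exercise one capability end to end:
`track_and_fit.py` (segmentation -> adaptive linking -> HMM -> the EF
cross-check), `classify_motion_states.py` (model-free L/H classification),
`frap_recovery.py` (recovery plateau = mobile ratio when confined molecules
never exchange), `optimal_search_range.py` (analytic and ground-truth-
benchmarked optimal gate).

A thin CLI mirrors the library (`phasetrack simulate|segment|track|fit|
classify|frap|pipeline|suite`); run `phasetrack --help`.

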