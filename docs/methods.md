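# Models and methods

This note records the models implemented in `phasetrack`, the parameter
choices that matter, what the synthetic-data generators do and do not
emulate, and the numerical decisions taken where the design was open.

## The physical picture

A molecule in a two-phase (condensed/dilute) system on a surface is modelled
by three simple diffusion processes: free diffusion in the dilute phase
(coefficient `D_d`), and a two-state process inside condensed regions that
alternates between a *mobile* state (coefficient `D_m`) and a *confined*
state bound to the condensed-phase molecular network (coefficient `D_c`,
zero by default — confined molecules are stationary and their apparent
motion in data is localization jitter).  Per-frame switching probabilities
`P_mc` (mobile to confined) and `P_cm` (confined to mobile) give the
stationary confinement and mobile ratios

    P_c = P_mc / (P_mc + P_cm),      P_m = 1 - P_c,

and mean dwell times `t_c = t/P_cm`, `t_m = t/P_mc` for frame interval `t`.

Because a molecule can cross the phase boundary only while mobile, flux
balance ties the kinetics to the equilibrium enrichment fold (the partition
coefficient, the ratio of molecular densities):

    EF = sigma_c / sigma_d = D_d / (P_m * D_m),

with the multi-state generalization that the density-weighted sum of
diffusion coefficients over states is equal across coexisting phases
(`flux_balance_check`).  The relation assumes no significant energy barrier
at the interface and near-symmetric attractive/repulsive fluctuations for
the mobile state.

## Equilibrium Monte Carlo engine

Molecules take Gaussian steps with per-axis standard deviation
`sqrt(2 D dt)`.  When a step starts in one phase and ends in the other, the
diffusion coefficient of the *starting* region applies to the whole step —
the Ito convention for state-dependent noise.  Its stationary density obeys
`D(x) p(x) = const`, which is exactly what makes the steady state follow
`EF = D_d/(P_m D_m)` rather than a `sqrt(D)` ratio; implementing a different
interface rule (reflection, interpolation) would change the equilibrium, so
the start-side rule is load-bearing, not an approximation detail.

State switching is evaluated once per integration step with probabilities
`P_mc = dt/t_m` and `P_cm` from detailed balance
`eta P_mc = (1-eta) P_cm`, where `eta` is the condensed-phase mobile ratio.
Only condensed-phase molecules can be confined.  Boundaries are periodic;
condensed-region geometry is rasterized (default cell 0.01 um) and the same
raster is used both for the per-step phase lookup and for the area terms of
the measured EF, so the discretization cancels from the density ratio.

Numerical notes:

* Step normals are drawn in float32 (the ~1e-7 relative step error is far
  below the Monte Carlo noise floor); draws are chunked in a fixed order, so
  a fixed seed reproduces the trajectory bit-for-bit.  An optional numba
  kernel accelerates the inner loop; the pure-numpy path computes the same
  update (verified by identical traces under a common seed).
* Finite `dt` leaves a boundary layer roughly one step wide at each phase
  boundary, producing percent-level deviations of the steady-state EF from
  the continuum relation.  The default validation geometry (a 2 x 4 grid of
  0.9-um droplets in a 15 x 30 um box, ~4.5% condensed area) keeps droplets
  large relative to the step length and well separated, so the deviation
  stays within a few percent at the documented reduced scale.
* Initialisation is either homogeneous ("uniform") or pre-partitioned at a
  chosen enrichment ("enriched", default: the kinetic prediction).  The
  steady state does not depend on the initialisation; the enriched start is
  used for reduced-duration runs because the slowest relaxation mode (global
  exchange between droplets and the dilute pool, time scale
  `r^2 / (4 eta D_m)`) can exceed a shortened run.  A homogeneous start is
  used when the monotone approach to the plateau is itself the property
  under test.

**Problem sizes.**  Validation runs use 5,000 molecules, `dt = 5e-4` s and
`T = 30` s averaged over 5 seeds (mean EF over the final 10 s); FRAP runs
use 10,000 molecules.  These sizes were chosen so the Monte Carlo error of
a seed-averaged EF stays near one percent while a full validation sweep
completes in minutes.

## FRAP simulation

The FRAP engine reuses the equilibrium stepper in a 20 x 8 um periodic box
containing seven droplets (radii 0.5/1/1/2/1/1/0.5 um at
x = 1/3/5/10/15/17/19 um, mid-height).  After pre-equilibration at the
configured enrichment, every molecule inside each 0.5-um-radius bleach
region is flagged bleached and the unbleached count in each region is
recorded, normalized to pre-bleach = 100% and post-bleach = 0%.  Confined
molecules may have a finite confined lifetime or be permanently immobile
(`confined_lifetime = inf`), in which case the recovery plateau equals the
mobile ratio — a FRAP plateau reports confinement, not viscosity.

## Synthetic localization generators

`simulate_homogeneous` emulates a sparse-labelling SMLM movie: track count
`density * area * n_frames / mean_lifetime`, Poisson lifetimes (mean 3.5
frames, floored at one frame — zero-length emitters are not observable),
uniform start frames, Brownian frame steps.  Sub-stepping at 0.1 ms would
sum to the identical Gaussian frame increment, so the frame step is drawn
directly.

`simulate_two_state` adds per-frame Markov switching; confined frames emit
localizations scattered Gaussian(`psf_scatter`, default 13.6 nm) around the
anchor position where the molecule was caught.  The anchored jitter is what
produces the subdiffusive ensemble MSD and the consecutive-step correlation
the classifier exploits; `simulate_hmm_tracks` instead draws both states as
Brownian (the HMM's own generative model) for estimator-recovery tests.

`simulate_condensate_scene` composes the two in a two-phase scene with birth
densities honouring a target enrichment.  The box behaves as a camera field
of view: molecules are born in a margin-extended region and emit only while
inside the box, so the in-box density stays uniform and no displacement is
kinematically distorted at an edge.  Features of real data *not* emulated:
per-molecule photophysics (re-blinking of the same fluorophore), detection
failures, spatially varying localization precision, and moving phase
boundaries.  Passing tests therefore demonstrate estimator correctness under
the stated model, not robustness to all experimental artifacts.

## Adaptive tracking

Total link error at dimensionless search range `X = R / sqrt(4 D t)` is
`exp(-X^2) + 2 c X`; the composite false-positive coefficient is exposed as
a single constant (default `c = pi sigma D t`) because only the product
matters and the admissible optimum `X*` (root of `X exp(-X^2) = c` on the
branch `X > 1/sqrt(2)`) varies weakly — about 2.5-3.0 — across realistic
conditions.  A fixed `X = 2.5` is the operational default.

The two-pass scheme links once with a 500-nm global gate, splits pass-1
displacements by phase, and sizes each phase's gate from a *gate-sizing*
diffusion estimate.  This estimate is the fastest component of a mixture of
Brownian displacement populations plus a fixed-shape clutter component
(`2 d / R^2` on `[0, R]`, the distance law of a spurious link accepted
within gate `R`), floored at the pooled moment estimate.  The mixture is
essential in a confined-dominated phase: the pooled estimator is dominated
by localization jitter and would strangle the mobile state, while the raw
fast component would be inflated by spurious pass-1 links.  Assignment is
optimal-bipartite (minimum summed distance over gated pairs) by default,
with greedy-nearest retained for speed comparisons; cross-phase candidate
pairs use the larger of the two phase gates so exchange events are not
truncated.  No gap closing by default.

## Two-state HMM

Baum-Welch EM over pooled tracks; the emission for state `i` is the 2D
Brownian displacement-magnitude density with scale `4 D_i t` (an optional
static localization-error term can widen it, off by default because the
confined-state `D_c` already absorbs detection error).  Each track's forward
pass starts from a shared initial distribution, initialized at the
stationary distribution of the transition matrix and then refined as a free
EM parameter so the pooled log-likelihood is provably non-decreasing (the
fitter raises if it ever decreases).  Initialization splits the displacement
histogram at its antimode; convergence at relative log-likelihood change
below 1e-8 or 10,000 iterations.  States are relabelled so `D_c <= D_m`.

When fitting *linked* (rather than ground-truth) tracks, an optional third
hidden state with the fixed clutter emission above absorbs spurious
gate-limited links, which otherwise inflate the small mobile population; the
reported model is the diffusive block with transitions renormalized over
diffusive destinations.  The pipeline enables this with the condensed-phase
gate; `hmm_fit` alone defaults to the pure two-state model.

## MSD analytics

Time-averaged MSD over overlapping windows (non-overlapping available);
linear fits return `D = slope/4`, anomalous fits `(D_alpha, alpha)` by
log-log regression (exact on noiseless power-law curves).  With
blinking-limited track lifetimes only the first few lags have support, so
the pipeline fits only lags backed by at least 5% of the lag-1 pair count.
Dilute-phase analysis defaults to the linear model; condensed-phase MSD of
anchored two-state motion is subdiffusive (`alpha < 1`) because confined
jitter anti-correlates consecutive steps.

## Correlation-based L/H classification

Eligible tracks lie entirely in the condensed phase with at least 10 steps.
For a demarcation `d_b`, the two conditional next-step distributions (given
the previous step below/above `d_b`) are compared by the overlap coefficient
`OVL = integral of min(P, Q)`; simple diffusion makes the conditionals equal
(OVL near 1), two-state motion produces an interior OVL minimum at the
scale separating the states.  Histograms use 5-nm bins and the scan covers
10-200 nm in 10-nm steps by default.  The raw OVL estimator is biased low
when either conditional has few samples, which would fake minima at extreme
demarcations; the scan therefore adds the analytic expected shortfall under
the equal-distribution null (`0.5 sqrt(2/pi) sqrt(1/n1 + 1/n2) sum_k
sqrt(p_k w)`) and excludes demarcations leaving fewer than 100 pairs on a
side.  A corrected curve with range below 0.02 is reported as flat (no
two-state structure).

Steps are labelled L (`d < d_b`) or H otherwise; `P_c`, `P_m` come from the
label counts and per-frame switching frequencies from the label transition
counts.  Component fits account for the truncation at `d_b`: the L component
uses the detection-error form with per-axis scale `s` (`s^2 = D_L t`), the H
component a truncated 2D Brownian MLE; a one-sided Levy fit with AIC
comparison is available as a heavy-tail diagnostic only.  Label-based
switching frequencies match the underlying state process only when the two
state scales are well separated relative to `d_b`; at marginal separation
the label process systematically differs (documented, and expected — the
HMM and the classifier disagree on marginal data by construction).

## Known limitations

* The kinetic relation is approximate; the equilibrium engine reproduces it
  to a few percent at finite `dt`, with the residual set by the
  boundary-layer artifact of the start-side step rule.
* Spurious track links at blinking-limited track ends are irreducible at
  realistic densities (~1-2% of links at 0.3 molecules/um^2/frame); the
  clutter-state HMM removes most, but single-replicate kinetic-EF estimates
  still scatter by ~15% when the mobile ratio is a few percent.  Replicate
  averaging is the intended use.
* Tracking is 2D, no gap closing, no drift correction, no
  motion-model-aware probabilistic linking.
* The classifier's switching frequencies are label statistics, not hidden-
  state estimates.
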