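"""Displacement-distribution and MSD analytics, the two-state HMM, and the
kinetic <-> equilibrium enrichment relations.

The central objects are the 2D Brownian displacement-magnitude density

    p(d) = (d / (2 D t)) * exp(-d^2 / (4 D t)),

a Rayleigh density with E[d^2] = 4 D t, and the two-state hidden Markov
model whose emissions are this density with state-specific D.  The model's
stationary confinement and mobile ratios follow from the per-frame switching
probabilities as P_c = P_mc / (P_mc + P_cm), P_m = 1 - P_c, and the kinetic
relation EF = D_d / (P_m * D_m) links them to the equilibrium enrichment
fold of the condensed phase.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import optimize

from .io import TrackSet

DEFAULT_BIN_NM = 5.0


# ---------------------------------------------------------------------------
# displacement pooling and single-population fits


def displacement_magnitudes(tracks: TrackSet, phase: Optional[str] = None,
                            bin_nm: float = DEFAULT_BIN_NM):
    """Pooled consecutive-frame step magnitudes (um) plus a histogram with
    ``bin_nm``-nanometre bins.  ``phase`` filters steps by their phase label.
    Returns (sorted displacements, (bin_edges_um, counts))."""
    d = np.sort(tracks.displacements(phase=phase))
    if d.size == 0:
        raise ValueError("no displacements match the requested filter")
    w = bin_nm / 1000.0
    edges = np.arange(0.0, d[-1] + 2 * w, w)
    counts, _ = np.histogram(d, bins=edges)
    return d, (edges, counts)


def rayleigh_moment_D(displacements: np.ndarray, t: float) -> float:
    """Closed-form moment estimator D = sum(d^2) / (4 n t)."""
    d = np.asarray(displacements, dtype=float)
    if d.size == 0:
        raise ValueError("no displacements")
    return float(np.sum(d**2) / (4.0 * d.size * t))


def truncated_rayleigh_mle(d: np.ndarray, lower: float = 0.0,
                           upper: float = np.inf) -> float:
    """MLE of the Rayleigh scale parameter sigma^2 for samples truncated to
    (lower, upper); sigma^2 = E[d^2]/2 of the untruncated law.

    Lower truncation alone has a closed form; otherwise the 1D likelihood
    equation is solved numerically.
    """
    d = np.asarray(d, dtype=float)
    n = d.size
    s2_hat = np.mean(d**2) / 2.0
    if not np.isfinite(upper):
        return float(s2_hat - lower**2 / 2.0)

    def dll(s2):
        # d/d(s2) of the truncated log-likelihood
        ea = np.exp(-lower**2 / (2 * s2)) if lower > 0 else 1.0
        eb = np.exp(-upper**2 / (2 * s2))
        z = ea - eb
        dz = (lower**2 / (2 * s2**2)) * ea - (upper**2 / (2 * s2**2)) * eb
        return -n / s2 + np.sum(d**2) / (2 * s2**2) - n * dz / max(z, 1e-300)

    lo, hi = 1e-10, max(s2_hat * 10, 1e-6)
    for _ in range(60):
        if dll(lo) > 0 > dll(hi):
            break
        hi *= 2
    return float(optimize.brentq(dll, lo, hi))


def rough_D(displacements, t: float, min_n: int = 50,
            gate: Optional[float] = None) -> float:
    """Quick diffusion-coefficient estimate from a displacement pool (the
    maximum-likelihood fit of the 2D Brownian magnitude density).  When the
    pool comes from gated linking, passing ``gate`` corrects for the upper
    truncation of the step distribution."""
    d = np.asarray(displacements, dtype=float)
    if d.size < min_n:
        raise ValueError(f"need at least {min_n} displacements, got {d.size}")
    if gate is not None and np.any(d > 0):
        return truncated_rayleigh_mle(d[d > 0], upper=gate) / (2.0 * t)
    return rayleigh_moment_D(d, t)


def rayleigh_mixture(displacements, t: float, n_components: int = 2,
                     clutter_max: Optional[float] = None,
                     max_iter: int = 500, tol: float = 1e-10):
    """EM fit of a mixture of 2D Brownian magnitude densities, optionally
    with a fixed-shape clutter component.

    The clutter component models spurious links to unrelated molecules: the
    distance from a localization to a uniformly placed neighbor accepted
    within a gate R has density f(d) = 2 d / R^2 on [0, R].  Including it
    keeps false-positive pass-1 links from inflating the fast diffusive
    component.  Returns (weights, Ds, clutter_weight) with the diffusive
    components sorted by D ascending.
    """
    d = np.asarray(displacements, dtype=float)
    d = d[d > 0]
    if d.size < 10:
        raise ValueError("too few displacements for a mixture fit")
    d2 = d**2
    qs = np.quantile(d2, np.linspace(0.3, 0.8, n_components))
    v = np.maximum(qs, 1e-12)           # per-component E[d^2]
    if clutter_max is not None:
        log_f_clutter = np.where(d <= clutter_max,
                                 np.log(2 * d / clutter_max**2), -np.inf)
        w = np.concatenate([np.full(n_components, 0.9 / n_components), [0.1]])
    else:
        w = np.full(n_components, 1.0 / n_components)
    prev = -np.inf
    for _ in range(max_iter):
        log_p = (np.log(w[:n_components])[None, :] - np.log(v)[None, :]
                 - d2[:, None] / v[None, :])
        if clutter_max is not None:
            log_p = np.column_stack([log_p, np.log(w[-1]) + log_f_clutter])
        m = log_p.max(axis=1, keepdims=True)
        p = np.exp(log_p - m)
        norm = p.sum(axis=1, keepdims=True)
        ll = float((np.log(norm) + m).sum())
        gamma = p / norm
        gsum = gamma.sum(axis=0)
        w = gsum / d2.size
        gs = gamma[:, :n_components]
        v = np.maximum((gs * d2[:, None]).sum(axis=0)
                       / np.maximum(gsum[:n_components], 1e-300), 1e-12)
        if abs(ll - prev) < tol * max(abs(ll), 1.0):
            break
        prev = ll
    order = np.argsort(v)
    clutter_w = float(w[-1]) if clutter_max is not None else 0.0
    return w[order], (v / (4.0 * t))[order], clutter_w


def rough_mobile_D(displacements, t: float, min_n: int = 50,
                   min_weight: float = 0.02,
                   gate: Optional[float] = None) -> float:
    """Gate-sizing diffusion estimate: the fastest diffusive mixture
    component with non-negligible weight, with spurious-link clutter (links
    accepted within ``gate``) modelled explicitly.  Falls back to the pooled
    moment estimator for effectively single-state pools."""
    d = np.asarray(displacements, dtype=float)
    if d.size < min_n:
        raise ValueError(f"need at least {min_n} displacements, got {d.size}")
    pooled = rayleigh_moment_D(d, t)
    try:
        w, Ds, _ = rayleigh_mixture(d, t, clutter_max=gate)
    except ValueError:
        return pooled
    fast = [D for wk, D in zip(w, Ds) if wk >= min_weight]
    # the pooled estimate is the floor: in a near-single-state pool the
    # clutter term can siphon genuine tail mass out of the fast component,
    # and a gate must never be narrower than the pooled motion suggests
    return float(max(fast + [pooled])) if fast else pooled


@dataclass
class RayleighFit:
    D: float
    D_stderr: float
    D_moment: float
    r_squared: float
    rmse: float
    converged: bool


def fit_rayleigh(displacements, t: float, bin_nm: float = DEFAULT_BIN_NM,
                 min_n: int = 50) -> RayleighFit:
    """Single-population 2D Brownian fit of the binned displacement histogram
    by nonlinear least squares; falls back to the moment estimator when the
    optimiser fails."""
    d = np.asarray(displacements, dtype=float)
    if d.size < min_n:
        raise ValueError(f"need at least {min_n} displacements, got {d.size}")
    d_moment = rayleigh_moment_D(d, t)
    w = bin_nm / 1000.0
    edges = np.arange(0.0, d.max() + 2 * w, w)
    counts, _ = np.histogram(d, bins=edges)
    centers = 0.5 * (edges[:-1] + edges[1:])
    norm = d.size * w

    def model(x, D):
        return norm * x / (2 * D * t) * np.exp(-(x**2) / (4 * D * t))

    try:
        popt, pcov = optimize.curve_fit(model, centers, counts, p0=[max(d_moment, 1e-9)])
        D_hat = float(popt[0])
        stderr = float(np.sqrt(pcov[0, 0]))
        converged = True
    except (RuntimeError, ValueError):
        D_hat, stderr, converged = d_moment, np.nan, False
    resid = counts - model(centers, D_hat)
    ss_tot = np.sum((counts - counts.mean()) ** 2)
    r2 = float(1.0 - np.sum(resid**2) / ss_tot) if ss_tot > 0 else np.nan
    rmse = float(np.sqrt(np.mean(resid**2)))
    return RayleighFit(D_hat, stderr, d_moment, r2, rmse, converged)


# ---------------------------------------------------------------------------
# MSD


def msd(tracks: TrackSet, max_lag: int = 10, overlapping: bool = True):
    """Time-averaged mean square displacement per lag, pooled over tracks.

    Returns (lag_times_s, msd_um2, n_pairs).  A track contributes to lag l
    only the (start, start+l) pairs it actually contains; with
    ``overlapping=False`` starts advance in strides of l.
    """
    t = tracks.acquisition.frame_interval
    sums = np.zeros(max_lag)
    counts = np.zeros(max_lag, dtype=int)
    for tr in tracks:
        n = len(tr.frames)
        # only contiguous-frame tracks participate in clean lag arithmetic
        for lag in range(1, min(max_lag, n - 1) + 1):
            starts = range(0, n - lag, 1 if overlapping else lag)
            idx = np.fromiter(starts, dtype=int)
            ok = tr.frames[idx + lag] - tr.frames[idx] == lag
            if not np.any(ok):
                continue
            disp = tr.xy[idx[ok] + lag] - tr.xy[idx[ok]]
            sums[lag - 1] += np.sum(disp[:, 0] ** 2 + disp[:, 1] ** 2)
            counts[lag - 1] += int(ok.sum())
    if counts.sum() == 0:
        raise ValueError("no track long enough for any requested lag")
    valid = counts > 0
    lags = (np.arange(1, max_lag + 1) * t)[valid]
    return lags, sums[valid] / counts[valid], counts[valid]


@dataclass
class MsdFit:
    model: str                  # 'linear' or 'anomalous'
    D: float                    # linear: D; anomalous: D_alpha
    alpha: float = 1.0
    lag_times: np.ndarray = None
    msd_values: np.ndarray = None
    r_squared: float = np.nan
    excluded_lags: int = 0


def fit_msd(lag_times, msd_values, model: str = "linear",
            n_lags: Optional[int] = 10) -> MsdFit:
    """Fit an MSD curve.

    linear:    MSD = 4 D t          (least squares through the origin slope)
    anomalous: MSD = 4 D_a t^alpha  (log-log linear regression)
    """
    lag_times = np.asarray(lag_times, dtype=float)
    msd_values = np.asarray(msd_values, dtype=float)
    if n_lags is not None:
        lag_times, msd_values = lag_times[:n_lags], msd_values[:n_lags]
    if len(lag_times) < 2:
        raise ValueError("need at least 2 lag points")
    if model == "linear":
        slope, intercept = np.polyfit(lag_times, msd_values, 1)
        pred = slope * lag_times + intercept
        D = float(slope / 4.0)
        alpha, excl = 1.0, 0
    elif model == "anomalous":
        pos = msd_values > 0
        excl = int((~pos).sum())
        if pos.sum() < 2:
            raise ValueError("not enough positive MSD values for log-log fit")
        lt, mv = np.log(lag_times[pos]), np.log(msd_values[pos])
        a, b = np.polyfit(lt, mv, 1)
        alpha = float(a)
        D = float(np.exp(b) / 4.0)
        pred = np.exp(a * np.log(lag_times[pos]) + b)
        msd_values = msd_values[pos]
    else:
        raise ValueError("model must be 'linear' or 'anomalous'")
    ss_tot = np.sum((msd_values - msd_values.mean()) ** 2)
    r2 = float(1 - np.sum((msd_values - pred) ** 2) / ss_tot) if ss_tot > 0 else np.nan
    return MsdFit(model, D, alpha, lag_times, msd_values, r2, excl)


# ---------------------------------------------------------------------------
# two-state HMM


@dataclass
class TwoStateModel:
    """Two-state diffusion model of condensed-phase motion.

    D_c <= D_m by construction (states are relabelled after fitting);
    switching probabilities are per frame.
    """

    D_c: float
    D_m: float
    P_cm: float
    P_mc: float
    frame_interval: float = 0.03
    log_likelihood: float = np.nan
    n_iterations: int = 0
    converged: bool = False
    flags: list = field(default_factory=list)

    @property
    def P_c(self) -> float:
        return self.P_mc / (self.P_mc + self.P_cm)

    @property
    def P_m(self) -> float:
        return 1.0 - self.P_c

    @property
    def confined_lifetime(self) -> float:
        """Mean confined dwell in seconds, t / P_cm."""
        return self.frame_interval / self.P_cm if self.P_cm > 0 else np.inf

    @property
    def mobile_lifetime(self) -> float:
        return self.frame_interval / self.P_mc if self.P_mc > 0 else np.inf

    def as_dict(self) -> dict:
        return {
            "D_c": self.D_c, "D_m": self.D_m,
            "P_cm": self.P_cm, "P_mc": self.P_mc,
            "P_c": self.P_c, "P_m": self.P_m,
            "confined_lifetime_s": self.confined_lifetime,
            "mobile_lifetime_s": self.mobile_lifetime,
            "log_likelihood": self.log_likelihood,
            "n_iterations": self.n_iterations,
            "converged": self.converged,
            "flags": list(self.flags),
        }


def confinement_ratios(model: TwoStateModel):
    """(P_c, P_m, t_c, t_m): stationary state fractions and mean dwell times
    (seconds) implied by the per-frame switching probabilities."""
    if model.P_cm == 0 and model.P_mc == 0:
        raise ValueError("both switching probabilities are zero")
    return model.P_c, model.P_m, model.confined_lifetime, model.mobile_lifetime


def _antimode_split(d: np.ndarray) -> float:
    """Split point between the two modes of a displacement histogram; falls
    back to the median when the smoothed histogram is unimodal."""
    hist, edges = np.histogram(d, bins=100)
    # light smoothing to suppress shot noise
    kernel = np.ones(5) / 5.0
    smooth = np.convolve(hist, kernel, mode="same")
    peaks = [i for i in range(1, len(smooth) - 1)
             if smooth[i] >= smooth[i - 1] and smooth[i] >= smooth[i + 1]]
    if len(peaks) >= 2:
        order = sorted(peaks, key=lambda i: -smooth[i])[:2]
        lo, hi = sorted(order)
        if hi > lo + 1:
            i_min = lo + 1 + int(np.argmin(smooth[lo + 1:hi]))
            return float(0.5 * (edges[i_min] + edges[i_min + 1]))
    return float(np.median(d))


def _prepare_tracks(tracks: TrackSet):
    """Pad per-track displacement sequences into a (n_tracks, L) matrix."""
    seqs = [tr.displacements() for tr in tracks if tr.n_steps >= 2]
    if not seqs:
        raise ValueError("no track with >= 2 steps")
    L = max(len(s) for s in seqs)
    D = np.zeros((len(seqs), L))
    mask = np.zeros((len(seqs), L), dtype=bool)
    for i, s in enumerate(seqs):
        D[i, :len(s)] = s
        mask[i, :len(s)] = True
    return D, mask


def hmm_fit(tracks: TrackSet, init: Optional[TwoStateModel] = None,
            tol: float = 1e-8, max_iter: int = 10_000,
            localization_error: float = 0.0,
            clutter_gate: Optional[float] = None) -> TwoStateModel:
    """Baum-Welch EM fit of the two-state diffusion HMM over pooled tracks.

    Emission per state i is the 2D Brownian magnitude density with scale
    4*D_i*t (optionally widened by a static localization-error term
    4*s^2, off by default).  Each track's forward pass starts from the
    stationary distribution of the current transition matrix; the initial
    distribution is then refined as a free EM parameter, so the pooled
    log-likelihood is non-decreasing at every iteration.  States are
    relabelled on output so that D_c <= D_m.

    ``clutter_gate`` (um) adds a third hidden state with the fixed emission
    2 d / R^2 on [0, R] — the distance law of a spurious link to an
    unrelated molecule accepted within gate R.  Tracked (as opposed to
    ground-truth) data contains a small fraction of such links at track
    ends; when the genuine mobile population is itself small they would
    otherwise be absorbed into D_m and P_m.  The reported two-state model is
    the diffusive block with transitions renormalized over diffusive
    destinations; the clutter occupancy is recorded in ``flags``.
    """
    t = tracks.acquisition.frame_interval
    d, mask = _prepare_tracks(tracks)
    d2 = d**2
    n_tracks, L = d.shape
    flags = []
    n_diff = 2
    K = 3 if clutter_gate is not None else 2

    if init is None:
        split = _antimode_split(d[mask])
        lo, hi = d[mask][d[mask] < split], d[mask][d[mask] >= split]
        if lo.size == 0 or hi.size == 0:
            lo = hi = d[mask]
        D0 = np.array([max(np.mean(lo**2) / (4 * t), 1e-8),
                       max(np.mean(hi**2) / (4 * t), 1e-8)])
    else:
        D0 = np.array([init.D_c, init.D_m])
    A = np.full((K, K), 0.1 / (K - 1)) + np.eye(K) * (0.9 - 0.1 / (K - 1))
    if init is not None and K == 2:
        A = np.array([[1 - init.P_cm, init.P_cm], [init.P_mc, 1 - init.P_mc]])
    if K == 3:
        B_clutter = np.where(
            (d > 0) & (d <= clutter_gate), 2.0 * d / clutter_gate**2, 1e-300)
        B_clutter[~mask] = 1.0

    err2 = localization_error**2
    pi = np.full(K, 1.0 / K)
    prev_ll = -np.inf
    ll = prev_ll
    for it in range(1, max_iter + 1):
        v = 4.0 * (D0 * t + err2)                     # per-state E[d^2]
        # emission densities, (n_tracks, L, K); padded cells get 1.0
        B = np.empty((n_tracks, L, K))
        B[:, :, :n_diff] = (2.0 * d[:, :, None] / v[None, None, :]
                            * np.exp(-d2[:, :, None] / v[None, None, :]))
        B[:, :, :n_diff][~mask] = 1.0
        if K == 3:
            B[:, :, 2] = B_clutter
        B = np.maximum(B, 1e-300)

        alpha = np.empty((n_tracks, L, K))
        c = np.empty((n_tracks, L))
        alpha[:, 0] = pi[None, :] * B[:, 0]
        c[:, 0] = alpha[:, 0].sum(axis=1)
        alpha[:, 0] /= c[:, 0, None]
        for k in range(1, L):
            a = alpha[:, k - 1] @ A * B[:, k]
            c[:, k] = a.sum(axis=1)
            alpha[:, k] = a / c[:, k, None]
        beta = np.empty((n_tracks, L, K))
        beta[:, L - 1] = 1.0
        for k in range(L - 2, -1, -1):
            beta[:, k] = (B[:, k + 1] * beta[:, k + 1]) @ A.T / c[:, k + 1, None]

        gamma = alpha * beta                          # posteriors, rows sum to 1
        ll = float(np.log(c[mask]).sum())

        # expected transition counts, only within valid step pairs
        valid_pair = mask[:, :-1] & mask[:, 1:]
        xi_num = (alpha[:, :-1, :, None] * A[None, None, :, :]
                  * (B[:, 1:] * beta[:, 1:])[:, :, None, :]
                  / c[:, 1:, None, None])
        xi_num[~valid_pair] = 0.0
        xi_sum = xi_num.sum(axis=(0, 1))              # (K, K)

        g = np.where(mask[:, :, None], gamma, 0.0)
        gsum = g.sum(axis=(0, 1))
        D_new = ((g[:, :, :n_diff] * d2[:, :, None]).sum(axis=(0, 1))
                 / (4.0 * t * gsum[:n_diff]) - err2 / t)
        D_new = np.maximum(D_new, 1e-9)
        denom = xi_sum.sum(axis=1, keepdims=True)
        A_new = np.where(denom > 0, xi_sum / np.maximum(denom, 1e-300), A)
        A_new = np.clip(A_new, 1e-9, 1 - 1e-9)
        A_new /= A_new.sum(axis=1, keepdims=True)
        pi_new = gamma[:, 0, :].sum(axis=0)           # sequences are left-aligned
        pi_new /= pi_new.sum()

        if ll < prev_ll - abs(prev_ll) * 1e-10 - 1e-9:
            raise RuntimeError(
                f"EM log-likelihood decreased at iteration {it}: {prev_ll} -> {ll}")
        done = it > 1 and (ll - prev_ll) <= tol * abs(ll)
        prev_ll = ll
        D0, A, pi = D_new, A_new, pi_new
        if done:
            break

    order = np.argsort(D0)                            # relabel so D_c <= D_m
    D0 = D0[order]
    diff_idx = list(order) + ([2] if K == 3 else [])
    A = A[np.ix_(diff_idx, diff_idx)]
    if K == 3:
        g = np.where(mask[:, :, None], gamma, 0.0)
        occ = g.sum(axis=(0, 1))
        flags.append(f"clutter occupancy {occ[2] / occ.sum():.4f}")
        # renormalize diffusive transitions over diffusive destinations
        A = A[:2, :2] / A[:2, :2].sum(axis=1, keepdims=True)
    if D0[1] / max(D0[0], 1e-12) < 1.5:
        flags.append("states nearly degenerate: single-state data?")
    model = TwoStateModel(
        D_c=float(D0[0]), D_m=float(D0[1]),
        P_cm=float(A[0, 1]), P_mc=float(A[1, 0]),
        frame_interval=t, log_likelihood=ll, n_iterations=it,
        converged=bool(done), flags=flags)
    return model


def _stationary(A: np.ndarray) -> np.ndarray:
    """Stationary distribution of a 2x2 row-stochastic matrix."""
    p01, p10 = A[0, 1], A[1, 0]
    if p01 + p10 == 0:
        return np.array([0.5, 0.5])
    return np.array([p10, p01]) / (p01 + p10)


def hmm_log_likelihood(tracks: TrackSet, model: TwoStateModel) -> float:
    """Pooled log-likelihood of tracks under a fixed two-state model."""
    t = tracks.acquisition.frame_interval
    d, mask = _prepare_tracks(tracks)
    d2 = d**2
    v = 4.0 * t * np.array([model.D_c, model.D_m])
    A = np.array([[1 - model.P_cm, model.P_cm], [model.P_mc, 1 - model.P_mc]])
    pi = _stationary(A)
    B = (2.0 * d[:, :, None] / v[None, None, :]) * np.exp(-d2[:, :, None] / v[None, None, :])
    B[~mask] = 1.0
    B = np.maximum(B, 1e-300)
    n_tracks, L = d.shape
    alpha = pi[None, :] * B[:, 0]
    c = alpha.sum(axis=1)
    ll = np.where(mask[:, 0], np.log(c), 0.0).copy()
    alpha = alpha / c[:, None]
    for k in range(1, L):
        a = alpha @ A * B[:, k]
        c = a.sum(axis=1)
        ll += np.where(mask[:, k], np.log(c), 0.0)
        alpha = a / c[:, None]
    return float(ll.sum())


# ---------------------------------------------------------------------------
# kinetic <-> equilibrium relations


def ef_from_kinetics(D_d: float, D_m: float, P_m: float) -> float:
    """Enrichment fold from the kinetic relation EF = D_d / (P_m * D_m)."""
    if P_m <= 0:
        raise ValueError("P_m must be positive (no mobile exchange, EF undefined)")
    if D_d <= 0 or D_m <= 0:
        raise ValueError("diffusion coefficients must be positive")
    return D_d / (P_m * D_m)


def flux_balance_check(phases: Sequence[Sequence[tuple]]):
    """Multi-state flux balance: per phase, sum over states of density x D.

    ``phases`` is a list of phases, each a list of (sigma_i, D_i) states.
    Returns (per-phase flux list, max pairwise relative imbalance).
    """
    if len(phases) < 2:
        raise ValueError("need at least two phases")
    fluxes = [float(sum(s * D for s, D in phase)) for phase in phases]
    mean = np.mean(fluxes)
    imbalance = (max(fluxes) - min(fluxes)) / mean if mean > 0 else np.nan
    return fluxes, float(imbalance)


def loc_error_scale(D_L: float, t: float) -> float:
    """Localization-error scale s = sqrt(D_L * t), reported in nanometres.

    A confined-state diffusion coefficient absorbs the apparent jitter of a
    stationary emitter; s is the per-axis scatter that jitter corresponds to.
    """
    if D_L < 0 or t <= 0:
        raise ValueError("require D_L >= 0 and t > 0")
    return math.sqrt(D_L * t) * 1000.0
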