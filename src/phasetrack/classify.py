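"""Model-free classification of displacement steps into low-mobility (L)
and high-mobility (H) states.

If condensed-phase motion were simple diffusion, consecutive step magnitudes
d_i, d_{i+1} would be independent, so the conditional distributions
P(d_{i+1} | d_i < d_b) and P(d_{i+1} | d_i > d_b) would coincide for any
demarcation d_b.  Correlated two-state motion makes them differ; the d_b
that *minimizes* their overlap coefficient

    OVL(P, Q) = ∫ min(P(x), Q(x)) dx

maximally separates the two mobility classes.  Steps below/above d_b* are
then labelled L/H, giving model-free confinement and mobile ratios and
per-frame switching frequencies from the label transition counts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import math

import numpy as np
from scipy import optimize, stats

from .geometry import CONDENSED
from .io import TrackSet
from .motion import truncated_rayleigh_mle

L_STATE = "L"
H_STATE = "H"
DEFAULT_BIN_NM = 5.0
MIN_STEPS = 10          # track eligibility: >= 10 steps (11 positions)
LOW_POWER_PAIRS = 100


def eligible_tracks(tracks: TrackSet, phase: Optional[str] = CONDENSED,
                    min_steps: int = MIN_STEPS):
    """Tracks entirely within ``phase`` (None = no phase filter) with at
    least ``min_steps`` steps."""
    out = []
    for tr in tracks:
        if tr.n_steps < min_steps:
            continue
        if phase is not None and not all(p == phase for p in tr.phase):
            continue
        out.append(tr)
    return out


@dataclass
class ConditionalDists:
    """The two conditional next-step distributions split at demarcation d_b."""

    d_b: float                   # um
    bin_edges: np.ndarray        # common grid, um
    p_low: np.ndarray            # P(d_{i+1} | d_i < d_b), normalized
    p_high: np.ndarray           # P(d_{i+1} | d_i > d_b)
    n_low: int
    n_high: int
    low_power: bool = False


def conditional_dists(tracks, d_b: float, bin_nm: float = DEFAULT_BIN_NM,
                      min_steps: int = MIN_STEPS,
                      prefiltered: bool = False) -> ConditionalDists:
    """Conditional distributions of d_{i+1} given d_i below/above d_b (um).

    Only condensed-phase tracks with >= ``min_steps`` steps contribute
    (unless ``prefiltered``).  If d_b collides with an observed displacement
    it is nudged by half a bin so no step sits exactly on the boundary.
    """
    trs = tracks if prefiltered else eligible_tracks(tracks, min_steps=min_steps)
    lows, highs = [], []
    all_d = []
    for tr in trs:
        d = tr.displacements()
        all_d.append(d)
        lows.append(d[1:][d[:-1] < d_b])
        highs.append(d[1:][d[:-1] > d_b])
    if not all_d:
        raise ValueError("no eligible track")
    all_d = np.concatenate(all_d)
    w = bin_nm / 1000.0
    if np.any(np.isclose(all_d, d_b, rtol=0, atol=1e-12)):
        d_b += 0.5 * w
        lows = [tr.displacements()[1:][tr.displacements()[:-1] < d_b] for tr in trs]
        highs = [tr.displacements()[1:][tr.displacements()[:-1] > d_b] for tr in trs]
    low = np.concatenate(lows) if lows else np.empty(0)
    high = np.concatenate(highs) if highs else np.empty(0)
    edges = np.arange(0.0, all_d.max() + 2 * w, w)
    p_low, _ = np.histogram(low, bins=edges, density=True)
    p_high, _ = np.histogram(high, bins=edges, density=True)
    return ConditionalDists(d_b, edges, p_low, p_high, low.size, high.size,
                            low_power=min(low.size, high.size) < LOW_POWER_PAIRS)


def ovl(p: np.ndarray, q: np.ndarray, bin_width: float) -> float:
    """Overlap coefficient of two normalized histograms on a common grid."""
    p, q = np.asarray(p, float), np.asarray(q, float)
    if p.shape != q.shape:
        raise ValueError("histograms must share the same grid")
    return float(np.minimum(p, q).sum() * bin_width)


@dataclass
class DemarcationScan:
    d_b_grid: np.ndarray       # um
    ovl_curve: np.ndarray
    d_b_star: Optional[float]  # None when the curve is flat (no structure)
    flat: bool


def _ovl_noise_deficit(p_pooled: np.ndarray, w: float, n1: int, n2: int) -> float:
    """Expected shortfall of the OVL estimator under the null that both
    conditionals share the pooled distribution.

    With bin probabilities p_k estimated from n1 and n2 samples, the
    half-absolute-difference statistic has expectation
    0.5 * sum_k E|p1_k - p2_k| ~ 0.5 * sqrt(2/pi) * sqrt(1/n1 + 1/n2)
    * sum_k sqrt(p_k * w); subtracting it debiases comparisons between
    demarcations with very different conditional sample sizes.
    """
    pk = np.clip(p_pooled * w, 0.0, 1.0)
    return float(0.5 * math.sqrt(2 / math.pi) * math.sqrt(1 / n1 + 1 / n2)
                 * np.sum(np.sqrt(pk)))


def scan_demarcation(tracks, d_b_grid=None, bin_nm: float = DEFAULT_BIN_NM,
                     min_steps: int = MIN_STEPS, min_pairs: int = LOW_POWER_PAIRS,
                     flat_tol: float = 0.02) -> DemarcationScan:
    """Scan demarcations (default 10-200 nm in 10 nm steps) and return the
    OVL-minimizing d_b*; a flat OVL curve (range < ``flat_tol``) yields a
    null result, the signature of simple single-state diffusion.

    The OVL at each demarcation is corrected for its expected sampling
    shortfall (small conditional samples bias raw OVL low, which would fake
    minima at extreme demarcations), and demarcations leaving fewer than
    ``min_pairs`` pairs on either side are excluded.
    """
    if d_b_grid is None:
        d_b_grid = np.arange(0.01, 0.201, 0.01)
    d_b_grid = np.asarray(d_b_grid, dtype=float)
    trs = eligible_tracks(tracks, min_steps=min_steps)
    if not trs:
        raise ValueError("no eligible track")
    curve = np.full(len(d_b_grid), np.nan)
    w = bin_nm / 1000.0
    for k, d_b in enumerate(d_b_grid):
        cd = conditional_dists(trs, d_b, bin_nm=bin_nm, prefiltered=True)
        if min(cd.n_low, cd.n_high) < min_pairs:
            continue
        raw = ovl(cd.p_low, cd.p_high, w)
        pooled = (cd.n_low * cd.p_low + cd.n_high * cd.p_high) / (cd.n_low + cd.n_high)
        curve[k] = min(raw + _ovl_noise_deficit(pooled, w, cd.n_low, cd.n_high), 1.0)
    valid = np.isfinite(curve)
    if not valid.any():
        return DemarcationScan(d_b_grid, curve, None, True)
    vmax, vmin = np.nanmax(curve), np.nanmin(curve)
    flat = bool(vmax - vmin < flat_tol)
    d_b_star = None if flat else float(d_b_grid[int(np.nanargmin(curve))])
    return DemarcationScan(d_b_grid, curve, d_b_star, flat)


@dataclass
class ClassificationResult:
    d_b: float                   # um
    labels: list                 # per-track object arrays of 'L'/'H'
    displacements: list          # per-track step magnitudes, same order
    P_c: float
    P_m: float
    P_cm: float                  # per-frame L->H switching frequency
    P_mc: float                  # per-frame H->L switching frequency
    n_L: int
    n_H: int
    fits: dict = field(default_factory=dict)

    def as_dict(self) -> dict:
        return {"d_b_nm": self.d_b * 1000, "P_c": self.P_c, "P_m": self.P_m,
                "P_cm": self.P_cm, "P_mc": self.P_mc,
                "n_L": self.n_L, "n_H": self.n_H, **self.fits}


def classify_steps(tracks, d_b: float, min_steps: int = MIN_STEPS,
                   prefiltered: bool = False) -> ClassificationResult:
    """Label each step L (d < d_b) or H (d > d_b); derive state ratios from
    label counts and switching frequencies from label transition counts:
    P_cm = #(L->H) / #(L followed by a step), P_mc = #(H->L) / #(H ...)."""
    if d_b <= 0:
        raise ValueError("d_b must be positive")
    trs = tracks if prefiltered else eligible_tracks(tracks, min_steps=min_steps)
    if not trs:
        raise ValueError("no eligible track")
    labels = []
    disps = []
    n_L = n_H = 0
    lh = hl = l_any = h_any = 0
    for tr in trs:
        d = tr.displacements()
        lab = np.where(d < d_b, L_STATE, H_STATE).astype(object)
        tr.state[:] = lab
        labels.append(lab)
        disps.append(d)
        n_L += int((lab == L_STATE).sum())
        n_H += int((lab == H_STATE).sum())
        prev, nxt = lab[:-1], lab[1:]
        l_any += int((prev == L_STATE).sum())
        h_any += int((prev == H_STATE).sum())
        lh += int(((prev == L_STATE) & (nxt == H_STATE)).sum())
        hl += int(((prev == H_STATE) & (nxt == L_STATE)).sum())
    total = n_L + n_H
    return ClassificationResult(
        d_b=d_b, labels=labels, displacements=disps,
        P_c=n_L / total, P_m=n_H / total,
        P_cm=lh / l_any if l_any else 0.0,
        P_mc=hl / h_any if h_any else 0.0,
        n_L=n_L, n_H=n_H)


# ---------------------------------------------------------------------------
# component fits




def fit_components(result: ClassificationResult, t: float,
                   heavy_tail: bool = False) -> dict:
    """Fit the L and H displacement components.

    The L component follows the detection-error form with per-axis scale s
    (s^2 = D_L * t, reported in nm); the H component is fitted as 2D
    Brownian with coefficient D_H.  Both fits account for the truncation at
    the demarcation d_b.  With ``heavy_tail=True`` a one-sided Levy fit of
    the H component is added with an AIC comparison against the Brownian
    form (a diagnostic only).
    """
    d_L = _component(result, L_STATE)
    d_H = _component(result, H_STATE)
    if d_L.size < 10 or d_H.size < 10:
        raise ValueError("a component is too small to fit")
    # L: Rayleigh truncated above at d_b; sigma^2 = 2 s^2 (difference of two
    # s-scattered localizations), so s = sqrt(sigma^2 / 2) and D_L = s^2 / t
    s2_L = truncated_rayleigh_mle(d_L, upper=result.d_b)
    s_nm = np.sqrt(s2_L / 2.0) * 1000.0
    D_L = (s_nm / 1000.0) ** 2 / t
    # H: Rayleigh truncated below at d_b; E[d^2] = 4 D t => sigma^2 = 2 D t
    s2_H = truncated_rayleigh_mle(d_H, lower=result.d_b)
    D_H = s2_H / (2.0 * t)
    fits = {"s_L_nm": float(s_nm), "D_L": float(D_L), "D_H": float(D_H)}
    if heavy_tail:
        n = d_H.size
        loc_scale = stats.levy.fit(d_H, floc=0.0)
        ll_levy = float(np.sum(stats.levy.logpdf(d_H, *loc_scale)
                               - stats.levy.logsf(result.d_b, *loc_scale)))
        sig = np.sqrt(s2_H)
        ll_ray = float(np.sum(stats.rayleigh.logpdf(d_H, scale=sig)
                              - stats.rayleigh.logsf(result.d_b, scale=sig)))
        fits.update({
            "levy_scale": float(loc_scale[1]),
            "aic_levy": 2 * 1 - 2 * ll_levy,
            "aic_brownian": 2 * 1 - 2 * ll_ray,
            "heavy_tail_preferred": bool(ll_levy > ll_ray),
        })
    result.fits.update(fits)
    return fits


def _component(result: ClassificationResult, which: str) -> np.ndarray:
    """Pooled displacement magnitudes of one component."""
    parts = [d[lab == which]
             for d, lab in zip(result.displacements, result.labels)]
    return np.concatenate(parts) if parts else np.empty(0)
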