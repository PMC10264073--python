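"""Monte Carlo engines.

Four families of simulations are provided:

* ground-truth localization generators (homogeneous Brownian scenes,
  two-state switching tracks, full two-phase condensate scenes) used to
  benchmark the tracker and the motion-model fitters;
* the equilibrium two-phase diffusion simulator, which evolves tens of
  thousands of molecules in a periodic box containing stationary condensed
  regions and measures the enrichment fold EF(t) = (sigma_c / sigma_d);
* the simple motion-switch random walk (apparent D versus mobile ratio);
* an in-silico FRAP experiment built on the equilibrium engine.

Physics conventions
-------------------
Brownian increments per axis are Gaussian with standard deviation
sqrt(2*D*dt).  When a step starts in one phase and ends in the other, the
diffusion coefficient of the *starting* region is used for the whole step
(no interface reflection or penalty).  This start-side rule is the Ito
convention for state-dependent noise; its stationary density satisfies
D(x)*p(x) = const, which is what makes the steady-state enrichment follow
EF = D_d / (P_m * D_m) rather than a sqrt(D) ratio.

Confined molecules in the condensed phase are stationary by default
(D_c = 0).  State switching is evaluated once per integration step dt in the
equilibrium engine (probabilities labelled per-dt) and once per camera frame
in the track generators (labelled per-frame); the two scales are never mixed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .geometry import (
    DiskRegions,
    RasterRegions,
    RegionGeometry,
    wrap_periodic,
)
from .io import AcquisitionParams, LocalizationTable, Track, TrackSet, table_from_arrays

CONFINED = "confined"
MOBILE = "mobile"


# ---------------------------------------------------------------------------
# elementary steps


def brownian_step(D: float, dt: float, rng: np.random.Generator, size: int = 1) -> np.ndarray:
    """(size, 2) array of Brownian displacements; per-axis sd sqrt(2*D*dt)."""
    if D < 0 or dt <= 0:
        raise ValueError("require D >= 0 and dt > 0")
    return rng.standard_normal((size, 2)) * math.sqrt(2.0 * D * dt)


@dataclass(frozen=True)
class SwitchRates:
    """Per-step switching probabilities between confined and mobile states.

    The ``per`` label records whether the probabilities are per integration
    step dt or per camera frame; the two scales must never be mixed.  When
    derived from a mobile ratio eta the detailed-balance relation
    eta * P_mc = (1 - eta) * P_cm holds.
    """

    P_cm: float
    P_mc: float
    per: str = "frame"

    def __post_init__(self):
        if not (0 <= self.P_cm <= 1 and 0 <= self.P_mc <= 1):
            raise ValueError("switching probabilities must lie in [0, 1]")

    @property
    def mobile_ratio(self) -> float:
        if self.P_cm == 0 and self.P_mc == 0:
            raise ValueError("mobile ratio undefined for frozen states")
        return self.P_cm / (self.P_cm + self.P_mc)

    @classmethod
    def from_mobile_lifetime(cls, mobile_ratio: float, mobile_lifetime: float,
                             dt: float) -> "SwitchRates":
        """P_mc = dt / t_m and P_cm from detailed balance (per-dt scale)."""
        if not (0 < mobile_ratio < 1):
            raise ValueError("mobile_ratio must be in (0, 1) to derive rates")
        if dt >= mobile_lifetime:
            raise ValueError("dt must be smaller than the mobile lifetime")
        p_mc = dt / mobile_lifetime
        p_cm = p_mc * mobile_ratio / (1.0 - mobile_ratio)
        return cls(P_cm=p_cm, P_mc=p_mc, per="dt")

    @classmethod
    def from_confined_lifetime(cls, mobile_ratio: float, confined_lifetime: float,
                               dt: float) -> "SwitchRates":
        if not (0 < mobile_ratio < 1):
            raise ValueError("mobile_ratio must be in (0, 1) to derive rates")
        p_cm = dt / confined_lifetime
        p_mc = p_cm * (1.0 - mobile_ratio) / mobile_ratio
        return cls(P_cm=p_cm, P_mc=p_mc, per="dt")

    def rescaled(self, t_from: float, t_to: float) -> "SwitchRates":
        """Convert probabilities between time bases via the rate picture."""
        f = t_to / t_from
        return SwitchRates(P_cm=self.P_cm * f, P_mc=self.P_mc * f, per="dt")


# ---------------------------------------------------------------------------
# ground-truth track generators


@dataclass
class GroundTruth:
    """True tracks with per-step true state labels ('confined'/'mobile')."""

    tracks: list
    acquisition: AcquisitionParams = field(default_factory=AcquisitionParams)

    def to_table(self, with_ids: bool = True) -> LocalizationTable:
        frames, xs, ys, ids = [], [], [], []
        for tid, t in enumerate(self.tracks):
            frames.append(t.frames)
            xs.append(t.xy[:, 0])
            ys.append(t.xy[:, 1])
            ids.append(np.full(len(t.frames), tid))
        if not frames:
            import pandas as pd
            from .io import LocalizationTable as _LT
            return _LT(pd.DataFrame({"frame": [], "x": [], "y": []}), self.acquisition)
        return table_from_arrays(
            np.concatenate(frames), np.concatenate(xs), np.concatenate(ys),
            ids=np.concatenate(ids) if with_ids else None,
            acquisition=self.acquisition)

    def true_links(self) -> set:
        """Set of ground-truth consecutive-frame localization links, keyed by
        (frame, x, y) -> (frame+1, x, y) rounded pairs."""
        links = set()
        for t in self.tracks:
            for i in range(len(t.frames) - 1):
                if t.frames[i + 1] == t.frames[i] + 1:
                    links.add(_link_key(t.frames[i], t.xy[i], t.xy[i + 1]))
        return links

    def mean_lifetime(self) -> float:
        return float(np.mean([len(t.frames) for t in self.tracks]))


def _link_key(frame, p0, p1):
    return (int(frame), round(p0[0], 6), round(p0[1], 6), round(p1[0], 6), round(p1[1], 6))


def _draw_lifetimes(n: int, mean_lifetime: float, rng) -> np.ndarray:
    """Poisson track lifetimes (in frames), floored at one frame."""
    return np.maximum(rng.poisson(mean_lifetime, n), 1)


def simulate_homogeneous(density: float, D: float, n_frames: int,
                         box=(10.0, 10.0), mean_lifetime: float = 3.5,
                         acquisition: Optional[AcquisitionParams] = None,
                         seed: int = 0):
    """Homogeneous Brownian scene mimicking a sparse-labelling SMLM movie.

    ``density`` is the per-frame fluorophore density (molecules/um^2); the
    number of tracks is density * area * n_frames / mean_lifetime.  Track
    lifetimes are Poisson (floored at 1 frame), start frames uniform, and
    frame-to-frame motion is Brownian with coefficient D.  Sub-stepping at
    0.1 ms would sum to the identical Gaussian frame increment, so the frame
    step is drawn directly.
    """
    if density <= 0 or n_frames < 2:
        raise ValueError("require density > 0 and n_frames >= 2")
    acquisition = acquisition or AcquisitionParams()
    rng = np.random.default_rng(seed)
    area = box[0] * box[1]
    n_tracks = int(round(density * area * n_frames / mean_lifetime))
    lifetimes = _draw_lifetimes(n_tracks, mean_lifetime, rng)
    starts = rng.integers(0, n_frames, n_tracks)
    tracks = []
    t = acquisition.frame_interval
    for L, s in zip(lifetimes, starts):
        L = int(min(L, n_frames - s))
        p0 = rng.uniform([0, 0], box)
        steps = brownian_step(D, t, rng, size=L - 1) if L > 1 else np.empty((0, 2))
        xy = np.vstack([p0, p0 + np.cumsum(steps, axis=0)]) if L > 1 else p0[None, :]
        frames = np.arange(s, s + L)
        noise = acquisition.localization_precision
        obs = xy + rng.standard_normal(xy.shape) * noise if noise > 0 else xy
        tr = Track(frames, obs)
        tr.state[:] = MOBILE
        tracks.append(tr)
    gt = GroundTruth(tracks, acquisition)
    return gt, gt.to_table(with_ids=False)


def simulate_two_state(n_tracks: int, n_steps, D_m: float,
                       rates: SwitchRates, psf_scatter: float = 0.0136,
                       box=(10.0, 10.0),
                       acquisition: Optional[AcquisitionParams] = None,
                       seed: int = 0):
    """Tracks switching per frame between a confined and a mobile state.

    Confined frames emit localizations scattered Gaussian(psf_scatter) about
    a fixed anchor (apparent jitter of a stationary emitter); mobile frames
    diffuse with D_m.  ``n_steps`` may be an int (fixed length) or an array
    of per-track step counts.  Initial states are drawn from the stationary
    distribution of the switching chain.
    """
    if rates.per != "frame":
        raise ValueError("track generation needs per-frame switching rates")
    acquisition = acquisition or AcquisitionParams()
    rng = np.random.default_rng(seed)
    t = acquisition.frame_interval
    if np.isscalar(n_steps):
        n_steps = np.full(n_tracks, int(n_steps))
    p_m = rates.mobile_ratio
    tracks = []
    for L in np.asarray(n_steps, dtype=int):
        anchor = rng.uniform([0, 0], box)
        pos = anchor.copy()
        mobile = rng.random() < p_m
        xy = np.empty((L + 1, 2))
        states = np.empty(L, dtype=object)
        xy[0] = pos if mobile else anchor + rng.standard_normal(2) * psf_scatter
        for i in range(L):
            u = rng.random()
            mobile = (u < rates.P_cm) if not mobile else (u >= rates.P_mc)
            if mobile:
                pos = pos + brownian_step(D_m, t, rng, 1)[0]
                xy[i + 1] = pos
                states[i] = MOBILE
            else:
                anchor = pos  # re-anchor where the molecule was caught
                xy[i + 1] = anchor + rng.standard_normal(2) * psf_scatter
                states[i] = CONFINED
        tr = Track(np.arange(L + 1), xy)
        tr.state[:] = states
        tracks.append(tr)
    gt = GroundTruth(tracks, acquisition)
    return gt, gt.to_table(with_ids=False)


def simulate_hmm_tracks(D_c: float, D_m: float, rates: SwitchRates,
                        n_tracks: int = 2000, mean_steps: float = 10.0,
                        acquisition: Optional[AcquisitionParams] = None,
                        seed: int = 0) -> TrackSet:
    """Tracks from the two-state *diffusive* generative model (both states
    Brownian, per-frame Markov switching) — the model the HMM fitter assumes.
    """
    if rates.per != "frame":
        raise ValueError("track generation needs per-frame switching rates")
    acquisition = acquisition or AcquisitionParams()
    rng = np.random.default_rng(seed)
    t = acquisition.frame_interval
    lengths = np.maximum(rng.poisson(mean_steps, n_tracks), 2)
    p_m = rates.mobile_ratio
    sd = np.sqrt(2.0 * t * np.array([D_c, D_m]))
    tracks = []
    for L in lengths:
        state = np.empty(L, dtype=int)
        state[0] = 1 if rng.random() < p_m else 0
        u = rng.random(L)
        for i in range(1, L):
            if state[i - 1] == 1:
                state[i] = 0 if u[i] < rates.P_mc else 1
            else:
                state[i] = 1 if u[i] < rates.P_cm else 0
        steps = rng.standard_normal((L, 2)) * sd[state][:, None]
        xy = np.vstack([[0.0, 0.0], np.cumsum(steps, axis=0)])
        tr = Track(np.arange(L + 1), xy)
        tr.state[:] = np.where(state == 1, MOBILE, CONFINED)
        tracks.append(tr)
    return TrackSet(tracks, acquisition, provenance={
        "D_c": D_c, "D_m": D_m, "P_cm": rates.P_cm, "P_mc": rates.P_mc})


def sample_in_region(geometry: RegionGeometry, n: int, rng, box,
                     condensed: bool = True) -> np.ndarray:
    """Uniform samples inside (condensed=True) or outside the regions."""
    if condensed and isinstance(geometry, DiskRegions) and len(geometry.disks):
        areas = np.pi * geometry.disks[:, 2] ** 2
        pick = rng.choice(len(areas), size=n, p=areas / areas.sum())
        r = geometry.disks[pick, 2] * np.sqrt(rng.random(n))
        th = rng.random(n) * 2 * np.pi
        return geometry.disks[pick, :2] + np.column_stack([r * np.cos(th), r * np.sin(th)])
    out = np.empty((0, 2))
    while len(out) < n:
        cand = rng.uniform([0, 0], box, size=(max(4 * n, 256), 2))
        keep = geometry.contains(cand)
        if not condensed:
            keep = ~keep
        out = np.vstack([out, cand[keep]])
    return out[:n]


def simulate_condensate_scene(geometry: RegionGeometry, box,
                              sigma_c: float, ef: float,
                              D_d: float, D_m: float, rates: SwitchRates,
                              n_frames: int = 2000,
                              psf_scatter: float = 0.0136,
                              mean_lifetime: float = 3.5,
                              fov_margin: Optional[float] = None,
                              acquisition: Optional[AcquisitionParams] = None,
                              seed: int = 0):
    """Two-phase SMLM scene: condensed tracks obey the two-state switching
    model, dilute tracks are Brownian with D_d, and per-frame birth densities
    honour the requested enrichment fold (sigma_d = sigma_c / ef).

    Tracks are born in one phase and thereafter follow the dynamics of the
    phase their current position lies in, so boundary crossings occur
    naturally.  The box acts as a camera field of view: molecules are born
    in a margin-extended region and localizations are emitted only while the
    molecule is inside the box, so the in-box density stays uniform and no
    step is kinematically distorted at the edge (a molecule that leaves and
    returns produces a fresh track, as in real data).
    """
    acquisition = acquisition or AcquisitionParams()
    rng = np.random.default_rng(seed)
    t = acquisition.frame_interval
    if fov_margin is None:
        # a few diffusion lengths over a track lifetime
        fov_margin = 2.0 * math.sqrt(4 * D_d * t * mean_lifetime)
    lo = np.array([-fov_margin, -fov_margin])
    hi = np.asarray(box, dtype=float) + fov_margin
    area_c = geometry.condensed_area()
    area_ext = (hi - lo).prod() - area_c
    sigma_d = sigma_c / ef
    n_c = int(round(sigma_c * area_c * n_frames / mean_lifetime))
    n_d = int(round(sigma_d * area_ext * n_frames / mean_lifetime))
    dilute_births = np.empty((0, 2))
    while len(dilute_births) < n_d:
        cand = lo + rng.uniform(size=(max(2 * n_d, 256), 2)) * (hi - lo)
        dilute_births = np.vstack([dilute_births, cand[~geometry.contains(cand)]])
    dilute_births = dilute_births[:n_d]
    births = np.concatenate([
        sample_in_region(geometry, n_c, rng, box, condensed=True),
        dilute_births,
    ])
    order = rng.permutation(len(births))
    births = births[order]
    lifetimes = _draw_lifetimes(len(births), mean_lifetime, rng)
    starts = rng.integers(0, n_frames, len(births))
    p_m = rates.mobile_ratio
    bw, bh = float(box[0]), float(box[1])

    tracks = []
    for k in range(len(births)):
        L = int(min(lifetimes[k], n_frames - starts[k]))
        pos = births[k].copy()
        anchor = pos.copy()
        in_cond = bool(geometry.contains(pos[None, :])[0])
        mobile = (rng.random() < p_m) if in_cond else True
        xy = np.empty((L, 2))
        states = np.empty(max(L - 1, 0), dtype=object)
        xy[0] = pos if mobile else anchor + rng.standard_normal(2) * psf_scatter
        for i in range(L - 1):
            in_cond = bool(geometry.contains(pos[None, :])[0])
            if in_cond:
                u = rng.random()
                mobile = (u < rates.P_cm) if not mobile else (u >= rates.P_mc)
                if mobile:
                    pos = pos + brownian_step(D_m, t, rng, 1)[0]
                    xy[i + 1] = pos
                    states[i] = MOBILE
                else:
                    anchor = pos
                    xy[i + 1] = anchor + rng.standard_normal(2) * psf_scatter
                    states[i] = CONFINED
            else:
                mobile = True
                pos = pos + brownian_step(D_d, t, rng, 1)[0]
                xy[i + 1] = pos
                states[i] = MOBILE
        frames = np.arange(starts[k], starts[k] + L)
        # emit only inside the field of view; exits split the track
        visible = ((xy[:, 0] >= 0) & (xy[:, 0] <= bw)
                   & (xy[:, 1] >= 0) & (xy[:, 1] <= bh))
        start_seg = None
        for i in range(L + 1):
            if i < L and visible[i]:
                if start_seg is None:
                    start_seg = i
            elif start_seg is not None:
                tr = Track(frames[start_seg:i], xy[start_seg:i])
                if i - start_seg > 1:
                    tr.state[:] = states[start_seg:i - 1]
                tracks.append(tr)
                start_seg = None
    gt = GroundTruth(tracks, acquisition)
    return gt, gt.to_table(with_ids=False)


# ---------------------------------------------------------------------------
# equilibrium two-phase engine


@dataclass
class SimWorld:
    """Configuration of the periodic two-phase Monte Carlo box.

    Diffusivities are um^2/s.  The condensed phase carries a two-state
    (confined/mobile) population with mobile ratio eta; switching per
    integration step is derived from the mobile lifetime t_m via
    P_mc = dt/t_m and detailed balance (or from a confined lifetime).
    eta = 1 means everyone in the condensed phase is mobile.
    """

    box: tuple = (15.0, 30.0)
    geometry: RegionGeometry = None
    D_d: float = 0.6
    D_m: float = 0.1
    D_c: float = 0.0
    mobile_ratio: float = 0.1
    mobile_lifetime: Optional[float] = 0.1
    confined_lifetime: Optional[float] = None
    dt: float = 1e-4
    n_molecules: int = 50_000
    T: float = 100.0
    seed: int = 0
    periodic: bool = True
    raster_cell: float = 0.01

    def __post_init__(self):
        if min(self.D_d, self.D_m, self.D_c) < 0:
            raise ValueError("diffusivities must be >= 0")
        if not (0 < self.mobile_ratio <= 1):
            raise ValueError("mobile_ratio must lie in (0, 1]")
        if self.box[0] <= 0 or self.box[1] <= 0:
            raise ValueError("box dimensions must be positive")
        if self.mobile_ratio == 1 and self.mobile_lifetime not in (None, np.inf):
            raise ValueError("mobile_ratio = 1 leaves no confined state; "
                             "set mobile_lifetime to None")

    def switch_rates(self) -> SwitchRates:
        """Per-dt switching probabilities implied by the configured lifetimes."""
        if self.mobile_ratio == 1:
            return SwitchRates(0.0, 0.0, per="dt")
        if self.confined_lifetime is not None:
            if np.isinf(self.confined_lifetime):
                return SwitchRates(0.0, 0.0, per="dt")
            return SwitchRates.from_confined_lifetime(
                self.mobile_ratio, self.confined_lifetime, self.dt)
        return SwitchRates.from_mobile_lifetime(
            self.mobile_ratio, self.mobile_lifetime, self.dt)

    def ef_theory(self) -> float:
        """Kinetic prediction EF = D_d / (eta * D_m)."""
        return self.D_d / (self.mobile_ratio * self.D_m)


@dataclass
class EFTrace:
    times: np.ndarray
    ef: np.ndarray

    def steady_state(self, window: float = 10.0) -> float:
        return steady_state_EF(self, window)


def _raster_of(world: SimWorld) -> RasterRegions:
    if isinstance(world.geometry, RasterRegions):
        return world.geometry
    nx = int(round(world.box[0] / world.raster_cell))
    ny = int(round(world.box[1] / world.raster_cell))
    return world.geometry.rasterize((0.0, 0.0), (ny, nx), world.raster_cell)


def _init_positions(world: SimWorld, raster: RasterRegions, rng,
                    init, ef0: Optional[float]):
    n = world.n_molecules
    if init == "uniform":
        pos = rng.uniform([0, 0], world.box, size=(n, 2))
        return pos
    if init != "enriched":
        raise ValueError("init must be 'uniform' or 'enriched'")
    ef0 = world.ef_theory() if ef0 is None else ef0
    a_c = raster.condensed_area()
    a_d = raster.total_area() - a_c
    frac_c = ef0 * a_c / (ef0 * a_c + a_d)
    n_c = int(round(n * frac_c))
    cells_c = np.flatnonzero(raster.mask.ravel())
    cells_d = np.flatnonzero(~raster.mask.ravel())
    ny, nx = raster.mask.shape

    def _place(cells, k):
        pick = rng.choice(cells, size=k)
        iy, ix = np.divmod(pick, nx)
        jitter = rng.random((k, 2))
        return (np.asarray(raster.origin)
                + (np.column_stack([ix, iy]) + jitter) * raster.cell_size)

    return np.vstack([_place(cells_c, n_c), _place(cells_d, n - n_c)])


try:  # optional acceleration; the numpy path is equivalent
    import numba as _numba
except ImportError:  # pragma: no cover
    _numba = None


def _chunk_kernel_py(x, y, confined, cond, U, N0, N1, flat, nx, ny, inv,
                     ox, oy, bw, bh, sd_m, sd_d, sd_c, p_cm, p_mc,
                     switching, periodic):
    for s in range(N0.shape[0]):
        if switching:
            u = U[s]
            flip = cond & np.where(confined, u < p_cm, u < p_mc)
            confined ^= flip
        confined &= cond
        sd = np.where(cond, sd_m, sd_d)
        sd[confined] = sd_c
        x += N0[s] * sd
        y += N1[s] * sd
        if periodic:
            x %= bw
            y %= bh
        ix = np.clip(((x - ox) * inv).astype(np.intp), 0, nx - 1)
        iy = np.clip(((y - oy) * inv).astype(np.intp), 0, ny - 1)
        cond[:] = flat[iy * nx + ix]


if _numba is not None:
    @_numba.njit(cache=True, fastmath=True)
    def _chunk_kernel(x, y, confined, cond, U, N0, N1, flat, nx, ny, inv,
                      ox, oy, bw, bh, sd_m, sd_d, sd_c, p_cm, p_mc,
                      switching, periodic):  # pragma: no cover - jitted
        m, n = N0.shape
        for s in range(m):
            for i in range(n):
                ci = cond[i]
                if not ci:
                    confined[i] = False
                elif switching:
                    u = U[s, i]
                    if confined[i]:
                        if u < p_cm:
                            confined[i] = False
                    elif u < p_mc:
                        confined[i] = True
                if confined[i]:
                    sd = sd_c
                elif ci:
                    sd = sd_m
                else:
                    sd = sd_d
                xi = x[i] + N0[s, i] * sd
                yi = y[i] + N1[s, i] * sd
                if periodic:
                    # steps are far smaller than the box: one wrap suffices
                    if xi >= bw:
                        xi -= bw
                    elif xi < 0.0:
                        xi += bw
                    if yi >= bh:
                        yi -= bh
                    elif yi < 0.0:
                        yi += bh
                ix = int((xi - ox) * inv)
                iy = int((yi - oy) * inv)
                if ix < 0:
                    ix = 0
                elif ix >= nx:
                    ix = nx - 1
                if iy < 0:
                    iy = 0
                elif iy >= ny:
                    iy = ny - 1
                cond[i] = flat[iy * nx + ix]
                x[i] = xi
                y[i] = yi
else:
    _chunk_kernel = _chunk_kernel_py


def _run_steps(x, y, confined, cond, world, raster, rates, rng, n_steps,
               callback=None, callback_every: Optional[int] = None,
               chunk: int = 256):
    """Advance the world ``n_steps`` integration steps in place.

    Per step: state switching inside the condensed phase, then a Brownian
    move with the start-side diffusion coefficient (Ito rule) and periodic
    wrapping.  ``callback(k, x, y, cond, confined)`` is invoked at every
    multiple of ``callback_every`` steps; random numbers are drawn
    chunk-wise in a fixed order, so a given seed reproduces the same
    trajectory.
    """
    n = x.size
    dt = world.dt
    sd_m = math.sqrt(2 * world.D_m * dt)
    sd_d = math.sqrt(2 * world.D_d * dt)
    sd_c = math.sqrt(2 * world.D_c * dt)
    switching = bool(rates.P_mc > 0 or rates.P_cm > 0)
    bw, bh = float(world.box[0]), float(world.box[1])
    ny, nx = raster.mask.shape
    flat = np.ascontiguousarray(raster.mask.ravel())
    inv = 1.0 / raster.cell_size
    ox, oy = float(raster.origin[0]), float(raster.origin[1])
    empty_u = np.zeros((1, 1))
    cadence = callback_every if (callback is not None and callback_every) else n_steps
    k = 0
    while k < n_steps:
        to_cb = cadence - (k % cadence)
        m = min(chunk, n_steps - k, to_cb)
        U = rng.random((m, n)) if switching else empty_u
        # float32 normals: the ~1e-7 relative step error is far below the
        # Monte Carlo noise floor, and generation is twice as fast
        N0 = rng.standard_normal((m, n), dtype=np.float32)
        N1 = rng.standard_normal((m, n), dtype=np.float32)
        _chunk_kernel(x, y, confined, cond, U, N0, N1, flat, nx, ny, inv,
                      ox, oy, bw, bh, sd_m, sd_d, sd_c,
                      float(rates.P_cm), float(rates.P_mc),
                      switching, bool(world.periodic))
        k += m
        if callback is not None and k % cadence == 0:
            callback(k, x, y, cond, confined)
    return x, y, confined, cond


def simulate_equilibrium(world: SimWorld, record_interval: float = 0.1,
                         init: str = "uniform", ef0: Optional[float] = None,
                         rng: Optional[np.random.Generator] = None,
                         snapshot_interval: Optional[float] = None):
    """Run the two-phase engine and record the enrichment-fold trace.

    ``init='uniform'`` scatters molecules homogeneously ("randomly
    distributed"); ``init='enriched'`` pre-partitions them at enrichment
    ``ef0`` (default: the kinetic theory value).  Returns ``(trace, pos)``
    or ``(trace, pos, snapshots)`` when ``snapshot_interval`` is set, where
    snapshots is a list of (time, positions-copy) for track rendering.
    """
    if world.geometry is None:
        raise ValueError("world.geometry is required")
    rng = rng or np.random.default_rng(world.seed)
    raster = _raster_of(world)
    rates = world.switch_rates()
    a_c = raster.condensed_area()
    a_d = raster.total_area() - a_c
    if a_c == 0 or a_d == 0:
        raise ValueError("both phases must have nonzero area")
    pos = _init_positions(world, raster, rng, init, ef0)
    cond = raster.contains(pos)
    # stationary initial state assignment inside the condensed phase
    confined = cond & (rng.random(world.n_molecules) >= world.mobile_ratio)
    n_steps = int(round(world.T / world.dt))
    rec_every = max(int(round(record_interval / world.dt)), 1)
    snap_every = (int(round(snapshot_interval / world.dt))
                  if snapshot_interval else None)
    times, efs, snaps = [], [], []
    n_mol = world.n_molecules

    def _record(k, x, y, cond_k, confined_k):
        if k % rec_every == 0:
            n_c = int(cond_k.sum())
            times.append(k * world.dt)
            efs.append((n_c / a_c) / max(n_mol - n_c, 1) * a_d)
        if snap_every and k % snap_every == 0:
            snaps.append((k * world.dt, np.column_stack([x, y])))

    x, y = pos[:, 0].copy(), pos[:, 1].copy()
    cadence = math.gcd(rec_every, snap_every) if snap_every else rec_every
    _run_steps(x, y, confined, cond, world, raster, rates, rng, n_steps,
               callback=_record, callback_every=cadence)
    pos = np.column_stack([x, y])
    trace = EFTrace(np.asarray(times), np.asarray(efs))
    if snapshot_interval:
        return trace, pos, snaps
    return trace, pos


def steady_state_EF(trace, window: float = 10.0):
    """Mean EF over the last ``window`` seconds of a trace; for a sequence of
    replicate traces, (mean, sd) of the per-trace steady-state means."""
    if isinstance(trace, (list, tuple)) and isinstance(trace[0], EFTrace):
        vals = np.array([steady_state_EF(tr, window) for tr in trace])
        return float(vals.mean()), float(vals.std(ddof=1))
    t_end = trace.times[-1]
    if t_end - trace.times[0] < window - 1e-9:
        raise ValueError("trace shorter than the averaging window")
    sel = trace.times > t_end - window + 1e-12
    return float(trace.ef[sel].mean())


def tracks_from_snapshots(snaps, acquisition: AcquisitionParams,
                          n_molecules: Optional[int] = None) -> TrackSet:
    """Render per-molecule tracks from equilibrium-engine snapshots."""
    times = np.array([t for t, _ in snaps])
    pos = np.stack([p for _, p in snaps])  # (n_snap, n_mol, 2)
    if n_molecules is not None:
        pos = pos[:, :n_molecules]
    frames = np.round(times / acquisition.frame_interval).astype(int)
    tracks = [Track(frames, pos[:, m]) for m in range(pos.shape[1])]
    return TrackSet(tracks, acquisition)


# ---------------------------------------------------------------------------
# simple motion-switch walk (apparent D versus mobile ratio)


def simulate_switch_walk(D_m: float = 0.61, P_cm: float = 0.1,
                         mobile_ratios: Sequence[float] = tuple(np.round(np.arange(0.1, 1.0, 0.1), 2)),
                         n_particles: int = 500, T: float = 100.0,
                         acquisition: Optional[AcquisitionParams] = None,
                         max_lag: int = 10, seed: int = 0) -> dict:
    """Per-frame two-state walk at each mobile ratio; returns
    {P_m: (msd_curve_lags_s, msd_values, D_apparent)} with the apparent D
    from a linear (alpha = 1) MSD fit.
    """
    from .motion import fit_msd, msd  # local import to avoid a cycle

    acquisition = acquisition or AcquisitionParams()
    t = acquisition.frame_interval
    n_frames = int(round(T / t))
    rng = np.random.default_rng(seed)
    out = {}
    for p_m in mobile_ratios:
        if p_m <= 0:
            raise ValueError("mobile ratio must be positive")
        if p_m >= 1:
            rates = SwitchRates(1.0, 0.0, per="frame")  # always mobile
        else:
            rates = SwitchRates(P_cm, P_cm * (1 - p_m) / p_m, per="frame")
        mobile = rng.random(n_particles) < p_m
        pos = np.zeros((n_particles, 2))
        traj = np.empty((n_frames, n_particles, 2))
        traj[0] = pos
        sd = math.sqrt(2 * D_m * t)
        for f in range(1, n_frames):
            u = rng.random(n_particles)
            mobile = np.where(mobile, u >= rates.P_mc, u < rates.P_cm)
            pos = pos + np.where(mobile[:, None], rng.standard_normal((n_particles, 2)) * sd, 0.0)
            traj[f] = pos
        tracks = [Track(np.arange(n_frames), traj[:, i]) for i in range(n_particles)]
        ts = TrackSet(tracks, acquisition)
        lags, values, _ = msd(ts, max_lag=max_lag)
        fit = fit_msd(lags, values, model="linear")
        out[float(p_m)] = (lags, values, fit.D)
    return out


# ---------------------------------------------------------------------------
# FRAP


def default_frap_droplets() -> DiskRegions:
    """Seven droplets in the 20 x 8 um FRAP box: radii 0.5/1/1/2/1/1/0.5 um
    at x = 1/3/5/10/15/17/19 um, centred at mid-height."""
    radii = [0.5, 1, 1, 2, 1, 1, 0.5]
    xs = [1, 3, 5, 10, 15, 17, 19]
    return DiskRegions(np.array([[x, 4.0, r] for x, r in zip(xs, radii)]))


@dataclass
class FrapConfig:
    """In-silico FRAP: bleach disk ROI(s), then watch unbleached molecules
    re-enter.  Kinetics are as in :class:`SimWorld`; ``confined_lifetime``
    may be ``inf`` for permanently immobilized confined molecules."""

    box: tuple = (20.0, 8.0)
    geometry: RegionGeometry = field(default_factory=default_frap_droplets)
    rois: Sequence = ((10.0, 4.0, 0.5), (3.0, 4.0, 0.5), (19.0, 4.0, 0.5))
    ef: float = 100.0
    D_d: float = 1.0
    D_m: float = 0.1
    mobile_ratio: float = 1.0
    confined_lifetime: Optional[float] = None
    dt: float = 1e-4
    n_molecules: int = 50_000
    T: float = 100.0
    burn_in: float = 2.0
    record_interval: float = 0.1
    seed: int = 0

    def world(self) -> SimWorld:
        return SimWorld(box=self.box, geometry=self.geometry, D_d=self.D_d,
                        D_m=self.D_m, mobile_ratio=self.mobile_ratio,
                        mobile_lifetime=None,
                        confined_lifetime=self.confined_lifetime,
                        dt=self.dt, n_molecules=self.n_molecules, T=self.T,
                        seed=self.seed)


@dataclass
class FrapResult:
    times: np.ndarray           # seconds since bleach
    recovery: np.ndarray        # (n_rois, n_times), percent
    prebleach_counts: np.ndarray

    def plateau(self, window: float = 5.0) -> np.ndarray:
        sel = self.times > self.times[-1] - window
        return self.recovery[:, sel].mean(axis=1)


def simulate_frap(config: FrapConfig) -> FrapResult:
    """Equilibrate at the configured EF, bleach every molecule inside each
    ROI, then record the unbleached fraction in each ROI over time,
    normalized to pre-bleach = 100 % and post-bleach = 0 %."""
    world = config.world()
    rois = np.atleast_2d(np.asarray(config.rois, dtype=float))
    for cx, cy, r in rois:
        if not (0 <= cx <= config.box[0] and 0 <= cy <= config.box[1]):
            raise ValueError("bleach ROI must intersect the box")
    rng = np.random.default_rng(config.seed)
    raster = _raster_of(world)
    rates = world.switch_rates()
    pos = _init_positions(world, raster, rng, "enriched", config.ef)
    cond = raster.contains(pos)
    confined = cond & (rng.random(world.n_molecules) >= world.mobile_ratio)
    x, y = pos[:, 0].copy(), pos[:, 1].copy()
    n_burn = int(round(config.burn_in / world.dt))
    _run_steps(x, y, confined, cond, world, raster, rates, rng, n_burn)

    def _in_roi(xs, ys):
        d2 = ((xs[:, None] - rois[None, :, 0]) ** 2
              + (ys[:, None] - rois[None, :, 1]) ** 2)
        return d2 <= rois[None, :, 2] ** 2  # (n_mol, n_roi)

    inroi = _in_roi(x, y)
    prebleach = inroi.sum(axis=0).astype(float)
    if np.any(prebleach == 0):
        raise ValueError("a bleach ROI contains no molecules at bleach time")
    unbleached = ~inroi.any(axis=1)
    n_steps = int(round(config.T / world.dt))
    rec_every = max(int(round(config.record_interval / world.dt)), 1)
    times, rec = [], []

    def _record(k, xs, ys, cond_k, confined_k):
        if k % rec_every == 0:
            inr = _in_roi(xs[unbleached], ys[unbleached])
            times.append(k * world.dt)
            rec.append(100.0 * inr.sum(axis=0) / prebleach)

    _run_steps(x, y, confined, cond, world, raster, rates, rng, n_steps,
               callback=_record, callback_every=rec_every)
    return FrapResult(np.asarray(times), np.asarray(rec).T, prebleach)
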