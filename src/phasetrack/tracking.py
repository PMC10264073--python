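"""Adaptive single-molecule track linking.

Linking a localization in frame f to one in frame f+1 trades two errors off
against each other: with search range R and a molecule of diffusivity D
observed at interval t, the chance of *missing* a true link (true negative)
is exp(-R^2 / 4 D t), while the chance of a *spurious* link (false positive)
grows linearly with R and with the molecule density sigma.  In the
dimensionless variable X = R / sqrt(4 D t) the total error

    E(X) = exp(-X^2) + 2 c X,        c ∝ sigma * D * t

has a unique admissible minimum at X* solving X exp(-X^2) = c on the branch
X > 1/sqrt(2).  Over the density/diffusivity ranges typical of condensate
imaging X* stays within ~2.5-3.0, so a fixed X = 2.5 is the operational
default: the tracker links once with a 500-nm default gate, estimates
per-phase diffusivities from the resulting displacements, converts them to
per-phase search ranges R = X * sqrt(4 D t), and relinks.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.optimize import brentq
from scipy.optimize import linear_sum_assignment
from scipy.spatial import cKDTree

from .geometry import CONDENSED, CROSSING, DILUTE, RegionGeometry
from .io import LocalizationTable, Track, TrackSet
from .motion import rough_D, rough_mobile_D

X_DEFAULT = 2.5
X_MIN = 1.0 / math.sqrt(2.0)  # second-derivative (minimum) condition


# ---------------------------------------------------------------------------
# assignment-error model


def assignment_error(X: float, c: float):
    """(E_TN, E_FP, E_total) of the link-error model at dimensionless search
    range X with composite false-positive coefficient c (∝ sigma*D*t)."""
    if X <= 0 or c < 0:
        raise ValueError("require X > 0 and c >= 0")
    e_tn = math.exp(-X * X)
    e_fp = 2.0 * c * X
    return e_tn, e_fp, e_tn + e_fp


def fp_coefficient(sigma: float, D: float, t: float) -> float:
    """Default composite false-positive coefficient c = pi * sigma * D * t."""
    return math.pi * sigma * D * t


def optimal_X(c: float, bracket=(X_MIN, 10.0)) -> float:
    """Error-minimizing X solving X * exp(-X^2) = c on the decreasing branch.

    The stationarity curve X*exp(-X^2) peaks at X = 1/sqrt(2); only the
    large-X root is a minimum of the total error.  Raises when c is too
    large for a root there (use the fixed default X instead).
    """
    if c <= 0:
        raise ValueError("c must be positive")
    g = lambda x: x * math.exp(-x * x) - c
    lo, hi = bracket
    if g(lo) <= 0:
        raise ValueError(
            f"c = {c:g} exceeds the admissible branch maximum "
            f"{lo * math.exp(-lo * lo):g}; fall back to the default X = 2.5")
    x = brentq(g, lo, hi, xtol=1e-14, rtol=8.9e-16)
    assert abs(g(x)) < 1e-10
    return float(x)


def search_range(D: float, t: float, X: float = X_DEFAULT) -> float:
    """Search range R = X * sqrt(4 D t) in um."""
    if D <= 0 or t <= 0:
        raise ValueError("require D > 0 and t > 0")
    return X * math.sqrt(4.0 * D * t)


@dataclass
class LinkConfig:
    """Parameters of the two-pass adaptive linker."""

    default_R: float = 0.5          # um, pass-1 global gate
    X_target: float = X_DEFAULT
    strategy: str = "optimal-bipartite"   # or 'greedy-nearest'
    max_gap: int = 0                # frames that may be skipped (0 = none)
    min_displacements: int = 50     # per phase, for the pass-1 rough D

    def __post_init__(self):
        if self.default_R <= 0:
            raise ValueError("default_R must be positive")
        if self.X_target <= X_MIN:
            raise ValueError(f"X_target must exceed 1/sqrt(2) ~ {X_MIN:.3f}")
        if self.strategy not in ("optimal-bipartite", "greedy-nearest"):
            raise ValueError("unknown assignment strategy")


# ---------------------------------------------------------------------------
# frame-to-frame linking


def _match_frame_pair(xy_a, xy_b, gate, strategy):
    """Match rows of xy_a (frame f) to rows of xy_b (frame f+1) within the
    per-pair gate matrix entries; returns list of (i, j)."""
    if len(xy_a) == 0 or len(xy_b) == 0:
        return []
    # candidate pairs within the largest gate, via KD-tree
    r_max = float(np.max(gate))
    tree = cKDTree(xy_b)
    pairs = []
    dists = []
    for i, neighbors in enumerate(tree.query_ball_point(xy_a, r_max)):
        for j in neighbors:
            d = math.hypot(xy_a[i, 0] - xy_b[j, 0], xy_a[i, 1] - xy_b[j, 1])
            if d <= gate[i, j]:
                pairs.append((i, j))
                dists.append(d)
    if not pairs:
        return []
    if strategy == "greedy-nearest":
        order = np.lexsort((np.array([p[1] for p in pairs]),
                            np.array([p[0] for p in pairs]),
                            np.array(dists)))
        used_a, used_b, out = set(), set(), []
        for k in order:
            i, j = pairs[k]
            if i not in used_a and j not in used_b:
                used_a.add(i)
                used_b.add(j)
                out.append((i, j))
        return out
    # optimal-bipartite: minimize total distance over gated pairs.  Work on
    # the subgraph of localizations that have any candidate, with a large
    # finite cost on forbidden pairs so unmatched rows stay unmatched.
    ai = sorted({p[0] for p in pairs})
    bj = sorted({p[1] for p in pairs})
    amap = {a: k for k, a in enumerate(ai)}
    bmap = {b: k for k, b in enumerate(bj)}
    BIG = 1e6
    cost = np.full((len(ai), len(bj)), BIG)
    for (i, j), d in zip(pairs, dists):
        cost[amap[i], bmap[j]] = d
    rows, cols = linear_sum_assignment(cost)
    return [(ai[r], bj[c]) for r, c in zip(rows, cols) if cost[r, c] < BIG]


def link(table: LocalizationTable, R_of_point, strategy: str = "optimal-bipartite",
         max_gap: int = 0, gate_mode: str = "min") -> TrackSet:
    """Link localizations frame-to-frame into tracks.

    ``R_of_point`` is a scalar search range or a per-localization array (um).
    A pair (i, j) is admissible within ``min(R_i, R_j)`` (``gate_mode='min'``)
    or within ``max(R_i, R_j)`` when the two gates differ
    (``gate_mode='max_mixed'``, used for cross-phase links so genuine
    exchange events are not truncated by the tighter gate).  Ties are broken
    deterministically (ascending distance, then row order), so the result is
    invariant to input row permutation.
    """
    frames = table.frames
    xy = table.xy
    n = len(table)
    R = np.broadcast_to(np.asarray(R_of_point, dtype=float), (n,)).copy()
    if np.any(R <= 0):
        raise ValueError("search ranges must be positive")
    # canonical ordering for deterministic tie-breaks
    order = np.lexsort((xy[:, 1], xy[:, 0], frames))
    frames, xy, R = frames[order], xy[order], R[order]

    parent = np.full(n, -1, dtype=int)   # index of previous localization
    child = np.full(n, -1, dtype=int)
    frame_values = np.unique(frames)
    idx_by_frame = {f: np.flatnonzero(frames == f) for f in frame_values}
    # open track tails eligible to link forward (supports frame gaps)
    for f in frame_values:
        tails = []
        for g in range(0, max_gap + 1):
            src = idx_by_frame.get(f - g, None)
            if src is None:
                continue
            tails.extend(int(i) for i in src if child[i] == -1)
        tgt = idx_by_frame.get(f + 1, None)
        if tgt is None or not tails:
            continue
        tails = np.asarray(sorted(set(tails)), dtype=int)
        tgt = np.asarray(tgt, dtype=int)
        gap_scale = np.sqrt(f + 1 - frames[tails])    # gate grows as sqrt(dt)
        Ra = R[tails] * gap_scale
        Rb = R[tgt]
        if gate_mode == "min":
            gate = np.minimum(Ra[:, None], Rb[None, :])
        elif gate_mode == "max_mixed":
            same = np.isclose(Ra[:, None], Rb[None, :])
            gate = np.where(same, Ra[:, None], np.maximum(Ra[:, None], Rb[None, :]))
        else:
            raise ValueError("gate_mode must be 'min' or 'max_mixed'")
        for i_loc, j_loc in _match_frame_pair(xy[tails], xy[tgt], gate, strategy):
            i, j = int(tails[i_loc]), int(tgt[j_loc])
            child[i] = j
            parent[j] = i

    tracks = []
    for start in range(n):
        if parent[start] != -1:
            continue
        chain = [start]
        while child[chain[-1]] != -1:
            chain.append(child[chain[-1]])
        chain = np.asarray(chain)
        tracks.append(Track(frames[chain], xy[chain]))
    acq = table.acquisition
    return TrackSet(tracks, acq, provenance={"strategy": strategy, "max_gap": max_gap})


# ---------------------------------------------------------------------------
# phase labelling and the two-pass adaptive pipeline


def label_phases(tracks: TrackSet, geometry: RegionGeometry) -> TrackSet:
    """Per-step phase labels from endpoint phases: condensed, dilute or
    crossing (endpoints in different phases)."""
    for tr in tracks:
        inside = geometry.contains(tr.xy)
        for i in range(tr.n_steps):
            if inside[i] and inside[i + 1]:
                tr.phase[i] = CONDENSED
            elif not inside[i] and not inside[i + 1]:
                tr.phase[i] = DILUTE
            else:
                tr.phase[i] = CROSSING
    return tracks


def adaptive_track(table: LocalizationTable, geometry: Optional[RegionGeometry],
                   config: Optional[LinkConfig] = None) -> TrackSet:
    """Two-pass adaptive linking.

    Pass 1 links every localization with the global default gate.  The
    pass-1 displacements are split by phase and a gate-sizing D is estimated
    per phase: the fast component of a two-component displacement-mixture
    fit, because in a two-state phase the pooled estimate is dominated by
    the confined state and would strangle mobile steps.  Per-phase gates
    R = X * sqrt(4 D t) drive pass 2 (cross-phase candidate pairs use the
    larger of the two gates).  Without geometry the scene is single-phase.
    """
    config = config or LinkConfig()
    t = table.acquisition.frame_interval
    pass1 = link(table, config.default_R, strategy=config.strategy,
                 max_gap=config.max_gap)
    provenance = {"X_target": config.X_target, "default_R": config.default_R,
                  "strategy": config.strategy}

    if geometry is None:
        disp = pass1.displacements()
        try:
            D_gate = rough_mobile_D(disp, t, min_n=config.min_displacements,
                                    gate=config.default_R)
            R_global = search_range(D_gate, t, config.X_target)
        except ValueError:
            D_gate, R_global = None, config.default_R
            provenance["fallback"] = "too few pass-1 displacements"
        provenance.update({"D_gate": D_gate, "R": R_global})
        pass2 = link(table, R_global, strategy=config.strategy,
                     max_gap=config.max_gap)
        pass2.provenance.update(provenance)
        return pass2

    label_phases(pass1, geometry)
    R_phase = {}
    D_phase = {}
    for phase in (CONDENSED, DILUTE):
        disp = pass1.displacements(phase=phase)
        try:
            D_gate = rough_mobile_D(disp, t, min_n=config.min_displacements,
                                    gate=config.default_R)
            R_phase[phase] = search_range(D_gate, t, config.X_target)
            D_phase[phase] = D_gate
        except ValueError:
            R_phase[phase] = config.default_R     # logged fallback
            D_phase[phase] = None
            provenance.setdefault("fallbacks", []).append(phase)
    provenance.update({"D_gate": D_phase, "R_phase": R_phase})

    inside = geometry.contains(table.xy)
    R_of_point = np.where(inside, R_phase[CONDENSED], R_phase[DILUTE])
    pass2 = link(table, R_of_point, strategy=config.strategy,
                 max_gap=config.max_gap, gate_mode="max_mixed")
    label_phases(pass2, geometry)
    pass2.provenance.update(provenance)
    return pass2


# ---------------------------------------------------------------------------
# boundary-crossing statistics


@dataclass
class CrossingStats:
    n_go_in: int
    n_go_out: int
    pct_go_in: float   # share of all crossing events
    pct_go_out: float


def crossing_events(tracks: TrackSet, geometry: RegionGeometry) -> CrossingStats:
    """Count dilute->condensed (go-in) and condensed->dilute (go-out) steps.

    Percentages are relative to the total number of crossing events, so at
    equilibrium both sit near 50%.
    """
    n_in = n_out = 0
    for tr in tracks:
        inside = geometry.contains(tr.xy)
        for i in range(tr.n_steps):
            if not inside[i] and inside[i + 1]:
                n_in += 1
            elif inside[i] and not inside[i + 1]:
                n_out += 1
    total = n_in + n_out
    return CrossingStats(
        n_in, n_out,
        100.0 * n_in / total if total else 0.0,
        100.0 * n_out / total if total else 0.0,
    )


# ---------------------------------------------------------------------------
# tracker evaluation against ground truth


def link_errors(trackset: TrackSet, true_links: set) -> dict:
    """True-negative (missed true link) and false-positive (spurious link)
    rates relative to the number of ground-truth consecutive-frame links."""
    from .simulate import _link_key

    found = set()
    for tr in trackset:
        for i in range(tr.n_steps):
            if tr.frames[i + 1] == tr.frames[i] + 1:
                found.add(_link_key(tr.frames[i], tr.xy[i], tr.xy[i + 1]))
    n_true = len(true_links)
    tn = len(true_links - found) / n_true
    fp = len(found - true_links) / n_true
    return {"TN": tn, "FP": fp, "total": tn + fp,
            "n_true": n_true, "n_found": len(found)}


def optimal_X_benchmark(density: float, D: float, n_frames: int = 1200,
                        box=(10.0, 10.0), X_grid=None, seed: int = 0,
                        strategy: str = "optimal-bipartite") -> dict:
    """Scan X over a grid on a simulated homogeneous scene and report the
    combined TN+FP link-error rate per X and the error-minimizing X."""
    from .simulate import simulate_homogeneous

    X_grid = np.arange(1.0, 5.01, 0.5) if X_grid is None else np.asarray(X_grid)
    gt, table = simulate_homogeneous(density, D, n_frames, box=box, seed=seed)
    truth = gt.true_links()
    t = table.acquisition.frame_interval
    errors = {}
    for X in X_grid:
        ts = link(table, search_range(D, t, float(X)), strategy=strategy)
        errors[float(X)] = link_errors(ts, truth)["total"]
    best = min(errors, key=errors.get)
    return {"errors": errors, "X_best": best}
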