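"""End-to-end orchestration.

``run_pipeline`` wires the stages together: phase segmentation from
localization densities, two-pass adaptive linking, the two-state HMM and
the model-free step classification in the condensed phase, and finally the
kinetic enrichment prediction EF = D_d / (P_m * D_m) juxtaposed with the
enrichment measured directly from localization densities — the headline
cross-validation of the whole approach.

``run_simulation_suite`` reproduces the equilibrium-simulator parameter
sweep (inputs, theoretical EF, simulated EF +/- sd over seeds).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import classify as _classify
from .geometry import CONDENSED, DILUTE, RegionGeometry
from .io import AcquisitionParams, LocalizationTable, TrackSet, write_tracks
from .motion import TwoStateModel, ef_from_kinetics, fit_msd, hmm_fit, msd, rough_D
from .segmentation import PhaseMap, enrichment_from_localizations, segment_localizations
from .simulate import SimWorld, simulate_equilibrium, steady_state_EF
from .tracking import LinkConfig, adaptive_track


PIPELINE_CONFIG_KEYS = {
    "input", "geometry", "frame_interval", "localization_precision",
    "segmentation", "linking", "classify_d_b", "seed", "outdir",
}


def load_pipeline_config(path) -> dict:
    """Read a YAML or JSON pipeline configuration and validate its keys.

    Recognised keys: input (localization CSV), geometry (geometry JSON),
    frame_interval (s), localization_precision (um), segmentation (kwargs
    for the density segmentation), linking (kwargs for LinkConfig),
    classify_d_b (nm), seed, outdir.
    """
    import yaml

    cfg = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(cfg, dict):
        raise ValueError(f"{path}: pipeline config must be a mapping")
    unknown = set(cfg) - PIPELINE_CONFIG_KEYS
    if unknown:
        raise ValueError(f"{path}: unknown config keys {sorted(unknown)}")
    for key in ("linking", "segmentation"):
        if key in cfg and not isinstance(cfg[key], dict):
            raise ValueError(f"{path}: '{key}' must be a mapping")
    if "linking" in cfg:
        LinkConfig(**cfg["linking"])    # validates field names and ranges
    return cfg


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception, partial: dict):
        super().__init__(f"pipeline stage '{stage}' failed: {cause}")
        self.stage = stage
        self.partial = partial


@dataclass
class PipelineResult:
    phase_map: Optional[PhaseMap]
    tracks: TrackSet
    model: Optional[TwoStateModel]
    classification: Optional[object]
    report: dict = field(default_factory=dict)

    def save(self, outdir) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_tracks(self.tracks, outdir / "tracks.csv")
        if self.model is not None:
            (outdir / "model.json").write_text(json.dumps(self.model.as_dict(), indent=2))
        if self.classification is not None:
            (outdir / "classification.json").write_text(
                json.dumps(self.classification.as_dict(), indent=2))
        (outdir / "report.json").write_text(json.dumps(self.report, indent=2, default=float))


def run_pipeline(table: LocalizationTable,
                 geometry: Optional[RegionGeometry] = None,
                 link_config: Optional[LinkConfig] = None,
                 segmentation_kwargs: Optional[dict] = None,
                 classify_d_b: Optional[float] = None,
                 min_class_steps: int = _classify.MIN_STEPS) -> PipelineResult:
    """Full analysis of a localization table.

    When ``geometry`` is None the condensed regions are segmented from the
    localization densities; a scene with no detectable condensed region
    falls back to single-phase analysis (no HMM / classification stages).
    """
    partial: dict = {}
    t = table.acquisition.frame_interval

    pmap = None
    if geometry is None:
        try:
            pmap = segment_localizations(table, **(segmentation_kwargs or {}))
            if pmap.degenerate:
                pmap = None
        except Exception as e:  # degenerate scenes: single-phase fallback
            partial["segmentation_warning"] = str(e)
            pmap = None
        geometry = pmap.geometry if pmap is not None else None
    partial["phase_map"] = pmap

    try:
        tracks = adaptive_track(table, geometry, link_config)
    except Exception as e:
        raise StageError("tracking", e, partial)
    partial["tracks"] = tracks

    report: dict = {"n_tracks": len(tracks), "n_localizations": table.data.shape[0],
                    "linking": {k: v for k, v in tracks.provenance.items()}}
    model = None
    classification = None
    if geometry is not None:
        try:
            condensed = TrackSet(
                [tr for tr in tracks
                 if tr.n_steps >= 2 and all(p == CONDENSED for p in tr.phase)],
                tracks.acquisition)
            # linked (not ground-truth) data carries a small population of
            # spurious gate-limited links; model them as clutter so they are
            # not absorbed into the mobile state
            gate = tracks.provenance.get("R_phase", {}).get(CONDENSED)
            model = hmm_fit(condensed, clutter_gate=gate)
        except Exception as e:
            raise StageError("hmm", e, partial)
        try:
            d_dilute = tracks.displacements(phase=DILUTE)
            gate_d = tracks.provenance.get("R_phase", {}).get(DILUTE)
            D_d = rough_D(d_dilute, t, gate=gate_d)
        except ValueError as e:
            raise StageError("dilute-D", e, partial)
        report["hmm"] = model.as_dict()
        report["D_d"] = D_d
        report["EF_kinetic"] = ef_from_kinetics(D_d, model.D_m, model.P_m)
        if pmap is not None:
            ef_loc, ef_err = enrichment_from_localizations(table, pmap)
            report["EF_localizations"] = ef_loc
            report["EF_localizations_err"] = ef_err
            report["phase_map"] = pmap.as_dict()
        try:
            if classify_d_b is None:
                scan = _classify.scan_demarcation(tracks, min_steps=min_class_steps)
                d_b = scan.d_b_star
                report["d_b_scan_flat"] = scan.flat
            else:
                d_b = classify_d_b
            if d_b is not None:
                classification = _classify.classify_steps(
                    tracks, d_b, min_steps=min_class_steps)
                _classify.fit_components(classification, t)
                report["classification"] = classification.as_dict()
                report["EF_classification"] = ef_from_kinetics(
                    D_d, classification.fits["D_H"], classification.P_m)
        except ValueError as e:
            report["classification_warning"] = str(e)
    else:
        # single-phase scene: overall mobility only.  With short (blinking-
        # limited) tracks only the first few lags carry real support; fit
        # only lags backed by a meaningful share of the lag-1 pair count.
        lags, values, counts = msd(tracks)
        keep = counts >= max(30, 0.05 * counts[0])
        fit = fit_msd(lags[keep], values[keep], model="linear")
        report["D_msd"] = fit.D
        report["single_phase"] = True
    return PipelineResult(pmap, tracks, model, classification, report)


# ---------------------------------------------------------------------------
# Table-1-style simulation suite


TABLE1_ROWS = (
    # (D_m, D_d, mobile_ratio, mobile_lifetime_s, EF_theory)
    (0.2, 0.6, 0.05, 0.1, 60.0),
    (0.1, 0.6, 0.10, 0.1, 60.0),
    (0.01, 0.6, 1.00, None, 60.0),
    (0.1, 0.6, 0.10, 0.5, 60.0),
    (0.1, 0.6, 0.05, 0.1, 120.0),
    (0.2, 0.6, 0.10, 0.1, 30.0),
)


def run_simulation_suite(rows: Sequence = TABLE1_ROWS, geometry=None,
                         box=(15.0, 30.0), n_molecules: int = 5000,
                         dt: float = 5e-4, T: float = 30.0,
                         n_seeds: int = 5, seed: int = 0,
                         init: str = "enriched", window: float = 10.0) -> pd.DataFrame:
    """Simulate each parameter row over ``n_seeds`` seeds and tabulate the
    theoretical and simulated steady-state enrichment folds."""
    from .geometry import DiskRegions

    if geometry is None:
        geometry = default_suite_droplets(box)
    records = []
    for row in rows:
        D_m, D_d, eta, t_m, ef_theory = row
        efs = []
        for s in range(n_seeds):
            world = SimWorld(box=box, geometry=geometry, D_d=D_d, D_m=D_m,
                             mobile_ratio=eta,
                             mobile_lifetime=t_m if eta < 1 else None,
                             dt=dt, n_molecules=n_molecules, T=T,
                             seed=seed * 1009 + s)
            trace, _ = simulate_equilibrium(world, init=init)
            efs.append(steady_state_EF(trace, window=window))
        records.append({
            "D_m": D_m, "D_d": D_d, "mobile_ratio": eta,
            "mobile_lifetime_s": t_m if t_m is not None else np.nan,
            "EF_theory": ef_theory,
            "EF_simulated": float(np.mean(efs)),
            "EF_sd": float(np.std(efs, ddof=1)) if n_seeds > 1 else 0.0,
        })
    return pd.DataFrame.from_records(records)


def default_suite_droplets(box=(15.0, 30.0), radius: float = 0.9,
                           nx: int = 2, ny: int = 4):
    """Synthetic stand-in for experimentally observed phase boundaries: a
    grid of well-separated droplets covering a few percent of the box.

    The radius is kept large relative to the per-step rms displacement so
    that the start-side-D boundary layer (one step wide) stays a small
    fraction of the droplet area; see docs/methods.md.
    """
    from .geometry import DiskRegions

    xs = (np.arange(nx) + 0.5) * box[0] / nx
    ys = (np.arange(ny) + 0.5) * box[1] / ny
    disks = [[x, y, radius] for x in xs for y in ys]
    return DiskRegions(np.asarray(disks))
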