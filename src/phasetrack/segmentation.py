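"""Phase segmentation from localization densities.

Because fluorophores switch on and off stochastically, a pooled localization
stack can be treated as a static sample of the underlying molecular
distribution.  Condensed-phase regions are the areas of high local
localization density; the enrichment fold (partition coefficient) is the
ratio of mean densities, EF = sigma_c / sigma_d.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.ndimage import gaussian_filter
from scipy.spatial import cKDTree
from skimage import measure, morphology
from skimage.filters import threshold_otsu

from .geometry import PolygonRegions, RasterRegions, RegionGeometry
from .io import LocalizationTable

DEFAULT_RADIUS = 0.1     # um, local-density neighborhood
DEFAULT_CELL = 0.05      # um, density-field grid cell
MIN_REGION_AREA = 0.01   # um^2, suppresses single-molecule blinking clusters


@dataclass
class DensityField:
    """Grid of localization densities (counts/um^2 per cell)."""

    counts: np.ndarray          # raw per-cell localization counts
    density: np.ndarray         # smoothed density, counts/um^2
    origin: tuple
    cell_size: float
    smoothing_radius: float

    @property
    def total_count(self) -> float:
        return float(self.counts.sum())


@dataclass
class PhaseMap:
    """Condensed-region geometry plus per-phase densities and areas."""

    geometry: RegionGeometry            # condensed regions
    raster: RasterRegions               # same regions on the analysis grid
    sigma_c: float                      # counts/um^2
    sigma_d: float
    area_c: float                       # um^2
    area_d: float
    boundaries: list = field(default_factory=list)   # polygon vertex arrays
    degenerate: bool = False            # all-or-nothing threshold warning

    @property
    def ef(self) -> float:
        return self.sigma_c / self.sigma_d if self.sigma_d > 0 else np.inf

    def as_dict(self) -> dict:
        return {"sigma_c": self.sigma_c, "sigma_d": self.sigma_d,
                "EF": self.ef, "area_c": self.area_c, "area_d": self.area_d,
                "degenerate": self.degenerate}


def local_density(table: LocalizationTable, radius: float = DEFAULT_RADIUS,
                  cell_size: float = DEFAULT_CELL):
    """Per-localization density (neighbors within ``radius`` / disk area,
    the point itself included) and a smoothed grid density field."""
    if radius <= 0:
        raise ValueError("radius must be positive")
    if len(table) == 0:
        raise ValueError("empty localization table")
    xy = table.xy
    tree = cKDTree(xy)
    neighbor_counts = np.array(tree.query_ball_point(xy, radius, return_length=True))
    per_point = neighbor_counts / (np.pi * radius**2)

    (xmin, ymin), (xmax, ymax) = table.extent
    pad = radius
    origin = (xmin - pad, ymin - pad)
    nx = max(int(np.ceil((xmax - xmin + 2 * pad) / cell_size)), 1)
    ny = max(int(np.ceil((ymax - ymin + 2 * pad) / cell_size)), 1)
    counts, _, _ = np.histogram2d(
        xy[:, 1], xy[:, 0], bins=(ny, nx),
        range=[[origin[1], origin[1] + ny * cell_size],
               [origin[0], origin[0] + nx * cell_size]])
    density = gaussian_filter(counts, sigma=radius / cell_size) / cell_size**2
    field = DensityField(counts, density, origin, cell_size, radius)
    return per_point, field


def segment_phases(field: DensityField, threshold: str = "otsu",
                   threshold_value: Optional[float] = None,
                   min_area: float = MIN_REGION_AREA,
                   closing_radius: Optional[float] = None,
                   min_contrast: float = 5.0,
                   point_densities: Optional[np.ndarray] = None) -> PhaseMap:
    """Threshold the density field into condensed and dilute phases.

    Strategies: 'otsu' (on the log-density histogram of occupied cells,
    exploiting the bimodality of a two-phase scene, then refined to the
    midpoint of the two class medians so the contour of the smoothing-blurred
    density step lands on the true phase boundary), 'k-median' (threshold =
    ``threshold_value`` times the median nonzero density) or 'absolute'
    (``threshold_value`` in counts/um^2).  A field whose high/low class
    contrast falls below ``min_contrast`` is declared to have no condensed
    regions (degenerate flag).  The condensed mask is cleaned by
    morphological closing and a minimum-area filter; per-phase densities use
    the raw (unsmoothed) counts.
    """
    dens = field.density
    occupied = dens > 0
    if not occupied.any():
        raise ValueError("density field is empty")
    degenerate = False
    if threshold == "otsu":
        if point_densities is not None:
            # histogram over localizations, not grid cells: a sparse dilute
            # phase contributes one vote per molecule instead of being
            # swamped by near-empty cells
            pos = point_densities[point_densities > 0]
            vals = np.log10(pos if pos.size else np.array([1.0]))
        else:
            vals = np.log10(dens[occupied])
        thr = 10 ** threshold_otsu(vals)
        mask0 = dens > thr
        if mask0.any() and not mask0.all():
            med_hi = float(np.median(dens[mask0]))
            med_lo = float(np.median(dens[~mask0]))
            if med_hi < min_contrast * max(med_lo, 1e-12):
                degenerate = True   # no real two-phase contrast
            else:
                # half-way level: the blurred step crosses it at the edge
                thr = 0.5 * (med_hi + med_lo)
        else:
            degenerate = True
    elif threshold == "k-median":
        k = 10.0 if threshold_value is None else threshold_value
        thr = k * np.median(dens[occupied])
    elif threshold == "absolute":
        if threshold_value is None:
            raise ValueError("absolute strategy needs threshold_value")
        thr = threshold_value
    else:
        raise ValueError("unknown threshold strategy")

    if degenerate:
        mask = np.zeros_like(dens, dtype=bool)
    else:
        mask = dens > thr
        closing_radius = (field.smoothing_radius if closing_radius is None
                          else closing_radius)
        r_cells = max(int(round(closing_radius / field.cell_size)), 1)
        mask = morphology.closing(mask, morphology.disk(r_cells)).astype(bool)
        min_cells = max(int(round(min_area / field.cell_size**2)), 1)
        mask = morphology.remove_small_objects(mask, max_size=min_cells - 1)

    degenerate = degenerate or bool(mask.all() or not mask.any())
    area_cell = field.cell_size**2
    area_c = float(mask.sum()) * area_cell
    area_d = float((~mask).sum()) * area_cell
    n_c = float(field.counts[mask].sum())
    n_d = float(field.counts[~mask].sum())
    sigma_c = n_c / area_c if area_c > 0 else 0.0
    sigma_d = n_d / area_d if area_d > 0 else 0.0

    raster = RasterRegions(field.origin, field.cell_size, mask)
    boundaries = []
    for contour in measure.find_contours(mask.astype(float), 0.5):
        # contour rows are (row, col) = (y, x) in cell units
        verts = np.column_stack([
            field.origin[0] + (contour[:, 1] + 0.5) * field.cell_size,
            field.origin[1] + (contour[:, 0] + 0.5) * field.cell_size,
        ])
        boundaries.append(verts)
    return PhaseMap(raster, raster, sigma_c, sigma_d, area_c, area_d,
                    boundaries, degenerate)


def enrichment_from_localizations(table: LocalizationTable, pmap: PhaseMap,
                                  n_boot: int = 200, seed: int = 0):
    """Enrichment fold sigma_c/sigma_d recomputed from raw localizations on
    the phase map, with a bootstrap standard error over localizations."""
    inside = pmap.geometry.contains(table.xy)
    if pmap.area_d <= 0 or (~inside).sum() == 0:
        raise ValueError("empty dilute phase")
    n = len(table)

    def _ef(mask_in):
        n_c = mask_in.sum()
        return (n_c / pmap.area_c) / max(n - n_c, 1) * pmap.area_d

    ef = _ef(inside)
    rng = np.random.default_rng(seed)
    boots = np.empty(n_boot)
    for b in range(n_boot):
        take = rng.integers(0, n, n)
        boots[b] = _ef(inside[take])
    return float(ef), float(boots.std(ddof=1))


def segment_localizations(table: LocalizationTable,
                          radius: float = DEFAULT_RADIUS,
                          cell_size: float = DEFAULT_CELL,
                          **kwargs) -> PhaseMap:
    """Convenience: local_density + segment_phases in one call.

    The threshold histogram is built from per-localization densities (with
    the self-count removed) so that both phases are represented in
    proportion to their molecule counts.
    """
    per_point, field = local_density(table, radius=radius, cell_size=cell_size)
    corrected = per_point - 1.0 / (np.pi * radius**2)
    return segment_phases(field, point_densities=corrected, **kwargs)
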