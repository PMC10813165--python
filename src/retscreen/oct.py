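"""ETDRS outer-ring quadrant analysis of segmented OCT layer-thickness maps.

A thickness map is a 2-D grid of per-pixel layer thickness (um) with a
physical pixel pitch; the ETDRS grid (1/3/6 mm concentric rings by
default) is centred on the optic nerve head and the 3-6 mm outer ring
is split into superior / inferior / nasal / temporal quadrants by the
45-degree diagonals.  Quadrant means ignore missing pixels and feed the
same longitudinal statistics as the ERG measures.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .stats import MEASURE_COLUMNS

__all__ = ["ThicknessMap", "ETDRSSectors", "etdrs_quadrant_means", "oct_measure_table"]

QUADRANTS = ("superior", "inferior", "nasal", "temporal")


@dataclass
class ThicknessMap:
    """Segmented thickness grid for one layer of one eye.

    ``grid`` is thickness in micrometres with NaN marking missing
    pixels; ``pitch_mm`` is (row, column) physical pixel size;
    ``centre_px`` the (row, column) optic-nerve-head position in pixel
    coordinates (may be fractional).  Nasal/temporal assignment depends
    on the eye side: for OD (right eye) nasal is to the +column side,
    for OS it is mirrored.
    """

    grid: np.ndarray
    pitch_mm: tuple[float, float]
    centre_px: tuple[float, float]
    layer: str = "TRT"
    eye: str = "OD"

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=float)
        if self.grid.ndim != 2:
            raise ValueError("grid must be 2-D")
        if np.nanmin(self.grid, initial=0.0) < 0:
            raise ValueError("thickness values must be >= 0 (NaN marks missing)")
        if any(p <= 0 for p in self.pitch_mm):
            raise ValueError("pixel pitch must be positive")
        if self.eye not in ("OD", "OS"):
            raise ValueError("eye must be 'OD' or 'OS'")
        r, c = self.centre_px
        nr, nc = self.grid.shape
        if not (0 <= r <= nr - 1 and 0 <= c <= nc - 1):
            raise ValueError("centre_px must lie inside the map")


@dataclass
class ETDRSSectors:
    """Outer-ring quadrant means (um) with per-quadrant pixel coverage."""

    ring_diameters_mm: tuple[float, float, float]
    quadrant_means_um: dict[str, float]
    combined_mean_um: float
    coverage: dict[str, float]
    pixel_counts: dict[str, int]
    low_coverage: bool


def _quadrant_masks(m: ThicknessMap, ring_inner_mm: float, ring_outer_mm: float):
    nr, nc = m.grid.shape
    rows, cols = np.mgrid[0:nr, 0:nc]
    dy_mm = (rows - m.centre_px[0]) * m.pitch_mm[0]
    dx_mm = (cols - m.centre_px[1]) * m.pitch_mm[1]
    # Superior is up (smaller row index); mirror the horizontal axis for OS
    # so that 'nasal' always points to the nose.
    ypos = -dy_mm
    xpos = dx_mm if m.eye == "OD" else -dx_mm
    r = np.hypot(dx_mm, dy_mm)
    in_ring = (r >= ring_inner_mm / 2.0) & (r < ring_outer_mm / 2.0)
    theta = np.degrees(np.arctan2(ypos, xpos)) % 360.0
    masks = {
        "superior": in_ring & (theta >= 45.0) & (theta < 135.0),
        "temporal": in_ring & (theta >= 135.0) & (theta < 225.0),
        "inferior": in_ring & (theta >= 225.0) & (theta < 315.0),
        "nasal": in_ring & ((theta >= 315.0) | (theta < 45.0)),
    }
    return masks, in_ring


def etdrs_quadrant_means(
    m: ThicknessMap,
    ring_diameters_mm: tuple[float, float, float] = (1.0, 3.0, 6.0),
) -> ETDRSSectors:
    """Mean thickness per outer-ring quadrant and their combined mean.

    A pixel belongs to the outer ring iff ring_inner/2 <= distance from
    the centre < ring_outer/2 in physical units (half-open, so boundary
    pixels are counted once).  Missing (NaN) pixels are ignored; the
    combined mean weights quadrants by their valid pixel counts.  A
    result is flagged low-coverage when any quadrant has < 50 % of its
    ring pixels valid.
    """
    inner_excl, ring_inner, ring_outer = ring_diameters_mm
    if not (0 < inner_excl < ring_inner < ring_outer):
        raise ValueError("ring diameters must be increasing and positive")
    masks, in_ring = _quadrant_masks(m, ring_inner, ring_outer)
    if not in_ring.any():
        raise ValueError("the outer ring does not intersect the map")
    means: dict[str, float] = {}
    cov: dict[str, float] = {}
    counts: dict[str, int] = {}
    for name, mask in masks.items():
        vals = m.grid[mask]
        valid = vals[~np.isnan(vals)]
        total = int(mask.sum())
        counts[name] = valid.size
        cov[name] = valid.size / total if total else 0.0
        means[name] = float(valid.mean()) if valid.size else float("nan")
    total_n = sum(counts.values())
    if total_n == 0:
        raise ValueError("no valid pixels in the outer ring")
    combined = float(
        sum(means[q] * counts[q] for q in QUADRANTS if counts[q]) / total_n
    )
    return ETDRSSectors(
        ring_diameters_mm=tuple(ring_diameters_mm),
        quadrant_means_um=means,
        combined_mean_um=combined,
        coverage=cov,
        pixel_counts=counts,
        low_coverage=any(c < 0.5 for c in cov.values()),
    )


def oct_measure_table(
    inputs,
    metadata: Mapping | Sequence[Mapping] | None = None,
    ring_diameters_mm: tuple[float, float, float] = (1.0, 3.0, 6.0),
) -> pd.DataFrame:
    """Build a long measure table (one row per subject x time x layer).

    ``inputs`` is either an iterable of ``(ThicknessMap, metadata)``
    pairs — metadata carrying subject_id/genotype/treatment/time_min —
    or a pre-sectored DataFrame with columns (subject_id, genotype,
    treatment, time_min, layer, thickness_um).  For maps, the value is
    the combined outer-ring mean.
    """
    rows = []
    if isinstance(inputs, pd.DataFrame):
        required = {"subject_id", "genotype", "treatment", "time_min", "layer", "thickness_um"}
        missing = required - set(inputs.columns)
        if missing:
            raise ValueError(f"pre-sectored table missing columns {sorted(missing)}")
        if inputs.empty:
            raise ValueError("empty pre-sectored input")
        for r in inputs.itertuples(index=False):
            rows.append(
                {
                    "subject_id": r.subject_id,
                    "genotype": r.genotype,
                    "treatment": r.treatment,
                    "time_min": float(r.time_min),
                    "measure": r.layer,
                    "value": float(r.thickness_um),
                }
            )
    else:
        inputs = list(inputs)
        if not inputs:
            raise ValueError("no thickness maps supplied")
        for m, meta in inputs:
            sectors = etdrs_quadrant_means(m, ring_diameters_mm)
            rows.append(
                {
                    "subject_id": meta["subject_id"],
                    "genotype": meta["genotype"],
                    "treatment": meta["treatment"],
                    "time_min": float(meta["time_min"]),
                    "measure": m.layer,
                    "value": sectors.combined_mean_um,
                }
            )
    out = pd.DataFrame(rows, columns=list(MEASURE_COLUMNS))
    dup = out.duplicated(["subject_id", "time_min", "measure"])
    if dup.any():
        raise ValueError(
            f"duplicate subject/time/layer rows: {out.loc[dup, ['subject_id', 'time_min', 'measure']].values.tolist()}"
        )
    return out
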