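"""Standardized ROI definition and per-ROI statistics.

Phantom ROIs are 1-cm-diameter circles on the middle slice, one per vial,
with a voxel included iff its center lies within the circle.  Breast tumor
ROIs are the multislice generating mask.  ROI means are arithmetic means
over unmasked voxels only; masked exclusions are counted and reported, and
a fully masked ROI is flagged invalid rather than silently zeroed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Literal

import numpy as np
import pandas as pd

from .images import ParametricMap
from .synth import BreastSpec, PhantomSpec

ROI_DIAMETER_MM = 10.0


@dataclass
class ROISet:
    """Labeled voxel index sets on a fixed grid."""

    labels: dict[str, np.ndarray]      # label -> (n, 3) voxel indices
    grid: tuple[int, int, int]
    kind: Literal["multislice_tumor", "vial_circles"]

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for label, idx in self.labels.items():
            if label in seen:
                raise ValueError(f"duplicate ROI label {label!r}")
            seen.add(label)
            idx = np.asarray(idx, dtype=int)
            if idx.ndim != 2 or idx.shape[1] != 3:
                raise ValueError("ROI indices must be (n, 3)")
            if idx.size and (idx.min() < 0
                             or np.any(idx.max(axis=0) >= np.asarray(self.grid))):
                raise ValueError(f"ROI {label!r} exceeds the voxel grid")
            self.labels[label] = idx
        if self.kind == "vial_circles" and len(self.labels) != 13:
            raise ValueError("vial-circle ROI sets must have 13 ROIs")


@dataclass
class ROIStats:
    label: str
    mean: float
    n_voxels: int
    n_masked_excluded: int
    valid: bool = True


def make_vial_rois(spec: PhantomSpec, slice_index: int | None = None) -> ROISet:
    """One 1-cm-diameter circular ROI per vial on a single (middle) slice."""
    nz = spec.grid[0]
    if slice_index is None:
        slice_index = nz // 2
    if not 0 <= slice_index < nz:
        raise IndexError(f"slice {slice_index} outside stack of {nz}")
    dy, dx = spec.spacing[1], spec.spacing[2]
    ny, nx = spec.grid[1], spec.grid[2]
    rows, cols = np.mgrid[0:ny, 0:nx]
    radius = ROI_DIAMETER_MM / 2.0
    labels: dict[str, np.ndarray] = {}
    for vial in spec.vials:
        if radius > vial.radius_mm:
            warnings.warn(
                f"ROI circle (r={radius} mm) exceeds vial {vial.label} "
                f"(r={vial.radius_mm} mm): partial-volume contamination")
        r2 = ((rows - vial.center[0]) * dy) ** 2 + ((cols - vial.center[1]) * dx) ** 2
        rr, cc = np.nonzero(r2 <= radius ** 2)
        idx = np.column_stack([np.full(rr.size, slice_index), rr, cc])
        labels[vial.label] = idx
    return ROISet(labels=labels, grid=spec.grid, kind="vial_circles")


def make_tumor_roi(spec: BreastSpec, label: str = "tumor") -> ROISet:
    """Multislice tumor ROI: the generating mask itself."""
    idx = np.column_stack(np.nonzero(spec.tumor_mask))
    return ROISet(labels={label: idx}, grid=spec.grid, kind="multislice_tumor")


def apply_rois(map_: ParametricMap, rois: ROISet) -> list[ROIStats]:
    """Arithmetic mean over unmasked voxels per ROI, exclusions counted."""
    if map_.shape != rois.grid:
        raise ValueError("map and ROI set are on different grids")
    values = map_.canonical_values()   # raises if the unit scale is unknown
    out: list[ROIStats] = []
    for label, idx in rois.labels.items():
        z, y, x = idx[:, 0], idx[:, 1], idx[:, 2]
        inmask = map_.mask[z, y, x]
        n_total = idx.shape[0]
        n_used = int(inmask.sum())
        if n_used == 0:
            out.append(ROIStats(label=label, mean=np.nan, n_voxels=0,
                                n_masked_excluded=n_total, valid=False))
            continue
        mean = float(values[z, y, x][inmask].mean())
        out.append(ROIStats(label=label, mean=mean, n_voxels=n_used,
                            n_masked_excluded=n_total - n_used))
    return out


def stats_to_rows(stats: list[ROIStats], implementation: str, dataset: str,
                  metric: str) -> pd.DataFrame:
    """ROI stats -> measurement-table rows (long format)."""
    return pd.DataFrame(
        [{
            "implementation": implementation,
            "dataset": dataset,
            "roi": s.label,
            "metric": metric,
            "value": s.mean,
            "n_voxels": s.n_voxels,
            "n_masked_excluded": s.n_masked_excluded,
            "valid": s.valid,
        } for s in stats]
    )
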