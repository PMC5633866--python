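"""Core in-memory containers: multi-b DWI studies and scalar parametric maps.

Conventions
-----------
* Image arrays are indexed ``(slice, row, col)``; voxel spacing is
  ``(dz, dy, dx)`` in millimetres.
* A :class:`DWIStudy` holds one image per (b-value, diffusion direction).
  The unweighted (b = 0) image always has exactly one "direction"; non-zero
  b-values carry either three orthogonal directional images or a single
  direction-averaged trace image.
* Parametric-map values are stored together with a ``rescale_factor``:
  ``stored_value * rescale_factor`` is the value in canonical units of
  1e-6 mm^2/s (the common unit for ADC maps in multisite pooling).
  ``rescale_factor=None`` means the scale is unknown and must be detected
  against a reference before quantitative use.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field
from typing import Any

import numpy as np

#: canonical unit for ADC parametric maps, in mm^2/s
CANONICAL_UNIT = 1e-6

VALID_METRICS = ("ADC2", "ADC4", "ADChi-low", "ADCslow", "PerfFrac")


@dataclass
class DWIStudy:
    """A multi-b-value diffusion-weighted image stack.

    Parameters
    ----------
    images
        Mapping ``b-value -> array`` of shape ``(n_directions, nz, ny, nx)``.
    b_values
        Sorted ascending, must include 0 for most downstream metrics.
    spacing
        Voxel spacing ``(dz, dy, dx)`` in mm.
    orientation
        Free-text stack orientation (``"axial"``, ``"coronal"`` ...).
    metadata
        Study label, generator seed, intensity rescale factor, etc.
    truth
        Optional reference to the generating specification (ground truth).
    """

    images: dict[float, np.ndarray]
    b_values: tuple[float, ...]
    spacing: tuple[float, float, float] = (4.0, 1.0, 1.0)
    orientation: str = "axial"
    metadata: dict[str, Any] = field(default_factory=dict)
    truth: Any = None

    def __post_init__(self) -> None:
        self.b_values = tuple(float(b) for b in self.b_values)
        if list(self.b_values) != sorted(self.b_values):
            raise ValueError("b_values must be sorted ascending")
        if set(self.images) != set(self.b_values):
            raise ValueError("images must carry exactly one entry per b-value")
        shapes = set()
        for b, arr in self.images.items():
            arr = np.asarray(arr, dtype=float)
            if arr.ndim != 4:
                raise ValueError(
                    f"image for b={b} must be (n_dir, nz, ny, nx), got ndim={arr.ndim}"
                )
            self.images[b] = arr
            shapes.add(arr.shape[1:])
        if len(shapes) != 1:
            raise ValueError("all images must share one voxel grid")
        if 0.0 in self.images and self.images[0.0].shape[0] != 1:
            raise ValueError("the b=0 image must have exactly one direction")

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return next(iter(self.images.values())).shape[1:]

    @property
    def n_directions(self) -> int:
        """Direction count of the non-zero-b images (1 = trace)."""
        for b in self.b_values:
            if b > 0:
                return self.images[b].shape[0]
        return 1

    @property
    def is_trace(self) -> bool:
        return self.n_directions == 1

    def signal(self, b: float) -> np.ndarray:
        """Single-direction (trace) image at ``b``; requires is_trace or b=0."""
        arr = self.images[float(b)]
        if arr.shape[0] != 1:
            raise ValueError(f"b={b} holds {arr.shape[0]} directions, not a trace")
        return arr[0]

    def stacked_signals(self) -> np.ndarray:
        """Trace signals stacked as ``(n_b, nz, ny, nx)`` in b order."""
        return np.stack([self.signal(b) for b in self.b_values])

    def copy(self) -> "DWIStudy":
        return DWIStudy(
            images={b: a.copy() for b, a in self.images.items()},
            b_values=self.b_values,
            spacing=self.spacing,
            orientation=self.orientation,
            metadata=copy.deepcopy(self.metadata),
            truth=self.truth,
        )


@dataclass
class ParametricMap:
    """One scalar voxel map (ADC in 1e-6 mm^2/s, or dimensionless Pf) + mask.

    ``values * rescale_factor`` is the map in canonical units; masked voxels
    are excluded from all ROI statistics and conventionally stored as 0.
    """

    values: np.ndarray
    mask: np.ndarray
    metric: str
    method: str | None = None
    rescale_factor: float | None = 1.0
    spacing: tuple[float, float, float] = (4.0, 1.0, 1.0)
    metadata: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.values.ndim != 3:
            raise ValueError("map values must be a 3-D (nz, ny, nx) array")
        if self.mask.shape != self.values.shape:
            raise ValueError("mask shape must match values shape")
        if self.metric not in VALID_METRICS:
            raise ValueError(
                f"unknown metric {self.metric!r}; expected one of {VALID_METRICS}"
            )
        if self.rescale_factor is not None and self.rescale_factor <= 0:
            raise ValueError("rescale_factor must be positive")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    def canonical_values(self) -> np.ndarray:
        """Values in canonical units (1e-6 mm^2/s for ADC metrics)."""
        if self.rescale_factor is None:
            raise ValueError(
                "rescale factor unknown; run scale detection before quantitative use"
            )
        return self.values * self.rescale_factor

    def copy(self) -> "ParametricMap":
        return ParametricMap(
            values=self.values.copy(),
            mask=self.mask.copy(),
            metric=self.metric,
            method=self.method,
            rescale_factor=self.rescale_factor,
            spacing=self.spacing,
            metadata=copy.deepcopy(self.metadata),
        )


def maps_congruent(a: ParametricMap, b: ParametricMap) -> bool:
    """True when two maps live on the same voxel grid."""
    return a.shape == b.shape
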