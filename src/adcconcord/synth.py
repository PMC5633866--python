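"""Synthetic multi-b DWI studies with known ground truth.

Two study families are generated:

* a 13-vial PVP diffusion phantom (ice-water controlled, coronal stack) whose
  vials span true ADC values from ~1.1e-3 mm^2/s (water) down to
  ~0.12e-3 mm^2/s (50% PVP mass fraction), imaged at b = {0, 500, 900, 2000}
  s/mm^2;
* an in-vivo-like breast tumor study whose signal carries a slow (tissue)
  monoexponential component plus a fast-decaying pseudo-diffusion (perfusion)
  component, imaged at b = {0, 800} or b = {0, 100, 600, 800} s/mm^2.

Non-zero b-values are simulated with three orthogonal diffusion-encoding
directions (isotropic media, so the three directional signals are identical
before noise); trace images are the geometric mean over directions, matching
standard on-scanner reconstruction.  Magnitude noise is Rician:
``M = sqrt((A + g1)^2 + g2^2)`` with i.i.d. Gaussian channels.

The module also reproduces the metadata pathologies seen when parametric maps
cross institutional boundaries: a lost intensity-rescale factor, a reversed
slice order, and not-a-number pixels.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
from scipy import ndimage

from .images import DWIStudy, ParametricMap

PHANTOM_B_VALUES = (0.0, 500.0, 900.0, 2000.0)
BREAST_B_VALUES_4 = (0.0, 100.0, 600.0, 800.0)
BREAST_B_VALUES_2 = (0.0, 800.0)

#: paper-anchored endpoints of the phantom true-ADC range, mm^2/s
ADC_WATER = 1.1e-3     # 0% PVP
ADC_PVP50 = 0.12e-3    # 50% PVP mass fraction

#: default b=0 signal-to-noise ratios (s0 / sigma)
PHANTOM_SNR = 100.0
BREAST_SNR = 30.0


def pvp_true_adc(mass_fraction_pct: float) -> float:
    """True ADC for a PVP mass fraction, log-linear between the endpoints.

    0% -> 1.1e-3 mm^2/s (water at 0 degC), 50% -> 0.12e-3 mm^2/s.
    """
    f = float(mass_fraction_pct)
    if not 0.0 <= f <= 50.0:
        raise ValueError("PVP mass fraction must be in [0, 50] %")
    return ADC_WATER * (ADC_PVP50 / ADC_WATER) ** (f / 50.0)


@dataclass(frozen=True)
class Vial:
    label: str
    center: tuple[float, float]   # (row, col) in voxels
    radius_mm: float


@dataclass
class PhantomSpec:
    """Geometry + ground truth for the 13-vial PVP phantom."""

    vials: tuple[Vial, ...]
    pvp_fractions: tuple[float, ...]          # per-vial mass fraction, %
    true_adc: tuple[float, ...]               # per-vial, mm^2/s
    s0: float = 1000.0
    grid: tuple[int, int, int] = (3, 128, 128)
    spacing: tuple[float, float, float] = (4.0, 1.0, 1.0)
    b_values: tuple[float, ...] = PHANTOM_B_VALUES

    def __post_init__(self) -> None:
        if len(self.vials) != 13:
            raise ValueError("phantom must have 13 vials")
        if not (len(self.pvp_fractions) == len(self.true_adc) == len(self.vials)):
            raise ValueError("per-vial fields must have one entry per vial")
        if any(a <= 0 for a in self.true_adc):
            raise ValueError("true ADC must be strictly positive")
        for (fi, ai) in zip(self.pvp_fractions, self.true_adc):
            for (fj, aj) in zip(self.pvp_fractions, self.true_adc):
                if fi > fj and not ai < aj:
                    raise ValueError(
                        "true ADC must decrease monotonically with PVP fraction"
                    )
        bs = tuple(float(b) for b in self.b_values)
        if list(bs) != sorted(bs) or 0.0 not in bs:
            raise ValueError("b_values must be ascending and include 0")
        self.b_values = bs
        # overlapping vials make the ground truth ambiguous
        dy, dx = self.spacing[1], self.spacing[2]
        for i, vi in enumerate(self.vials):
            for vj in self.vials[i + 1:]:
                d = np.hypot((vi.center[0] - vj.center[0]) * dy,
                             (vi.center[1] - vj.center[1]) * dx)
                if d < vi.radius_mm + vj.radius_mm:
                    raise ValueError(f"vials {vi.label} and {vj.label} overlap")

    @property
    def n_slices(self) -> int:
        return self.grid[0]


def default_phantom_spec(
    s0: float = 1000.0,
    b_values: Sequence[float] = PHANTOM_B_VALUES,
    vial_radius_mm: float = 9.0,
) -> PhantomSpec:
    """13 vials: one central water vial, 4 on an inner ring, 8 on an outer ring.

    Water (0% PVP) fills the centre vial and two ring vials; fractions
    10-50% appear twice each, mirroring the physical phantom layout.
    """
    nz, ny, nx = 3, 128, 128
    c = (ny - 1) / 2.0
    centers: list[tuple[float, float]] = [(round(c), round(c))]
    # centers snap to whole voxels, as on a positioning grid
    for k in range(4):                       # inner ring, radius 26 mm
        th = 2 * np.pi * k / 4 + np.pi / 4
        centers.append((round(c + 26.0 * np.sin(th)), round(c + 26.0 * np.cos(th))))
    for k in range(8):                       # outer ring, radius 48 mm
        th = 2 * np.pi * k / 8
        centers.append((round(c + 48.0 * np.sin(th)), round(c + 48.0 * np.cos(th))))
    fractions = (0.0, 0.0, 0.0, 10.0, 10.0, 20.0, 20.0, 30.0,
                 30.0, 40.0, 40.0, 50.0, 50.0)
    position = ["C", "I", "I", "I", "I", "O", "O", "O", "O", "O", "O", "O", "O"]
    vials = tuple(
        Vial(label=f"{int(f)}%{p}{i}", center=centers[i], radius_mm=vial_radius_mm)
        for i, (f, p) in enumerate(zip(fractions, position))
    )
    return PhantomSpec(
        vials=vials,
        pvp_fractions=fractions,
        true_adc=tuple(pvp_true_adc(f) for f in fractions),
        s0=s0,
        grid=(nz, ny, nx),
        b_values=tuple(b_values),
    )


@dataclass
class BreastSpec:
    """Voxelwise ground truth for a synthetic breast tumor DWI study.

    The signal model in tumor voxels is

        S(b) = s0 * [(1 - Pf) * exp(-b * ADCslow) + Pf * exp(-b * Dfast)]

    with a slow (tissue) diffusion coefficient field, a perfusion-fraction
    field Pf in [0, 1), and a single fast pseudo-diffusion coefficient Dfast
    large enough that the fast component is negligible for b >= 100 s/mm^2.
    """

    tumor_mask: np.ndarray                   # bool (nz, ny, nx)
    adc_slow_field: np.ndarray               # mm^2/s
    perf_fraction_field: np.ndarray          # dimensionless in [0, 1)
    d_fast: float = 0.05                     # mm^2/s
    s0: float = 600.0
    b_values: tuple[float, ...] = BREAST_B_VALUES_4
    spacing: tuple[float, float, float] = (4.0, 1.5, 1.5)

    def __post_init__(self) -> None:
        self.tumor_mask = np.asarray(self.tumor_mask, dtype=bool)
        self.adc_slow_field = np.asarray(self.adc_slow_field, dtype=float)
        self.perf_fraction_field = np.asarray(self.perf_fraction_field, dtype=float)
        if not (self.tumor_mask.shape == self.adc_slow_field.shape
                == self.perf_fraction_field.shape):
            raise ValueError("truth fields must share the tumor-mask grid")
        pf = self.perf_fraction_field[self.tumor_mask]
        if pf.size and (pf.min() < 0 or pf.max() >= 1):
            raise ValueError("perfusion fraction must lie in [0, 1)")
        adc = self.adc_slow_field[self.tumor_mask]
        if adc.size and adc.min() <= 0:
            raise ValueError("slow ADC field must be strictly positive")
        if adc.size and self.d_fast <= adc.max():
            raise ValueError("d_fast must exceed the slow ADC everywhere")
        bs = tuple(float(b) for b in self.b_values)
        if list(bs) != sorted(bs) or 0.0 not in bs:
            raise ValueError("b_values must be ascending and include 0")
        self.b_values = bs

    @property
    def grid(self) -> tuple[int, int, int]:
        return self.tumor_mask.shape


def _smooth_field(rng: np.random.Generator, shape, mean, sd, lo, hi,
                  smooth_vox=(0.5, 2.0, 2.0)) -> np.ndarray:
    # short correlation length along the slice axis: thick slices sample
    # nearly independent tissue, so anatomy varies slice to slice
    raw = rng.standard_normal(shape)
    sm = ndimage.gaussian_filter(raw, sigma=smooth_vox)
    sm = (sm - sm.mean()) / sm.std()
    return np.clip(mean + sd * sm, lo, hi)


def default_breast_spec(
    seed: int = 0,
    b_values: Sequence[float] = BREAST_B_VALUES_4,
    shape: tuple[int, int, int] = (4, 48, 48),
    s0: float = 600.0,
    d_fast: float = 0.05,
) -> BreastSpec:
    """A multislice ellipsoidal tumor with smooth heterogeneous truth fields.

    ADCslow is a smoothed Gaussian random field clipped to [0.8, 2.2]e-3
    mm^2/s; Pf a smooth field clipped to [0.02, 0.35].  ``seed`` makes the
    virtual patient reproducible.
    """
    rng = np.random.default_rng(seed)
    nz, ny, nx = shape
    zz, yy, xx = np.mgrid[0:nz, 0:ny, 0:nx]
    # off-center along the slice axis: tumors do not straddle the stack
    # symmetrically, and the asymmetric footprint is what makes automatic
    # slice-order detection possible
    cz, cy, cx = 0.38 * (nz - 1), (ny - 1) / 2.0, (nx - 1) / 2.0
    mask = (((zz - cz) / (0.55 * nz)) ** 2
            + ((yy - cy) / (0.30 * ny)) ** 2
            + ((xx - cx) / (0.30 * nx)) ** 2) <= 1.0
    adc = _smooth_field(rng, shape, mean=1.4e-3, sd=0.25e-3, lo=0.8e-3, hi=2.2e-3)
    pf = _smooth_field(rng, shape, mean=0.12, sd=0.05, lo=0.02, hi=0.35)
    return BreastSpec(
        tumor_mask=mask,
        adc_slow_field=adc,
        perf_fraction_field=pf,
        d_fast=d_fast,
        s0=s0,
        b_values=tuple(b_values),
    )


@dataclass(frozen=True)
class NoiseModel:
    """Magnitude-noise description: ``none`` or Rician with channel sigma."""

    kind: Literal["none", "rician"] = "rician"
    sigma: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in ("none", "rician"):
            raise ValueError("noise kind must be 'none' or 'rician'")
        if self.sigma < 0:
            raise ValueError("sigma must be non-negative")


# ---------------------------------------------------------------------------
# study generation

def phantom_truth_map(spec: PhantomSpec) -> np.ndarray:
    """Per-voxel true ADC (mm^2/s), 0 outside the vials."""
    nz, ny, nx = spec.grid
    dy, dx = spec.spacing[1], spec.spacing[2]
    rows, cols = np.mgrid[0:ny, 0:nx]
    plane = np.zeros((ny, nx))
    for vial, adc in zip(spec.vials, spec.true_adc):
        r2 = ((rows - vial.center[0]) * dy) ** 2 + ((cols - vial.center[1]) * dx) ** 2
        plane[r2 <= vial.radius_mm ** 2] = adc
    return np.broadcast_to(plane, (nz, ny, nx)).copy()


def make_phantom(spec: PhantomSpec) -> DWIStudy:
    """Noiseless directional phantom study: S(b) = s0 exp(-b ADC) per vial."""
    adc = phantom_truth_map(spec)
    inside = adc > 0
    images: dict[float, np.ndarray] = {}
    for b in spec.b_values:
        plane = np.where(inside, spec.s0 * np.exp(-b * adc), 0.0)
        ndir = 1 if b == 0 else 3
        images[b] = np.repeat(plane[None], ndir, axis=0)
    return DWIStudy(
        images=images,
        b_values=spec.b_values,
        spacing=spec.spacing,
        orientation="coronal",
        metadata={"label": "phantom", "rescale": 1.0},
        truth=spec,
    )


def make_breast(spec: BreastSpec) -> DWIStudy:
    """Noiseless directional breast study with slow + fast signal components."""
    images: dict[float, np.ndarray] = {}
    m = spec.tumor_mask
    pf = spec.perf_fraction_field
    for b in spec.b_values:
        decay = (1 - pf) * np.exp(-b * spec.adc_slow_field) \
            + pf * np.exp(-b * spec.d_fast)
        plane = np.where(m, spec.s0 * decay, 0.0)
        ndir = 1 if b == 0 else 3
        images[b] = np.repeat(plane[None], ndir, axis=0)
    return DWIStudy(
        images=images,
        b_values=spec.b_values,
        spacing=spec.spacing,
        orientation="axial",
        metadata={"label": "breast", "rescale": 1.0},
        truth=spec,
    )


def rician_sample(rng: np.random.Generator, amplitude: np.ndarray,
                  sigma: float) -> np.ndarray:
    """Magnitude of (A + g1) + i g2 with g1, g2 ~ N(0, sigma^2)."""
    g1 = rng.normal(0.0, sigma, size=np.shape(amplitude))
    g2 = rng.normal(0.0, sigma, size=np.shape(amplitude))
    return np.sqrt((amplitude + g1) ** 2 + g2 ** 2)


def add_noise(study: DWIStudy, nm: NoiseModel) -> DWIStudy:
    """Independent Rician noise per (b, direction) image; seed-reproducible."""
    if nm.kind == "none" or nm.sigma == 0.0:
        return study.copy()
    rng = np.random.default_rng(nm.seed)
    out = study.copy()
    for b in out.b_values:          # fixed order -> bit-identical under a seed
        out.images[b] = rician_sample(rng, out.images[b], nm.sigma)
    out.metadata["noise"] = {"kind": nm.kind, "sigma": nm.sigma, "seed": nm.seed}
    return out


def snr_sigma(s0: float, snr: float) -> float:
    """Gaussian channel sigma for a target b=0 SNR = s0 / sigma."""
    if snr <= 0:
        raise ValueError("SNR must be positive")
    return s0 / snr


def compute_trace(study: DWIStudy) -> DWIStudy:
    """Direction-averaged (trace) study: geometric mean over the 3 directions.

    b = 0 passes through unchanged.  Voxels with a negative directional value
    (impossible for magnitude data, possible after corruption) become NaN and
    are masked by downstream fitting.
    """
    images: dict[float, np.ndarray] = {}
    for b in study.b_values:
        arr = study.images[b]
        if b == 0 or arr.shape[0] == 1:
            images[b] = arr[:1].copy()
            continue
        if arr.shape[0] != 3:
            raise ValueError("trace reconstruction needs 3 directional images")
        with np.errstate(invalid="ignore"):
            gm = np.cbrt(arr[0] * arr[1] * arr[2])
        gm[np.any(arr < 0, axis=0)] = np.nan
        images[b] = gm[None]
    out = DWIStudy(
        images=images,
        b_values=study.b_values,
        spacing=study.spacing,
        orientation=study.orientation,
        metadata={**study.metadata, "trace": True},
        truth=study.truth,
    )
    return out


# ---------------------------------------------------------------------------
# metadata pathologies

CorruptMode = Literal["drop_rescale", "reverse_slices", "inject_nan"]


def corrupt(obj: DWIStudy | ParametricMap, mode: CorruptMode, *,
            count: int | None = None, seed: int = 0):
    """Apply one of the metadata/data pathologies seen in multisite pooling.

    ``drop_rescale``
        The stored unit-rescale factor is lost (set to 1) while pixel values
        keep their original scaling — a naive ROI mean is then off by the
        true factor until the scale is re-detected.
    ``reverse_slices``
        The slice axis is inverted while the metadata still claims stored
        order (an involution).
    ``inject_nan``
        Exactly ``count`` randomly chosen voxels become not-a-number.
    """
    out = obj.copy()
    if mode == "drop_rescale":
        if isinstance(out, ParametricMap):
            out.metadata["true_rescale"] = out.rescale_factor
            out.rescale_factor = 1.0
        else:
            out.metadata["true_rescale"] = out.metadata.get("rescale", 1.0)
            out.metadata["rescale"] = 1.0
        return out
    if mode == "reverse_slices":
        if isinstance(out, ParametricMap):
            out.values = out.values[::-1].copy()
            out.mask = out.mask[::-1].copy()
        else:
            for b in out.b_values:
                out.images[b] = out.images[b][:, ::-1].copy()
        return out
    if mode == "inject_nan":
        if count is None or count < 0:
            raise ValueError("inject_nan needs a non-negative count")
        rng = np.random.default_rng(seed)
        if isinstance(out, ParametricMap):
            flat = out.values.reshape(-1)
            idx = rng.choice(flat.size, size=count, replace=False)
            flat[idx] = np.nan
        else:
            sizes = [out.images[b].size for b in out.b_values]
            total = int(np.sum(sizes))
            idx = rng.choice(total, size=count, replace=False)
            offset = 0
            for b, n in zip(out.b_values, sizes):
                sel = idx[(idx >= offset) & (idx < offset + n)] - offset
                out.images[b].reshape(-1)[sel] = np.nan
                offset += n
        return out
    raise ValueError(f"unknown corruption mode {mode!r}")
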