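"""Parametric-map harmonization and interchange.

Replicates the centralized pre-analysis applied when parametric maps from
many sites are pooled: automatic unit-scale detection against a reference
map (snapping to integer powers of ten, covering the common 1e-3 vs 1e-6
mm^2/s conventions), automatic slice-order detection for formats without
orientation metadata, and not-a-number sanitization.  Map pixel data are
never altered beyond these corrections.

Interchange formats: NIfTI-1 (canonical), NRRD (raw encoding), and DICOM
series (read-only, honoring RescaleSlope/RescaleIntercept).  A JSON sidecar
carries metric name, fit method, rescale factor and provenance for the
writable formats; the analysis mask travels as a companion volume.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import nibabel as nib
import numpy as np

from . import _nrrd
from .images import ParametricMap, maps_congruent


class HarmonizationError(ValueError):
    """Raised when a harmonization step is undecidable."""


@dataclass(frozen=True)
class MapMetadata:
    """Harmonization-relevant metadata for a stored map."""

    rescale_factor: float | None
    slice_order: str = "as_stored"        # or "reversed"
    source_format: str = "nifti"
    notes: tuple[str, ...] = ()


# ---------------------------------------------------------------------------
# harmonization steps

def detect_scale(map_: ParametricMap, reference: ParametricMap) -> float:
    """Power-of-ten factor bringing ``map_`` onto the reference's unit scale.

    Computes the median ratio reference/map over jointly unmasked, positive
    voxels and snaps its log10 to the nearest integer k, returning 10**k.
    The reference must already be in canonical units.
    """
    if not maps_congruent(map_, reference):
        raise ValueError("maps must cover the same voxel grid")
    joint = (map_.mask & reference.mask
             & (map_.values > 0) & (reference.values > 0)
             & np.isfinite(map_.values) & np.isfinite(reference.values))
    if not joint.any():
        raise HarmonizationError("scale undecidable: no usable overlapping voxels")
    ratio = reference.values[joint] / map_.values[joint]
    k = int(np.round(np.log10(np.median(ratio))))
    return float(10.0 ** k)


def apply_scale(map_: ParametricMap, factor: float) -> ParametricMap:
    """Multiply values by ``factor``; the result is declared canonical."""
    out = map_.copy()
    out.values = out.values * factor
    out.rescale_factor = 1.0
    out.metadata.setdefault("notes", []).append(f"scaled by {factor:g}")
    return out


def detect_slice_order(map_: ParametricMap, reference: ParametricMap) -> str:
    """``"as_stored"`` or ``"reversed"``: the order maximizing voxelwise
    rank (Spearman) correlation with the reference.  Rank correlation keeps
    the heavy-tailed values that fits produce in pure-noise background from
    swamping the anatomical agreement.  A tie (slice-symmetric volume) keeps
    stored order with a warning."""
    if not maps_congruent(map_, reference):
        raise ValueError("maps must cover the same voxel grid")
    if map_.shape[0] < 2:
        raise ValueError("slice-order detection needs at least 2 slices")

    def corr(vals, msk):
        joint = msk & reference.mask & np.isfinite(vals) & np.isfinite(reference.values)
        if joint.sum() < 2:
            return -np.inf
        a = vals[joint]
        b = reference.values[joint]
        if a.std() == 0 or b.std() == 0:
            return -np.inf
        from scipy import stats as sps
        return float(sps.spearmanr(a, b).statistic)

    c_fwd = corr(map_.values, map_.mask)
    c_rev = corr(map_.values[::-1], map_.mask[::-1])
    if c_fwd == c_rev:
        warnings.warn("slice order undecidable (symmetric volume); keeping stored order")
        return "as_stored"
    return "as_stored" if c_fwd > c_rev else "reversed"


def apply_slice_order(map_: ParametricMap, order: str) -> ParametricMap:
    if order == "as_stored":
        return map_.copy()
    if order != "reversed":
        raise ValueError(f"unknown slice order {order!r}")
    out = map_.copy()
    out.values = out.values[::-1].copy()
    out.mask = out.mask[::-1].copy()
    out.metadata.setdefault("notes", []).append("slice order reversed")
    return out


def sanitize(map_: ParametricMap) -> ParametricMap:
    """Reassign non-finite voxels to 0.0 and mask them out; count recorded.

    No other pixel is altered.
    """
    out = map_.copy()
    bad = ~np.isfinite(out.values)
    out.values[bad] = 0.0
    out.mask &= ~bad
    out.metadata["n_sanitized"] = int(bad.sum()) + int(out.metadata.get("n_sanitized", 0))
    return out


def harmonize(map_: ParametricMap, reference: ParametricMap | None = None) -> ParametricMap:
    """Full centralized pre-analysis: sanitize, rescale, fix slice order.

    With a reference map the unit scale and slice order are detected
    automatically; a detected scale disagreeing with the stored rescale
    factor is corrected and loudly reported (metadata corruption is a known
    failure mode of multisite map exchange, never silently absorbed).
    Idempotent: harmonizing a harmonized map is the identity.
    """
    out = sanitize(map_)
    if reference is not None:
        f = detect_scale(out, reference)
        stored = out.rescale_factor
        if stored is None:
            warnings.warn(f"rescale factor unknown; detected {f:g} from reference")
        elif not np.isclose(f, stored):
            warnings.warn(
                f"stored rescale factor {stored:g} contradicts detected {f:g}; "
                "using detected value (possible metadata corruption)")
        out = apply_scale(out, f)
        order = detect_slice_order(out, reference)
        out = apply_slice_order(out, order)
    else:
        if out.rescale_factor is None:
            raise HarmonizationError(
                "rescale factor unknown and no reference supplied")
        if out.rescale_factor != 1.0:
            out = apply_scale(out, out.rescale_factor)
    out.metadata["harmonized"] = True
    return out


# ---------------------------------------------------------------------------
# format I/O

def _sidecar(map_: ParametricMap) -> dict:
    return {
        "metric": map_.metric,
        "method": map_.method,
        "rescale_factor": map_.rescale_factor,
        "spacing": list(map_.spacing),
        "metadata": {k: v for k, v in map_.metadata.items()
                     if isinstance(v, (str, int, float, bool, list, type(None)))},
    }


def _from_sidecar(values, sc: dict, mask, source_format: str) -> ParametricMap:
    if mask is None:
        mask = np.isfinite(values)
    return ParametricMap(
        values=values,
        mask=mask,
        metric=sc.get("metric", "ADC4"),
        method=sc.get("method"),
        rescale_factor=sc.get("rescale_factor"),
        spacing=tuple(sc.get("spacing", (4.0, 1.0, 1.0))),
        metadata={**sc.get("metadata", {}), "source_format": source_format},
    )


def _stem(path: Path) -> Path:
    name = path.name
    for suf in (".nii.gz", ".nii", ".nrrd"):
        if name.endswith(suf):
            return path.with_name(name[: -len(suf)])
    return path.with_suffix("")


def write_map(map_: ParametricMap, path) -> None:
    """Write a map (+mask +JSON sidecar) as NIfTI or NRRD, by extension."""
    path = Path(path)
    stem = _stem(path)
    if path.name.endswith((".nii", ".nii.gz")):
        affine = np.diag([map_.spacing[2], map_.spacing[1], map_.spacing[0], 1.0])
        # nibabel is (x, y, z); store as (col, row, slice)
        nib.save(nib.Nifti1Image(map_.values.T.astype(np.float32), affine), str(path))
        nib.save(nib.Nifti1Image(map_.mask.T.astype(np.uint8), affine),
                 str(stem) + "_mask" + path.name[len(stem.name):])
    elif path.name.endswith(".nrrd"):
        _nrrd.write_nrrd(path, map_.values.astype(np.float32),
                         spacings=map_.spacing,
                         key_values={"adcconcord metric": map_.metric})
        _nrrd.write_nrrd(str(stem) + "_mask.nrrd", map_.mask.astype(np.uint8),
                         spacings=map_.spacing)
    else:
        raise ValueError(f"unsupported output format for {path.name!r}")
    with open(str(stem) + ".json", "w") as fh:
        json.dump(_sidecar(map_), fh, indent=1)


def read_map(path) -> ParametricMap:
    """Read a map written by :func:`write_map` (NIfTI or NRRD)."""
    path = Path(path)
    stem = _stem(path)
    sc_path = Path(str(stem) + ".json")
    sc = json.loads(sc_path.read_text()) if sc_path.exists() else {}
    if path.name.endswith((".nii", ".nii.gz")):
        img = nib.load(str(path))
        values = np.asarray(img.dataobj, dtype=np.float32).T.astype(float)
        mask_path = Path(str(stem) + "_mask" + path.name[len(stem.name):])
        mask = None
        if mask_path.exists():
            mask = np.asarray(nib.load(str(mask_path)).dataobj).T.astype(bool)
        return _from_sidecar(values, sc, mask, "nifti")
    if path.name.endswith(".nrrd"):
        values, _, _ = _nrrd.read_nrrd(path)
        values = values.astype(float)
        mask_path = Path(str(stem) + "_mask.nrrd")
        mask = None
        if mask_path.exists():
            mask = _nrrd.read_nrrd(mask_path)[0].astype(bool)
        return _from_sidecar(values, sc, mask, "nrrd")
    raise ValueError(f"unsupported input format for {path.name!r}")


def write_study(study, directory) -> None:
    """Write a DWI study as one NIfTI volume per (b, direction) + sidecar."""
    from .images import DWIStudy  # noqa: F401  (typing aid only)

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    frames = []
    for b in study.b_values:
        arr = study.images[b]
        for d in range(arr.shape[0]):
            name = f"b{int(b):04d}_dir{d}.nii.gz"
            affine = np.diag([study.spacing[2], study.spacing[1],
                              study.spacing[0], 1.0])
            nib.save(nib.Nifti1Image(arr[d].T.astype(np.float32), affine),
                     str(directory / name))
            frames.append({"b": b, "direction": d, "file": name})
    sidecar = {
        "b_values": list(study.b_values),
        "n_directions": study.n_directions,
        "spacing": list(study.spacing),
        "orientation": study.orientation,
        "frames": frames,
        "metadata": {k: v for k, v in study.metadata.items()
                     if isinstance(v, (str, int, float, bool, list, dict,
                                       type(None)))},
    }
    (directory / "study.json").write_text(json.dumps(sidecar, indent=1))


def read_study(directory):
    """Read a study written by :func:`write_study`."""
    from .images import DWIStudy

    directory = Path(directory)
    sc = json.loads((directory / "study.json").read_text())
    images: dict[float, np.ndarray] = {}
    for fr in sc["frames"]:
        arr = np.asarray(nib.load(str(directory / fr["file"])).dataobj,
                         dtype=np.float32).T.astype(float)
        images.setdefault(float(fr["b"]), []).append(arr)
    images = {b: np.stack(v) for b, v in images.items()}
    return DWIStudy(
        images=images,
        b_values=tuple(sc["b_values"]),
        spacing=tuple(sc["spacing"]),
        orientation=sc.get("orientation", "axial"),
        metadata=sc.get("metadata", {}),
    )


def read_dicom_series(directory, metric: str = "ADC4") -> ParametricMap:
    """Read a single-frame DICOM series as a map (read-only support).

    Slices are ordered by InstanceNumber; RescaleSlope/RescaleIntercept are
    multiplied through on read.  Whether the resulting values are in
    canonical units is unknowable from the slope alone, so the rescale
    factor is recorded as unknown unless the series carried no slope (then
    left unknown too): run :func:`detect_scale` before ROI analysis.
    """
    import pydicom

    files = sorted(Path(directory).glob("*.dcm"))
    if not files:
        raise ValueError(f"no DICOM files in {directory}")
    datasets = [pydicom.dcmread(str(f)) for f in files]
    datasets.sort(key=lambda d: int(getattr(d, "InstanceNumber", 0)))
    slices = []
    spacing = (4.0, 1.0, 1.0)
    for ds in datasets:
        arr = ds.pixel_array.astype(float)
        slope = float(getattr(ds, "RescaleSlope", 1.0))
        intercept = float(getattr(ds, "RescaleIntercept", 0.0))
        slices.append(arr * slope + intercept)
        if hasattr(ds, "PixelSpacing"):
            st = float(getattr(ds, "SliceThickness", 4.0))
            spacing = (st, float(ds.PixelSpacing[0]), float(ds.PixelSpacing[1]))
    values = np.stack(slices)
    return ParametricMap(
        values=values,
        mask=np.isfinite(values),
        metric=metric,
        method=None,
        rescale_factor=None,
        spacing=spacing,
        metadata={"source_format": "dicom", "n_files": len(files)},
    )
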