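"""Minimal NRRD0004 reader/writer (raw encoding, little-endian).

Covers exactly what this package needs for parametric-map interchange:
3-D float arrays, ``raw`` encoding, per-axis ``spacings``, and custom
``key:=value`` fields.  Detached headers, compression and other NRRD
features are out of scope.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

_TYPE_TO_DTYPE = {
    "float": np.dtype("<f4"),
    "double": np.dtype("<f8"),
    "short": np.dtype("<i2"),
    "int": np.dtype("<i4"),
    "uchar": np.dtype("u1"),
}
_DTYPE_TO_TYPE = {
    "f4": "float", "f8": "double", "i2": "short", "i4": "int", "u1": "uchar",
}


def write_nrrd(path, array: np.ndarray, spacings=None,
               key_values: dict[str, str] | None = None) -> None:
    """Write ``array`` as an attached-header raw NRRD file."""
    arr = np.asarray(array)
    kind = _DTYPE_TO_TYPE.get(arr.dtype.str[1:])
    if kind is None:
        arr = arr.astype("<f8")
        kind = "double"
    else:
        arr = arr.astype(arr.dtype.newbyteorder("<"))
    lines = [
        "NRRD0004",
        "# produced by adcconcord",
        f"type: {kind}",
        f"dimension: {arr.ndim}",
        # NRRD lists sizes fastest axis first
        "sizes: " + " ".join(str(n) for n in arr.shape[::-1]),
        "encoding: raw",
        "endian: little",
    ]
    if spacings is not None:
        lines.append("spacings: " + " ".join(f"{s:.17g}" for s in spacings[::-1]))
    for k, v in (key_values or {}).items():
        if any(c in k for c in ":="):
            raise ValueError(f"invalid NRRD key {k!r}")
        lines.append(f"{k}:={v}")
    header = "\n".join(lines) + "\n\n"
    with open(path, "wb") as fh:
        fh.write(header.encode("ascii"))
        fh.write(np.ascontiguousarray(arr, dtype=arr.dtype).tobytes(order="C"))


def read_nrrd(path):
    """Read an attached-header raw NRRD; returns (array, spacings, key_values)."""
    data = Path(path).read_bytes()
    split = data.find(b"\n\n")
    if not data.startswith(b"NRRD") or split < 0:
        raise ValueError(f"{path}: not an attached-header NRRD file")
    header = data[:split].decode("ascii", errors="replace")
    payload = data[split + 2:]
    fields: dict[str, str] = {}
    key_values: dict[str, str] = {}
    for line in header.splitlines()[1:]:
        if not line or line.startswith("#"):
            continue
        if ":=" in line:
            k, v = line.split(":=", 1)
            key_values[k.strip()] = v.strip()
        elif ": " in line or line.endswith(":"):
            k, _, v = line.partition(":")
            fields[k.strip().lower()] = v.strip()
    if fields.get("encoding") != "raw":
        raise ValueError("only raw-encoded NRRD is supported")
    dtype = _TYPE_TO_DTYPE.get(fields.get("type", ""))
    if dtype is None:
        raise ValueError(f"unsupported NRRD type {fields.get('type')!r}")
    if fields.get("endian", "little") != "little":
        dtype = dtype.newbyteorder(">")
    sizes = [int(x) for x in fields["sizes"].split()][::-1]
    arr = np.frombuffer(payload, dtype=dtype, count=int(np.prod(sizes)))
    arr = arr.reshape(sizes)
    spacings = None
    if "spacings" in fields:
        spacings = tuple(float(x) for x in fields["spacings"].split())[::-1]
    return arr.copy(), spacings, key_values
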