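"""Minimal NRRD volume reader/writer (raw and gzip encodings).

Covers the subset of NRRD used by this package: 3D arrays, attached header,
little-endian, ``space directions`` as a diagonal matrix encoding the voxel
pitch, ``space origin`` for the grid origin.  Label volumes are uint8; maps
are float32/float64.
"""

from __future__ import annotations

import gzip
from pathlib import Path

import numpy as np

from .errors import ConfigurationError

__all__ = ["write_nrrd", "read_nrrd", "save_grid", "load_grid"]

_TYPE_TO_NRRD = {
    np.dtype(np.uint8): "uint8",
    np.dtype(np.int16): "short",
    np.dtype(np.int32): "int",
    np.dtype(np.int64): "long",
    np.dtype(np.float32): "float",
    np.dtype(np.float64): "double",
}
_NRRD_TO_TYPE = {v: k for k, v in _TYPE_TO_NRRD.items()}
_NRRD_TO_TYPE.update(
    {
        "uchar": np.dtype(np.uint8),
        "unsigned char": np.dtype(np.uint8),
        "float32": np.dtype(np.float32),
        "float64": np.dtype(np.float64),
        "double": np.dtype(np.float64),
    }
)


def write_nrrd(path, array: np.ndarray, pitch_mm: float, origin_mm=(0.0, 0.0, 0.0),
               encoding: str = "raw") -> None:
    """Write a 3D array with isotropic pitch as an attached-header NRRD."""
    array = np.ascontiguousarray(array)
    if array.ndim != 3:
        raise ConfigurationError("only 3D volumes are supported")
    if array.dtype not in _TYPE_TO_NRRD:
        raise ConfigurationError(f"unsupported dtype {array.dtype}")
    if encoding not in ("raw", "gzip"):
        raise ConfigurationError(f"unsupported encoding {encoding!r}")
    origin = np.asarray(origin_mm, dtype=float)
    header = [
        "NRRD0004",
        f"type: {_TYPE_TO_NRRD[array.dtype]}",
        "dimension: 3",
        "space: left-posterior-superior",
        "sizes: {} {} {}".format(*array.shape),
        "space directions: ({},0,0) (0,{},0) (0,0,{})".format(pitch_mm, pitch_mm, pitch_mm),
        "kinds: domain domain domain",
        "endian: little",
        f"encoding: {encoding}",
        "space origin: ({},{},{})".format(*origin),
        "",
        "",
    ]
    # NRRD data order is fastest-first; write Fortran order so axis 0 is fastest
    payload = array.tobytes(order="F")
    if encoding == "gzip":
        payload = gzip.compress(payload)
    with open(path, "wb") as fh:
        fh.write("\n".join(header).encode("ascii"))
        fh.write(payload)


def read_nrrd(path):
    """Read an attached-header NRRD; returns (array, pitch_mm, origin_mm)."""
    blob = Path(path).read_bytes()
    end = blob.find(b"\n\n")
    if end < 0:
        raise ConfigurationError(f"{path}: no NRRD header terminator found")
    lines = blob[:end].decode("ascii", errors="replace").splitlines()
    if not lines or not lines[0].startswith("NRRD"):
        raise ConfigurationError(f"{path} is not an NRRD file")
    fields = {}
    for line in lines[1:]:
        if not line or line.startswith("#"):
            continue
        key, _, value = line.partition(":")
        fields[key.strip().lower()] = value.strip()
    try:
        dtype = _NRRD_TO_TYPE[fields["type"]]
        sizes = tuple(int(s) for s in fields["sizes"].split())
        encoding = fields.get("encoding", "raw")
    except KeyError as exc:
        raise ConfigurationError(f"{path}: missing NRRD field {exc}") from exc
    if int(fields.get("dimension", len(sizes))) != 3 or len(sizes) != 3:
        raise ConfigurationError(f"{path}: only 3D NRRD volumes are supported")
    if fields.get("endian", "little") != "little":
        raise ConfigurationError(f"{path}: only little-endian NRRD is supported")

    pitch = 1.0
    if "space directions" in fields:
        vecs = _parse_vectors(fields["space directions"])
        diag = [v[i] for i, v in enumerate(vecs)]
        if not np.allclose(diag, diag[0]) or not np.allclose(
            [v[j] for i, v in enumerate(vecs) for j in range(3) if j != i], 0.0
        ):
            raise ConfigurationError(f"{path}: only isotropic diagonal pitch supported")
        pitch = float(diag[0])
    origin = np.zeros(3)
    if "space origin" in fields:
        origin = np.array(_parse_vectors(fields["space origin"])[0])

    payload = blob[end + 2 :]
    if encoding == "gzip":
        payload = gzip.decompress(payload)
    elif encoding != "raw":
        raise ConfigurationError(f"{path}: unsupported encoding {encoding!r}")
    count = int(np.prod(sizes))
    data = np.frombuffer(payload, dtype=dtype, count=count)
    array = np.ascontiguousarray(data.reshape(sizes, order="F"))
    return array, pitch, origin


def _parse_vectors(text: str):
    vecs = []
    for token in text.split(")"):
        token = token.strip().lstrip("(").strip()
        if not token:
            continue
        vecs.append([float(x) for x in token.replace(",", " ").split()])
    return vecs


def save_grid(path, grid) -> None:
    """Write a :class:`~toothmc.geometry.VoxelGrid` as a uint8 label NRRD."""
    write_nrrd(path, grid.labels, grid.pitch_mm, grid.origin_mm)


def load_grid(path):
    """Read a label NRRD into a :class:`~toothmc.geometry.VoxelGrid`."""
    from .geometry import VoxelGrid

    array, pitch, origin = read_nrrd(path)
    if array.dtype != np.uint8:
        if array.max(initial=0) > 3 or array.min(initial=0) < 0:
            raise ConfigurationError(f"{path}: labels must lie in {{0..3}}")
        array = array.astype(np.uint8)
    return VoxelGrid(labels=array, pitch_mm=pitch, origin_mm=origin)
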