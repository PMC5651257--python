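"""Triangulated-surface and momentum-field containers with file I/O.

Surfaces are plain vertex/face arrays in millimeters; momenta are one
3-vector per template vertex.  PLY (ASCII or binary little-endian) and OFF
(ASCII) are supported through :mod:`trimesh`; momenta are stored either as a
CSV table or as a flat float binary with a JSON sidecar.  Vertex order is
semantic (momenta are vertex-indexed) and is never permuted by I/O.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import trimesh


class SurfaceFormatError(ValueError):
    """Raised when a surface or momentum file fails validation."""


@dataclass(frozen=True)
class TriSurface:
    """A triangulated surface: vertex coordinates (mm) and 0-based faces."""

    vertices: np.ndarray
    faces: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.vertices, dtype=np.float64)
        f = np.asarray(self.faces, dtype=np.int64)
        if v.ndim != 2 or v.shape[1] != 3:
            raise SurfaceFormatError(f"vertices must be (n, 3), got {v.shape}")
        if f.ndim != 2 or f.shape[1] != 3:
            raise SurfaceFormatError(f"faces must be (m, 3), got {f.shape}")
        if v.shape[0] < 3:
            raise SurfaceFormatError(f"need at least 3 vertices, got {v.shape[0]}")
        if not np.all(np.isfinite(v)):
            bad = int(np.flatnonzero(~np.isfinite(v).all(axis=1))[0])
            raise SurfaceFormatError(f"non-finite coordinate at vertex {bad}")
        if f.size and (f.min() < 0 or f.max() >= v.shape[0]):
            bad_row = int(
                np.flatnonzero(((f < 0) | (f >= v.shape[0])).any(axis=1))[0]
            )
            raise SurfaceFormatError(
                f"face index out of range at face {bad_row}: {f[bad_row].tolist()} "
                f"(mesh has {v.shape[0]} vertices)"
            )
        object.__setattr__(self, "vertices", v)
        object.__setattr__(self, "faces", f)

    @property
    def n_vertices(self) -> int:
        return self.vertices.shape[0]

    @property
    def n_faces(self) -> int:
        return self.faces.shape[0]

    def with_vertices(self, vertices: np.ndarray) -> "TriSurface":
        """Same connectivity, new vertex positions."""
        return TriSurface(vertices=np.asarray(vertices, float), faces=self.faces)


@dataclass(frozen=True)
class MomentumField:
    """One momentum 3-vector per template vertex (initial momentum p0)."""

    values: np.ndarray = field()

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=np.float64)
        if v.ndim != 2 or v.shape[1] != 3:
            raise SurfaceFormatError(f"momenta must be (n, 3), got {v.shape}")
        if not np.all(np.isfinite(v)):
            raise SurfaceFormatError("momentum field contains non-finite entries")
        object.__setattr__(self, "values", v)

    @property
    def vertex_count(self) -> int:
        return self.values.shape[0]

    def __add__(self, other: "MomentumField") -> "MomentumField":
        return MomentumField(self.values + other.values)

    def __mul__(self, scalar: float) -> "MomentumField":
        return MomentumField(self.values * float(scalar))

    __rmul__ = __mul__


_SURFACE_SUFFIXES = {".ply": "ply", ".off": "off"}


def _resolve_format(path: Path, fmt: str) -> str:
    fmt = fmt.lower()
    if fmt == "auto":
        try:
            return _SURFACE_SUFFIXES[path.suffix.lower()]
        except KeyError:
            raise SurfaceFormatError(
                f"cannot infer surface format from suffix {path.suffix!r}"
            ) from None
    if fmt not in ("ply", "off"):
        raise SurfaceFormatError(f"unsupported surface format {fmt!r}")
    return fmt


def read_surface(path: str | Path, fmt: str = "auto") -> TriSurface:
    """Read a PLY or OFF surface, preserving vertex order from the file."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = _resolve_format(path, fmt)
    try:
        mesh = trimesh.load(path, file_type=fmt, process=False)
    except Exception as exc:  # trimesh raises heterogeneous errors
        raise SurfaceFormatError(f"failed to parse {path} as {fmt}: {exc}") from exc
    if not isinstance(mesh, trimesh.Trimesh) or len(mesh.vertices) == 0:
        raise SurfaceFormatError(f"{path}: empty or non-triangular mesh")
    return TriSurface(
        vertices=np.asarray(mesh.vertices, float),
        faces=np.asarray(mesh.faces, np.int64),
    )


def _export_ply_double(surface: TriSurface, path: Path) -> None:
    # trimesh's PLY writer truncates vertices to float32; emit float64
    # binary little-endian directly so write/read roundtrips bit-exact
    header = (
        "ply\n"
        "format binary_little_endian 1.0\n"
        f"element vertex {surface.n_vertices}\n"
        "property double x\nproperty double y\nproperty double z\n"
        f"element face {surface.n_faces}\n"
        "property list uchar int vertex_indices\n"
        "end_header\n"
    )
    faces = np.empty(
        surface.n_faces, dtype=[("count", "<u1"), ("index", "<i4", (3,))]
    )
    faces["count"] = 3
    faces["index"] = surface.faces
    with open(path, "wb") as fh:
        fh.write(header.encode("ascii"))
        fh.write(surface.vertices.astype("<f8").tobytes())
        fh.write(faces.tobytes())


def write_surface(surface: TriSurface, path: str | Path, fmt: str = "auto") -> None:
    """Write a surface as PLY (binary little-endian, float64 coordinates,
    bit-exact roundtrip) or OFF (ASCII, 10 decimal digits)."""
    path = Path(path)
    fmt = _resolve_format(path, fmt)
    if fmt == "ply":
        _export_ply_double(surface, path)
        return
    mesh = trimesh.Trimesh(
        vertices=surface.vertices, faces=surface.faces, process=False
    )
    mesh.export(path, file_type=fmt)


def write_momenta(fld: MomentumField, path: str | Path) -> None:
    """Serialize a momentum field.

    ``.csv`` writes columns (vertex_index, px, py, pz); any other suffix
    writes raw little-endian float64 with a ``<path>.json`` sidecar recording
    ``vertex_count`` and ``dtype`` (bit-exact roundtrip).
    """
    path = Path(path)
    if path.suffix.lower() == ".csv":
        df = pd.DataFrame(fld.values, columns=["px", "py", "pz"])
        df.insert(0, "vertex_index", np.arange(fld.vertex_count))
        df.to_csv(path, index=False)  # shortest-roundtrip float repr: exact
    else:
        fld.values.astype("<f8").tofile(path)
        sidecar = {"vertex_count": fld.vertex_count, "dtype": "float64"}
        Path(str(path) + ".json").write_text(json.dumps(sidecar))


def read_momenta(path: str | Path) -> MomentumField:
    """Read a momentum field written by :func:`write_momenta`."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.suffix.lower() == ".csv":
        df = pd.read_csv(path, float_precision="round_trip")
        required = {"vertex_index", "px", "py", "pz"}
        if not required.issubset(df.columns):
            raise SurfaceFormatError(
                f"{path}: expected columns {sorted(required)}, got {list(df.columns)}"
            )
        df = df.sort_values("vertex_index")
        idx = df["vertex_index"].to_numpy()
        if not np.array_equal(idx, np.arange(len(df))):
            raise SurfaceFormatError(
                f"{path}: vertex_index must be 0..{len(df) - 1} without gaps"
            )
        return MomentumField(df[["px", "py", "pz"]].to_numpy(float))
    sidecar_path = Path(str(path) + ".json")
    if not sidecar_path.exists():
        raise SurfaceFormatError(f"missing JSON sidecar {sidecar_path}")
    meta = json.loads(sidecar_path.read_text())
    n = int(meta["vertex_count"])
    raw = np.fromfile(path, dtype=np.dtype(meta.get("dtype", "float64")).newbyteorder("<"))
    if raw.size != 3 * n:
        raise SurfaceFormatError(
            f"{path}: {raw.size} scalars on disk but sidecar declares "
            f"vertex_count={n} (expected {3 * n})"
        )
    return MomentumField(raw.astype(np.float64).reshape(n, 3))
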