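"""Triangle-mesh input/output and validation.

Meshes are carried as :class:`trimesh.Trimesh` objects throughout the
package (vertices in millimetres, the STL/DICOM convention; no unit
conversion is ever applied).  Reading welds duplicate vertices — STL
stores a facet soup — and drops zero-area facets, attaching a small
validation report to ``mesh.metadata["validation"]``.

Scalar-annotated surfaces (e.g. a deviation map with per-vertex colors)
are written as ASCII PLY with named float vertex properties; STL cannot
carry them and requesting it raises.  The PLY reader/writer here is
deliberately self-contained so that named scalar properties survive a
round trip.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import trimesh

log = logging.getLogger(__name__)

#: vertices closer than this (mm) are welded into one; far below CT resolution
WELD_TOLERANCE = 1e-6


class MeshFormatError(ValueError):
    """File could not be parsed in the declared format."""


class InvalidMeshError(ValueError):
    """Mesh is empty or geometrically unusable."""


@dataclass
class AnnotatedMesh:
    """A surface plus named per-vertex scalar fields and optional colors.

    Every scalar field and the color array must have exactly one entry per
    vertex.
    """

    mesh: trimesh.Trimesh
    vertex_scalars: dict[str, np.ndarray] = field(default_factory=dict)
    vertex_colors: np.ndarray | None = None  # (n, 3) uint8 RGB

    def __post_init__(self) -> None:
        n = len(self.mesh.vertices)
        for name, values in self.vertex_scalars.items():
            values = np.asarray(values, dtype=np.float64)
            if values.shape != (n,):
                raise InvalidMeshError(
                    f"scalar field {name!r} has {values.shape} values "
                    f"for {n} vertices"
                )
            self.vertex_scalars[name] = values
        if self.vertex_colors is not None:
            self.vertex_colors = np.asarray(self.vertex_colors, dtype=np.uint8)
            if self.vertex_colors.shape != (n, 3):
                raise InvalidMeshError(
                    f"vertex_colors shape {self.vertex_colors.shape} "
                    f"does not match {n} vertices"
                )


def _weld_and_validate(
    mesh: trimesh.Trimesh, return_vertex_map: bool = False
) -> trimesh.Trimesh | tuple[trimesh.Trimesh, np.ndarray]:
    """Weld near-duplicate vertices, drop degenerate faces, attach report.

    Welding is order-stable: kept vertices appear in first-occurrence order,
    so an already-welded mesh passes through unchanged.  With
    ``return_vertex_map`` the (old index -> kept representative) map is
    returned too, for remapping per-vertex annotations.
    """
    if len(mesh.faces) == 0 or len(mesh.vertices) == 0:
        raise InvalidMeshError("mesh has no geometry")
    vertices = np.asarray(mesh.vertices, dtype=np.float64)
    faces = np.asarray(mesh.faces, dtype=np.int64)

    # weld: snap coordinates to the tolerance grid and group
    key = np.round(vertices / WELD_TOLERANCE).astype(np.int64)
    _, first, inverse = np.unique(key, axis=0, return_index=True, return_inverse=True)
    order = np.argsort(first, kind="stable")
    rank = np.empty(len(order), dtype=np.int64)
    rank[order] = np.arange(len(order))
    keep_idx = first[order]
    vertices = vertices[keep_idx]
    vertex_map = rank[inverse]
    faces = vertex_map[faces]

    out = trimesh.Trimesh(vertices=vertices, faces=faces, process=False)
    areas = out.area_faces
    keep = areas > 0.0
    dropped = int((~keep).sum())
    if dropped:
        log.warning("dropped %d degenerate (zero-area) faces", dropped)
        out.update_faces(keep)
    if len(out.faces) == 0 or out.area <= 0.0:
        raise InvalidMeshError("mesh has zero surface area after validation")
    if (out.faces >= len(out.vertices)).any() or (out.faces < 0).any():
        raise InvalidMeshError("face indices out of range")
    out.metadata["validation"] = {
        "n_vertices": len(out.vertices),
        "n_faces": len(out.faces),
        "watertight": bool(out.is_watertight),
        "dropped_degenerate_faces": dropped,
    }
    if return_vertex_map:
        return out, keep_idx
    return out


def _infer_format(path: Path, format: str | None) -> str:
    if format is not None:
        return format.lower()
    suffix = path.suffix.lower().lstrip(".")
    if suffix in ("stl", "ply"):
        return suffix
    raise MeshFormatError(f"cannot infer mesh format from {path.name!r}")


def read_mesh(path: str | Path, format: str | None = None) -> trimesh.Trimesh:
    """Read an STL (binary or ASCII) or PLY mesh, weld and validate it.

    Scalar vertex properties present in a PLY file are attached to
    ``mesh.metadata["vertex_scalars"]`` (pre-weld order is preserved only
    when no vertices are merged; annotated maps written by this package
    are already welded).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = _infer_format(path, format)
    if fmt == "ply":
        annotated = read_annotated_ply(path)
        mesh = annotated.mesh
        if annotated.vertex_scalars:
            mesh.metadata["vertex_scalars"] = annotated.vertex_scalars
        if annotated.vertex_colors is not None:
            mesh.visual.vertex_colors = np.column_stack(
                [annotated.vertex_colors, np.full(len(mesh.vertices), 255, np.uint8)]
            )
        return mesh
    try:
        mesh = trimesh.load_mesh(path, file_type=fmt, process=False)
    except Exception as exc:  # trimesh raises a zoo of types
        raise MeshFormatError(f"could not parse {path} as {fmt}: {exc}") from exc
    if not isinstance(mesh, trimesh.Trimesh):
        raise MeshFormatError(f"{path} did not contain a single triangle mesh")
    if len(mesh.faces) == 0 or len(mesh.vertices) == 0:
        raise MeshFormatError(f"no readable geometry in {path}")
    return _weld_and_validate(mesh)


def write_mesh(
    mesh: trimesh.Trimesh | AnnotatedMesh,
    path: str | Path,
    format: str | None = None,
) -> Path:
    """Write a mesh as STL (geometry only) or PLY (geometry + annotations)."""
    path = Path(path)
    fmt = _infer_format(path, format)
    if isinstance(mesh, AnnotatedMesh):
        if fmt == "stl":
            raise MeshFormatError(
                "STL carries geometry only; write annotated meshes to PLY"
            )
        write_annotated_ply(mesh, path)
        return path
    if fmt == "stl":
        mesh.export(path, file_type="stl")
    elif fmt == "ply":
        write_annotated_ply(AnnotatedMesh(mesh=mesh), path)
    else:
        raise MeshFormatError(f"unsupported mesh format {fmt!r}")
    return path


# ---------------------------------------------------------------------------
# ASCII PLY with named float vertex properties


def write_annotated_ply(annotated: AnnotatedMesh, path: str | Path) -> None:
    mesh = annotated.mesh
    n_v = len(mesh.vertices)
    n_f = len(mesh.faces)
    scalars = annotated.vertex_scalars
    colors = annotated.vertex_colors

    header = ["ply", "format ascii 1.0", f"element vertex {n_v}"]
    header += [f"property double {ax}" for ax in "xyz"]
    if colors is not None:
        header += [f"property uchar {ch}" for ch in ("red", "green", "blue")]
    header += [f"property double {name}" for name in scalars]
    header += [
        f"element face {n_f}",
        "property list uchar int vertex_indices",
        "end_header",
    ]

    columns = [np.asarray(mesh.vertices, dtype=np.float64)]
    fmt_parts = ["%.17g %.17g %.17g"]
    if colors is not None:
        columns.append(colors.astype(np.float64))
        fmt_parts.append("%d %d %d")
    for values in scalars.values():
        columns.append(values[:, None])
        fmt_parts.append("%.17g")
    table = np.column_stack(columns)

    with open(path, "w") as fh:
        fh.write("\n".join(header) + "\n")
        np.savetxt(fh, table, fmt=" ".join(fmt_parts))
        faces = np.column_stack(
            [np.full(n_f, 3, dtype=np.int64), np.asarray(mesh.faces, dtype=np.int64)]
        )
        np.savetxt(fh, faces, fmt="%d")


def read_annotated_ply(path: str | Path) -> AnnotatedMesh:
    with open(path, "rb") as fh:
        magic = fh.readline().strip()
        if magic != b"ply":
            raise MeshFormatError(f"{path} is not a PLY file")
        fmt_line = fh.readline().split()
        if len(fmt_line) < 2 or fmt_line[1] != b"ascii":
            raise MeshFormatError("only ASCII PLY is supported")
        n_v = n_f = 0
        vertex_props: list[str] = []
        element = None
        for raw in fh:
            tokens = raw.split()
            if not tokens or tokens[0] == b"comment":
                continue
            if tokens[0] == b"element":
                element = tokens[1]
                if element == b"vertex":
                    n_v = int(tokens[2])
                elif element == b"face":
                    n_f = int(tokens[2])
            elif tokens[0] == b"property" and element == b"vertex":
                if tokens[1] == b"list":
                    raise MeshFormatError("list properties on vertices unsupported")
                vertex_props.append(tokens[-1].decode())
            elif tokens[0] == b"end_header":
                break
        body = fh.read().split(b"\n")

    if n_v == 0 or n_f == 0:
        raise InvalidMeshError(f"{path} contains an empty mesh")
    vdata = np.array(
        [line.split() for line in body[:n_v]], dtype=np.float64
    )
    if vdata.shape != (n_v, len(vertex_props)):
        raise MeshFormatError("vertex table shape does not match header")
    cols = {name: vdata[:, i] for i, name in enumerate(vertex_props)}
    vertices = np.column_stack([cols.pop("x"), cols.pop("y"), cols.pop("z")])
    colors = None
    if {"red", "green", "blue"} <= cols.keys():
        colors = np.column_stack(
            [cols.pop("red"), cols.pop("green"), cols.pop("blue")]
        ).astype(np.uint8)
    scalars = {name: values for name, values in cols.items()}

    faces = []
    for line in body[n_v : n_v + n_f]:
        tokens = line.split()
        count = int(tokens[0])
        if count != 3:
            raise MeshFormatError("only triangle faces are supported")
        faces.append([int(t) for t in tokens[1:4]])
    mesh, keep_idx = _weld_and_validate(
        trimesh.Trimesh(vertices=vertices, faces=np.array(faces), process=False),
        return_vertex_map=True,
    )
    scalars = {name: values[keep_idx] for name, values in scalars.items()}
    if colors is not None:
        colors = colors[keep_idx]
    return AnnotatedMesh(mesh=mesh, vertex_scalars=scalars, vertex_colors=colors)
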