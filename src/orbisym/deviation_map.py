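"""Signed surface deviation maps and their clinical-band segmentation.

After mirroring and registration, each vertex of the true surface is
compared against the mirrored surface: the deviation is the distance to
the closest point on the mirrored surface, signed positive when the vertex
lies on the outward-normal side of the nearest mirrored face (true surface
proud of the mirror) and negative otherwise.  Deviations inside a clinical
band — ±1 mm by convention for craniofacial surfaces — are regarded as
clinically non-significant; the band segmentation partitions the surface
into ``below`` / ``within`` / ``above`` regions whose areas feed the
symmetry indices.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field

import numpy as np
import trimesh

from .mesh_io import AnnotatedMesh
from .proximity import MeshProximity

#: deviations inside this closed band (mm) are clinically non-significant
CLINICAL_BAND: tuple[float, float] = (-1.0, 1.0)

BAND_LABELS = ("below", "within", "above")


@dataclass
class DeviationField:
    """Per-vertex signed distances (mm) from a true mesh to a mirrored one."""

    mesh: trimesh.Trimesh
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.shape != (len(self.mesh.vertices),):
            raise ValueError("one deviation value per vertex required")
        if not np.isfinite(self.values).all():
            raise ValueError("deviation field contains non-finite values")


@dataclass
class DeviationSummary:
    mean: float
    sd: float
    rms: float
    bin_edges: np.ndarray
    bin_counts: np.ndarray


@dataclass
class BandSegmentation:
    """Partition of a surface into below/within/above the deviation band."""

    mesh: trimesh.Trimesh
    band: tuple[float, float]
    vertex_labels: np.ndarray  # str array in BAND_LABELS
    face_labels: np.ndarray
    within_area: float
    above_area: float
    below_area: float
    total_area: float


def signed_deviation(
    true_mesh: trimesh.Trimesh, registered_mirror: trimesh.Trimesh
) -> DeviationField:
    """Signed closest-point distance from every true-mesh vertex to the
    registered mirrored surface.

    The sign comes from the outward normal of the nearest mirrored face:
    positive when the true vertex sits outside the mirrored surface.  Both
    meshes must already be registered; no alignment is performed here.
    """
    if len(true_mesh.faces) == 0 or len(registered_mirror.faces) == 0:
        raise ValueError("both meshes must be nonempty")
    prox = MeshProximity(registered_mirror)
    points = np.asarray(true_mesh.vertices, dtype=np.float64)
    closest, distance, tri_id = prox.query(points)
    normals = np.asarray(registered_mirror.face_normals, dtype=np.float64)[tri_id]
    outside = np.einsum("ij,ij->i", points - closest, normals) >= 0.0
    values = np.where(outside, distance, -distance)
    return DeviationField(mesh=true_mesh, values=values)


def summarize(
    field: DeviationField,
    bin_width: float = 0.1,
    bin_range: tuple[float, float] = (-3.0, 3.0),
) -> DeviationSummary:
    """Mean, SD (n-1), RMS and a histogram of the deviation values.

    The histogram covers ``bin_range`` in ``bin_width`` steps with two open
    tail bins, so counts always sum to the vertex count.
    """
    d = field.values
    if d.size == 0:
        raise ValueError("empty deviation field")
    lo, hi = bin_range
    inner = np.arange(lo, hi + bin_width / 2, bin_width)
    edges = np.concatenate([[-np.inf], inner, [np.inf]])
    counts, _ = np.histogram(d, bins=edges)
    return DeviationSummary(
        mean=float(np.mean(d)),
        sd=float(np.std(d, ddof=1)) if d.size > 1 else 0.0,
        rms=float(np.sqrt(np.mean(d**2))),
        bin_edges=edges,
        bin_counts=counts,
    )


def band_segment(
    field: DeviationField, band: tuple[float, float] = CLINICAL_BAND
) -> BandSegmentation:
    """Segment the surface at the clinical deviation band (closed interval).

    Vertices are labelled below/within/above; each face takes the majority
    label of its three vertices, with ties resolved to ``within`` (the
    conservative, clinically non-significant call).  Areas are summed from
    face labels.
    """
    low, high = band
    if not low < high:
        raise ValueError("band requires low < high")
    d = field.values
    vertex_code = np.ones(len(d), dtype=np.int8)  # 1 = within
    vertex_code[d < low] = 0  # below
    vertex_code[d > high] = 2  # above

    face_codes = vertex_code[field.mesh.faces]  # (n_faces, 3)
    face_label = np.full(len(face_codes), 1, dtype=np.int8)
    for code in (0, 2):
        majority = (face_codes == code).sum(axis=1) >= 2
        face_label[majority] = code
    # faces with three distinct labels have no majority -> within (tie rule)

    areas = np.asarray(field.mesh.area_faces, dtype=np.float64)
    below_area = float(areas[face_label == 0].sum())
    within_area = float(areas[face_label == 1].sum())
    above_area = float(areas[face_label == 2].sum())
    labels = np.array(BAND_LABELS)
    return BandSegmentation(
        mesh=field.mesh,
        band=(float(low), float(high)),
        vertex_labels=labels[vertex_code],
        face_labels=labels[face_label],
        within_area=within_area,
        above_area=above_area,
        below_area=below_area,
        total_area=float(areas.sum()),
    )


def export_colormap(
    field: DeviationField,
    band: tuple[float, float] = CLINICAL_BAND,
    saturation: float = 3.0,
) -> AnnotatedMesh:
    """Color-coded deviation map: green within the band, grading to red
    above and blue below, saturating at ``saturation`` mm beyond zero.

    Returns an :class:`AnnotatedMesh` carrying the ``deviation`` scalar and
    per-vertex RGB, suitable for PLY export.
    """
    low, high = band
    d = field.values
    colors = np.zeros((len(d), 3), dtype=np.float64)
    colors[:, 1] = 1.0  # green baseline

    above = d > high
    below = d < low
    # fraction of the way from the band edge to saturation
    f_above = np.clip((d[above] - high) / max(saturation - high, 1e-12), 0.0, 1.0)
    f_below = np.clip((low - d[below]) / max(low + saturation, 1e-12), 0.0, 1.0)
    colors[above, 0] = f_above
    colors[above, 1] = 1.0 - f_above
    colors[below, 2] = f_below
    colors[below, 1] = 1.0 - f_below

    rgb = np.round(colors * 255).astype(np.uint8)
    return AnnotatedMesh(
        mesh=field.mesh,
        vertex_scalars={"deviation": field.values.copy()},
        vertex_colors=rgb,
    )


def write_histogram_csv(summary: DeviationSummary, path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["bin_low", "bin_high", "count"])
        for lo, hi, c in zip(
            summary.bin_edges[:-1], summary.bin_edges[1:], summary.bin_counts
        ):
            writer.writerow([lo, hi, int(c)])


def write_summary_json(summary: DeviationSummary, path) -> None:
    with open(path, "w") as fh:
        json.dump(
            {"mean_mm": summary.mean, "sd_mm": summary.sd, "rms_mm": summary.rms},
            fh,
            indent=2,
        )
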