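"""Global and local symmetry indices and per-zone RMS.

The Global Symmetry Index (GSI) is the fraction of the model's surface
area whose deviation lies within the clinical band; the Local Symmetry
Index (LSI) is the same ratio restricted to one anatomical zone.  Both are
area ratios computed from face labels, so over zones that partition the
surface the area-weighted mean of the LSIs reproduces the GSI exactly.

Per-zone RMS is offered in two flavours: ``area_weighted`` (the pooled RMS
``sqrt(sum_c a_c * rms_c^2 / sum_c a_c)`` in mm — the default for
reporting) and ``literal`` (the sum of per-cell RMS values divided by the
zone area, in mm/mm² — a historical definition retained for comparability
with reports that use it).
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .deviation_map import BandSegmentation, DeviationField
from .surface_grid import GridCellMap, ZoneMap

log = logging.getLogger(__name__)


@dataclass
class ZoneReport:
    zone: str
    lsi: float
    area_mm2: float
    rms_weighted_mm: float | None = None
    rms_literal_mm_per_mm2: float | None = None


@dataclass
class SymmetryReport:
    """Per-model symmetry summary: GSI, deviation stats, per-zone details."""

    gsi: float
    mean_mm: float
    sd_mm: float
    rms_mm: float
    total_area_mm2: float
    within_area_mm2: float
    zones: list[ZoneReport] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "gsi": self.gsi,
            "mean_mm": self.mean_mm,
            "sd_mm": self.sd_mm,
            "rms_mm": self.rms_mm,
            "total_area_mm2": self.total_area_mm2,
            "within_area_mm2": self.within_area_mm2,
            "zones": [vars(z) for z in self.zones],
        }

    def save_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            dict(zone="__global__", lsi=self.gsi, area_mm2=self.total_area_mm2,
                 rms_weighted_mm=self.rms_mm, rms_literal_mm_per_mm2=None)
        ]
        rows += [vars(z) for z in self.zones]
        return pd.DataFrame(rows)


def global_symmetry_index(bands: BandSegmentation) -> float:
    """GSI = within-band surface area / total surface area."""
    if bands.total_area <= 0:
        raise ValueError("mesh has zero surface area")
    return bands.within_area / bands.total_area


def local_symmetry_index(bands: BandSegmentation, zones: ZoneMap, zone: str) -> float:
    """LSI of one zone = within-band area inside the zone / zone area."""
    zone_faces = zones.zone_of_face == zone
    if not zone_faces.any():
        raise ValueError(f"zone {zone!r} is unknown or empty")
    areas = np.asarray(bands.mesh.area_faces, dtype=np.float64)
    zone_area = float(areas[zone_faces].sum())
    within = zone_faces & (bands.face_labels == "within")
    return float(areas[within].sum()) / zone_area


def _per_cell_rms(field: DeviationField, cells: GridCellMap,
                  cell_ids: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """RMS of the deviation over each cell's vertices, plus cell areas.

    A vertex contributes to every cell owning a face that contains it.
    Cells whose faces contain no vertices cannot occur (every face has 3),
    but cells may be skipped upstream if the field is undefined there.
    """
    mesh = cells.mesh
    faces = np.asarray(mesh.faces)
    d2 = field.values**2
    n_cells = cells.n_cells

    sums = np.zeros(n_cells)
    counts = np.zeros(n_cells, dtype=np.int64)
    cell_of_face = cells.cell_of_face
    # unique (cell, vertex) incidences: a vertex counts once per owning cell
    pair = np.concatenate(
        [cell_of_face * len(mesh.vertices) + faces[:, k] for k in range(3)]
    )
    uniq = np.unique(pair)
    uc, uv = uniq // len(mesh.vertices), uniq % len(mesh.vertices)
    np.add.at(sums, uc, d2[uv])
    np.add.at(counts, uc, 1)

    rms = np.full(n_cells, np.nan)
    ok = counts > 0
    rms[ok] = np.sqrt(sums[ok] / counts[ok])
    return rms[cell_ids], cells.cell_areas[cell_ids]


def zone_rms(
    field: DeviationField,
    cells: GridCellMap,
    zones: ZoneMap,
    zone: str,
    mode: str = "area_weighted",
) -> float:
    """Per-zone RMS from grid-cell RMS values.

    ``area_weighted``: pooled RMS ``sqrt(sum a_c rms_c^2 / sum a_c)`` (mm).
    ``literal``: ``sum(rms_c) / zone_area`` (mm/mm²).
    """
    if mode not in ("area_weighted", "literal"):
        raise ValueError(f"unknown mode {mode!r}")
    zone_cells = np.flatnonzero(zones.zone_of_cell == zone)
    if len(zone_cells) == 0:
        raise ValueError(f"zone {zone!r} is unknown or empty")
    rms_c, area_c = _per_cell_rms(field, cells, zone_cells)
    ok = np.isfinite(rms_c)
    if not ok.all():
        warnings.warn(
            f"{(~ok).sum()} cells in zone {zone!r} carry no deviation values; skipped",
            stacklevel=2,
        )
        rms_c, area_c = rms_c[ok], area_c[ok]
    if len(rms_c) == 0:
        raise ValueError(f"zone {zone!r} has no cells with deviation values")
    if mode == "literal":
        return float(rms_c.sum() / area_c.sum())
    return float(np.sqrt((area_c * rms_c**2).sum() / area_c.sum()))


def symmetry_report(
    bands: BandSegmentation,
    field: DeviationField,
    zones: ZoneMap | None = None,
    cells: GridCellMap | None = None,
) -> SymmetryReport:
    """Assemble the full per-model report: GSI, deviation stats, zones."""
    d = field.values
    zone_reports: list[ZoneReport] = []
    if zones is not None:
        for zone in zones.zones:
            rep = ZoneReport(
                zone=zone,
                lsi=local_symmetry_index(bands, zones, zone),
                area_mm2=zones.zone_area(zone),
            )
            if cells is not None:
                rep.rms_weighted_mm = zone_rms(field, cells, zones, zone)
                rep.rms_literal_mm_per_mm2 = zone_rms(
                    field, cells, zones, zone, mode="literal"
                )
            zone_reports.append(rep)
    return SymmetryReport(
        gsi=global_symmetry_index(bands),
        mean_mm=float(np.mean(d)),
        sd_mm=float(np.std(d, ddof=1)) if d.size > 1 else 0.0,
        rms_mm=float(np.sqrt(np.mean(d**2))),
        total_area_mm2=bands.total_area,
        within_area_mm2=bands.within_area,
        zones=zone_reports,
    )
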