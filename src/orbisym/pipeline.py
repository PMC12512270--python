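"""End-to-end symmetry workflow and cohort aggregation.

``run_symmetry`` chains the whole single-model analysis: load (or extract)
the surface, estimate the midsagittal plane, mirror, rigidly register the
mirrored copy back (optionally via a reference sub-mesh such as the skull
vault), compute the signed deviation field, segment it at the clinical
band, build grid cells and zones, and emit a :class:`SymmetryReport` with
all artifacts on disk.  ``run_cohort`` aggregates per-subject reports into
a table and runs the standard statistical battery.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import trimesh

from . import cohort_stats
from .deviation_map import (
    CLINICAL_BAND,
    band_segment,
    export_colormap,
    signed_deviation,
    summarize,
    write_histogram_csv,
    write_summary_json,
)
from .mesh_io import read_mesh, write_mesh
from .mirror_register import (
    Plane,
    RegistrationResult,
    estimate_midsagittal_plane,
    icp_register,
    mirror_mesh,
    register_via_reference,
)
from .surface_grid import ZoneMap, assign_zones, grid_segment, load_zone_seeds
from .symmetry_indices import SymmetryReport, symmetry_report
from .volume_segmentation import (
    STANDARD_WINDOWS,
    HUWindow,
    extract_surface,
    read_volume,
    threshold_segment,
)

log = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Reproducible configuration of one symmetry run.

    Defaults follow the clinical protocol: a ±1 mm deviation band and
    25 mm² (5 x 5 mm) grid cells.
    """

    mesh_path: str | None = None
    volume_path: str | None = None
    hu_window: str | tuple[float, float] | None = None
    reference_path: str | None = None  # registration reference sub-mesh
    zone_seed_path: str | None = None
    band: tuple[float, float] = CLINICAL_BAND
    cell_area_mm2: float = 25.0
    max_iterations: int = 100
    tolerance: float = 1e-6
    sample_count: int = 10_000
    seed: int = 0
    out_dir: str | None = None
    plane: Plane | None = None  # explicit midsagittal plane, skips estimation

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        if self.plane is not None:
            d["plane"] = {
                "normal": self.plane.normal.tolist(),
                "offset": self.plane.offset,
            }
        return d


@dataclass
class SymmetryRun:
    """All intermediate objects of one run, for inspection and testing."""

    mesh: trimesh.Trimesh
    plane: Plane
    registration: RegistrationResult
    aligned_mirror: trimesh.Trimesh
    field: "object"
    bands: "object"
    cells: "object"
    zones: ZoneMap | None
    report: SymmetryReport


def _resolve_window(window) -> HUWindow:
    if isinstance(window, HUWindow):
        return window
    if isinstance(window, str):
        return STANDARD_WINDOWS[window]
    low, high = window
    return HUWindow(float(low), float(high))


def _load_input_mesh(config: RunConfig) -> trimesh.Trimesh:
    if config.mesh_path:
        return read_mesh(config.mesh_path)
    if config.volume_path:
        if config.hu_window is None:
            raise ValueError("volume input requires an HU window")
        volume = read_volume(config.volume_path)
        mask = threshold_segment(volume, _resolve_window(config.hu_window))
        return extract_surface(mask)
    raise ValueError("config needs mesh_path or volume_path")


def run_symmetry_on_mesh(
    mesh: trimesh.Trimesh,
    reference: trimesh.Trimesh | None = None,
    plane: Plane | None = None,
    band: tuple[float, float] = CLINICAL_BAND,
    cell_area_mm2: float = 25.0,
    zone_seeds: dict | None = None,
    max_iterations: int = 100,
    tolerance: float = 1e-6,
    sample_count: int = 10_000,
    seed: int = 0,
) -> SymmetryRun:
    """Full mirror -> register -> deviation -> indices analysis of one mesh.

    ``reference`` is an optional sub-mesh (e.g. the skull vault) on which
    the plane is estimated and the registration transform computed before
    being applied to the mirrored full model.  An explicit ``plane`` skips
    estimation.
    """
    basis = reference if reference is not None else mesh
    if plane is None:
        plane = estimate_midsagittal_plane(basis, seed=seed,
                                           sample_count=min(sample_count, 5000))
    mirrored = mirror_mesh(mesh, plane)

    if reference is not None:
        mirrored_ref = mirror_mesh(reference, plane)
        registration, moved, _ = register_via_reference(
            reference, mirrored_ref, [mirrored],
            max_iterations=max_iterations, tolerance=tolerance,
            sample_count=sample_count, seed=seed,
        )
        aligned = moved[0]
    else:
        registration = icp_register(
            mirrored, mesh, max_iterations=max_iterations,
            tolerance=tolerance, sample_count=sample_count, seed=seed,
        )
        aligned = registration.transform.apply_mesh(mirrored)

    field = signed_deviation(mesh, aligned)
    bands = band_segment(field, band)
    cells = grid_segment(mesh, cell_area_mm2, seed=seed)
    zones = assign_zones(cells, zone_seeds) if zone_seeds else None
    report = symmetry_report(bands, field, zones=zones, cells=cells)
    return SymmetryRun(
        mesh=mesh, plane=plane, registration=registration,
        aligned_mirror=aligned, field=field, bands=bands,
        cells=cells, zones=zones, report=report,
    )


def run_symmetry(config: RunConfig) -> SymmetryRun:
    """File-level front end of :func:`run_symmetry_on_mesh` with artifacts."""
    mesh = _load_input_mesh(config)
    reference = read_mesh(config.reference_path) if config.reference_path else None
    zone_seeds = (
        load_zone_seeds(config.zone_seed_path) if config.zone_seed_path else None
    )
    run = run_symmetry_on_mesh(
        mesh,
        reference=reference,
        plane=config.plane,
        band=config.band,
        cell_area_mm2=config.cell_area_mm2,
        zone_seeds=zone_seeds,
        max_iterations=config.max_iterations,
        tolerance=config.tolerance,
        sample_count=config.sample_count,
        seed=config.seed,
    )
    if config.out_dir:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        run.registration.transform.save_json(out / "transform.json")
        write_mesh(export_colormap(run.field, config.band), out / "deviation.ply")
        summary = summarize(run.field)
        write_histogram_csv(summary, out / "deviation_histogram.csv")
        write_summary_json(summary, out / "deviation_summary.json")
        run.report.save_json(out / "report.json")
        run.report.to_frame().to_csv(out / "report.csv", index=False)
        cell_df = pd.DataFrame(
            {
                "face": np.arange(len(mesh.faces)),
                "cell": run.cells.cell_of_face,
                "zone": run.zones.zone_of_face if run.zones is not None else "none",
            }
        )
        cell_df.to_csv(out / "cells.csv", index=False)
        (out / "run.json").write_text(json.dumps(config.to_dict(), indent=2))
        log.info("run artifacts written to %s (seed=%d)", out, config.seed)
    return run


# ---------------------------------------------------------------------------
# cohorts


def cohort_table(
    reports: dict[str, dict[str, SymmetryReport]]
) -> pd.DataFrame:
    """Flatten per-subject, per-structure reports into a long table."""
    rows = []
    for subject, structures in reports.items():
        for structure, rep in structures.items():
            rows.append(
                dict(subject=subject, structure=structure, gsi=rep.gsi,
                     rms_mm=rep.rms_mm, mean_mm=rep.mean_mm, sd_mm=rep.sd_mm,
                     total_area_mm2=rep.total_area_mm2)
            )
    return pd.DataFrame(rows)


def analyze_cohort(
    table: pd.DataFrame,
    value_columns: tuple[str, ...] = ("gsi", "rms_mm"),
    paired: bool = True,
) -> dict:
    """Standard cohort battery over a subject x structure table.

    For each value column: pairwise structure comparisons (paired across
    subjects by default), an omnibus test when there are >= 3 structures,
    and the GSI-RMS correlation when both columns are present.  Returns a
    JSON-serializable dict of results.
    """
    if table["subject"].nunique() < 2:
        raise ValueError(
            "cohort analysis needs >= 2 subjects; use run_symmetry for one"
        )
    structures = sorted(table["structure"].unique())
    wide = {
        col: table.pivot_table(index="subject", columns="structure",
                               values=col, aggfunc="mean")
        for col in value_columns if col in table.columns
    }
    results: dict = {"comparisons": [], "omnibus": {}, "correlations": []}
    for col, w in wide.items():
        for i in range(len(structures)):
            for j in range(i + 1, len(structures)):
                a, b = structures[i], structures[j]
                sub = w[[a, b]].dropna()
                res = cohort_stats.compare_two(sub[a], sub[b], paired=paired)
                results["comparisons"].append(
                    dict(variable=col, group1=a, group2=b,
                         test=res.test_name, statistic=res.statistic,
                         p_value=res.p_value, direction=res.effect_direction)
                )
        if len(structures) >= 3:
            groups = [w[s].dropna().to_numpy() for s in structures]
            omni = cohort_stats.compare_many(groups)
            results["omnibus"][col] = dict(
                test=omni.omnibus.test_name,
                statistic=omni.omnibus.statistic,
                p_value=omni.omnibus.p_value,
                posthoc=omni.posthoc.to_dict(orient="records"),
            )
    if {"gsi", "rms_mm"} <= set(table.columns):
        res = cohort_stats.correlate(table["gsi"], table["rms_mm"])
        results["correlations"].append(
            dict(x="gsi", y="rms_mm", r=res.statistic, p_value=res.p_value)
        )
    return results
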