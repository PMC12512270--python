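"""Synthetic phantoms with known ground truth.

Every stage of the symmetry pipeline is validated against phantoms whose
asymmetry is constructed, not measured: meshes that are *exactly* mirror
symmetric in floating point (built by subdividing an octahedron, whose
arithmetic commutes with negating x), optionally decorated with
cosine-tapered surface bumps whose out-of-band footprint area is available
in closed form, plus HU-valued CT volumes on the clinical
0.4 x 0.4 x 0.6 mm voxel grid.

A bump of amplitude ``A`` (mm) and geodesic radius ``R`` displaces the
surface radially by ``A/2 * (1 + cos(pi * g / R))`` for geodesic distance
``g < R``.  In a true-versus-mirrored comparison the bump shows up twice
(at its own location and at its mirror image), so the expected
out-of-band footprint of one bump at band half-width ``b`` is twice the
spherical-cap area where the displacement exceeds ``b``; that cap radius is
``R / pi * arccos(2 b / |A| - 1)``, available in closed form because the
taper is a cosine.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import trimesh

from .mirror_register import Plane, RigidTransform
from .volume_segmentation import VolumeImage

log = logging.getLogger(__name__)

DEFAULT_RADIUS = 40.0  # mm, orbital-region scale
DEFAULT_SUBDIVISIONS = 6  # ~33k faces: stable ICP, seconds-scale queries
DEFAULT_HU_CLASSES = {
    "background": -1000.0,
    "fat": -100.0,
    "muscle": 60.0,
    "bone": 700.0,
}
#: polar cap (towards +z) kept free of bumps and used as the registration
#: reference, playing the role of the skull vault
VAULT_Z = 0.8


@dataclass(frozen=True)
class Bump:
    """One cosine-tapered radial surface displacement."""

    side: str  # 'right' (+x), 'left' (-x) or 'midline'
    center_direction: tuple[float, float, float]
    radius_mm: float
    amplitude_mm: float  # negative = depression

    def __post_init__(self) -> None:
        if self.radius_mm <= 0:
            raise ValueError("bump radius must be positive")
        if self.side not in ("right", "left", "midline"):
            raise ValueError(f"unknown side {self.side!r}")
        # normalise to a tuple so specs compare equal after a JSON round trip
        object.__setattr__(
            self, "center_direction", tuple(float(c) for c in self.center_direction)
        )


@dataclass(frozen=True)
class PhantomSpec:
    seed: int = 0
    base_shape: str = "sphere"  # sphere | orbit_like | hemisphere_pair | flat_sheet
    radius_mm: float = DEFAULT_RADIUS
    subdivisions: int = DEFAULT_SUBDIVISIONS
    bumps: tuple[Bump, ...] = ()
    rigid_perturbation: tuple[float, float] = (0.0, 0.0)  # (angle deg, |t| mm)
    noise_sd_mm: float = 0.0

    def __post_init__(self) -> None:
        if self.subdivisions < 3:
            raise ValueError("resolution must be >= 3 subdivisions")

    def to_json(self) -> str:
        d = asdict(self)
        return json.dumps(d, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "PhantomSpec":
        d = json.loads(text)
        d["bumps"] = tuple(Bump(**b) for b in d.get("bumps", ()))
        for key in ("rigid_perturbation",):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)


@dataclass
class GroundTruth:
    """What the generator knows exactly about a phantom."""

    plane: Plane
    total_area_mm2: float
    bump_footprint_fractions: list[float]  # at the 1 mm band, ghosts included
    expected_gsi: float
    injected_transform: RigidTransform | None = None
    vault_face_mask: np.ndarray | None = None


# ---------------------------------------------------------------------------
# exactly mirror-symmetric base meshes


def _octahedron_sphere(subdivisions: int, radius: float) -> trimesh.Trimesh:
    """Subdivided octahedron sphere, exactly symmetric under x -> -x
    (and y, z): midpoint and normalisation arithmetic commute with
    negating a coordinate in IEEE floats."""
    vertices = np.array(
        [
            [1.0, 0, 0], [-1.0, 0, 0],
            [0, 1.0, 0], [0, -1.0, 0],
            [0, 0, 1.0], [0, 0, -1.0],
        ]
    )
    faces = np.array(
        [
            [0, 2, 4], [2, 1, 4], [1, 3, 4], [3, 0, 4],
            [2, 0, 5], [1, 2, 5], [3, 1, 5], [0, 3, 5],
        ]
    )
    for _ in range(subdivisions):
        edges = np.sort(
            np.concatenate([faces[:, [0, 1]], faces[:, [1, 2]], faces[:, [2, 0]]]),
            axis=1,
        )
        uniq, inverse = np.unique(edges, axis=0, return_inverse=True)
        mid = (vertices[uniq[:, 0]] + vertices[uniq[:, 1]]) / 2.0
        mid /= np.sqrt((mid**2).sum(axis=1))[:, None]
        mid_index = len(vertices) + np.arange(len(uniq))
        vertices = np.concatenate([vertices, mid])
        n = len(faces)
        e01, e12, e20 = (
            mid_index[inverse[:n]],
            mid_index[inverse[n : 2 * n]],
            mid_index[inverse[2 * n :]],
        )
        a, b, c = faces[:, 0], faces[:, 1], faces[:, 2]
        faces = np.concatenate(
            [
                np.column_stack([a, e01, e20]),
                np.column_stack([e01, b, e12]),
                np.column_stack([e20, e12, c]),
                np.column_stack([e01, e12, e20]),
            ]
        )
    return trimesh.Trimesh(vertices=vertices * radius, faces=faces, process=False)


def _flat_sheet(half_width: float, n: int) -> trimesh.Trimesh:
    """Square sheet in the z=0 plane, exactly symmetric about x=0."""
    dx = 2.0 * half_width / (n - 1)
    m = (n - 1) / 2.0
    coords = (np.arange(n) - m) * dx
    X, Y = np.meshgrid(coords, coords, indexing="ij")
    vertices = np.column_stack([X.ravel(), Y.ravel(), np.zeros(n * n)])
    idx = np.arange(n * n).reshape(n, n)
    a = idx[:-1, :-1].ravel()
    b = idx[1:, :-1].ravel()
    c = idx[1:, 1:].ravel()
    d = idx[:-1, 1:].ravel()
    faces = np.concatenate(
        [np.column_stack([a, b, c]), np.column_stack([a, c, d])]
    )
    return trimesh.Trimesh(vertices=vertices, faces=faces, process=False)


def _mirror_concat(right: trimesh.Trimesh) -> trimesh.Trimesh:
    """Union of a mesh and its exact reflection across x=0."""
    rv = np.asarray(right.vertices)
    lv = rv * np.array([-1.0, 1.0, 1.0])
    lf = np.asarray(right.faces)[:, ::-1] + len(rv)
    return trimesh.Trimesh(
        vertices=np.concatenate([rv, lv]),
        faces=np.concatenate([right.faces, lf]),
        process=False,
    )


def _base_mesh(spec: PhantomSpec) -> trimesh.Trimesh:
    r = spec.radius_mm
    if spec.base_shape == "sphere":
        return _octahedron_sphere(spec.subdivisions, r)
    if spec.base_shape == "orbit_like":
        mesh = _octahedron_sphere(spec.subdivisions, 1.0)
        # symmetric concave sockets (the paired orbits) and a midline chin
        # bump break the spurious y/z symmetries of the bare ellipsoid
        v = np.asarray(mesh.vertices)
        for direction, amp, rad in (
            ((0.55, 0.75, 0.37), -0.12, 0.55),
            ((-0.55, 0.75, 0.37), -0.12, 0.55),
            ((0.0, -0.8, 0.6), 0.08, 0.5),
        ):
            d = np.asarray(direction) / np.linalg.norm(direction)
            ang = np.arccos(np.clip(v @ d / np.sqrt((v**2).sum(axis=1)), -1, 1))
            s = np.where(ang < rad, amp / 2.0 * (1 + np.cos(np.pi * ang / rad)), 0.0)
            v = v * (1.0 + s)[:, None]
        scale = np.array([1.125, 0.95, 0.8])
        return trimesh.Trimesh(vertices=v * scale * r, faces=mesh.faces, process=False)
    if spec.base_shape == "hemisphere_pair":
        half = _octahedron_sphere(max(3, spec.subdivisions - 1), r / 2.0)
        right = trimesh.Trimesh(
            vertices=np.asarray(half.vertices) + np.array([0.75 * r, 0.0, 0.0]),
            faces=half.faces,
            process=False,
        )
        return _mirror_concat(right)
    if spec.base_shape == "flat_sheet":
        return _flat_sheet(r, 2 ** max(4, spec.subdivisions) + 1)
    raise ValueError(f"unknown base shape {spec.base_shape!r}")


# ---------------------------------------------------------------------------
# bumps


def _bump_displacement(
    mesh: trimesh.Trimesh, bump: Bump, radius_mm: float
) -> np.ndarray:
    """Per-vertex radial displacement (mm) of one bump on a sphere base."""
    v = np.asarray(mesh.vertices)
    norms = np.sqrt((v**2).sum(axis=1))
    vhat = v / norms[:, None]
    c = np.asarray(bump.center_direction, dtype=np.float64)
    c = c / np.linalg.norm(c)
    if bump.side == "left" and c[0] > 0:
        c = c * np.array([-1.0, 1.0, 1.0])
    geodesic = radius_mm * np.arccos(np.clip(vhat @ c, -1.0, 1.0))
    s = np.zeros(len(v))
    inside = geodesic < bump.radius_mm
    s[inside] = (
        bump.amplitude_mm
        / 2.0
        * (1.0 + np.cos(np.pi * geodesic[inside] / bump.radius_mm))
    )
    return s


def bump_band_crossing_radius(bump: Bump, band_halfwidth: float = 1.0) -> float:
    """Geodesic radius (mm) at which the bump displacement equals the band."""
    a = abs(bump.amplitude_mm)
    if a <= band_halfwidth:
        return 0.0
    return bump.radius_mm / np.pi * np.arccos(2.0 * band_halfwidth / a - 1.0)


def _cap_area(geodesic_radius: float, sphere_radius: float) -> float:
    """Area of a spherical cap of given geodesic radius."""
    theta = min(geodesic_radius / sphere_radius, np.pi)
    return 2.0 * np.pi * sphere_radius**2 * (1.0 - np.cos(theta))


def bump_footprint_fraction(
    bump: Bump, sphere_radius: float, band_halfwidth: float = 1.0
) -> float:
    """Fraction of total sphere area that one bump pushes out of the band.

    Counts both the bump patch and its mirror-image ghost: the part
    comparison is two-sided, so a one-sided bump produces deviations at its
    own location (positive) and at the mirrored location (negative).
    """
    r_cross = bump_band_crossing_radius(bump, band_halfwidth)
    if r_cross == 0.0:
        return 0.0
    total = 4.0 * np.pi * sphere_radius**2
    return 2.0 * _cap_area(r_cross, sphere_radius) / total


def solve_bump_radius(
    footprint_fraction: float,
    amplitude_mm: float,
    sphere_radius: float,
    band_halfwidth: float = 1.0,
) -> float:
    """Bump radius producing a requested out-of-band footprint fraction."""
    if not 0.0 < footprint_fraction < 1.0:
        raise ValueError("footprint fraction must lie in (0, 1)")
    a = abs(amplitude_mm)
    if a <= band_halfwidth:
        raise ValueError("amplitude must exceed the band half-width")
    # two caps of fraction f/2 each: 1 - cos(theta) = f
    theta = np.arccos(1.0 - footprint_fraction)
    r_cross = sphere_radius * theta
    return float(r_cross * np.pi / np.arccos(2.0 * band_halfwidth / a - 1.0))


def make_phantom(
    spec: PhantomSpec, band_halfwidth: float = 1.0
) -> tuple[trimesh.Trimesh, GroundTruth]:
    """Generate a phantom mesh and its exact ground truth.

    The base mesh is exactly plane-symmetric about x=0; bumps (smooth
    cosine-tapered radial displacements) then inject known asymmetry.
    Expected GSI is ``1 - sum of footprint fractions`` of bumps whose
    amplitude exceeds the band; overlapping footprints are unioned
    numerically with a warning.  Deterministic for a fixed spec.
    """
    mesh = _base_mesh(spec)
    vault_mask = None
    if spec.base_shape in ("sphere", "orbit_like"):
        centers = np.asarray(mesh.triangles_center)
        zhat = centers[:, 2] / np.linalg.norm(centers, axis=1)
        vault_mask = zhat > VAULT_Z

    fractions: list[float] = []
    if spec.bumps:
        if spec.base_shape != "sphere":
            raise ValueError("bumps are only supported on the sphere base shape")
        v = np.asarray(mesh.vertices)
        vhat = v / np.sqrt((v**2).sum(axis=1))[:, None]
        total_disp = np.zeros(len(v))
        for bump in spec.bumps:
            s = _bump_displacement(mesh, bump, spec.radius_mm)
            total_disp += s
            fractions.append(
                bump_footprint_fraction(bump, spec.radius_mm, band_halfwidth)
            )
        mesh = trimesh.Trimesh(
            vertices=v + total_disp[:, None] * vhat, faces=mesh.faces, process=False
        )
        if _bumps_overlap(spec.bumps, spec.radius_mm):
            warnings.warn(
                "bump footprints overlap; expected GSI uses their numeric union",
                stacklevel=2,
            )
            union = _numeric_union_fraction(
                mesh, spec, total_disp, band_halfwidth
            )
            fractions = [union]

    expected_gsi = max(0.0, 1.0 - sum(fractions))
    plane = Plane(np.array([1.0, 0.0, 0.0]), 0.0)

    injected = None
    rng = np.random.default_rng(spec.seed)
    if spec.noise_sd_mm > 0:
        noisy = np.asarray(mesh.vertices) + rng.normal(
            0.0, spec.noise_sd_mm, (len(mesh.vertices), 3)
        )
        mesh = trimesh.Trimesh(vertices=noisy, faces=mesh.faces, process=False)
    angle, shift = spec.rigid_perturbation
    if angle != 0.0 or shift != 0.0:
        axis = rng.normal(size=3)
        direction = rng.normal(size=3)
        direction /= np.linalg.norm(direction)
        injected = RigidTransform.from_axis_angle(axis, angle, shift * direction)
        mesh = injected.apply_mesh(mesh)

    truth = GroundTruth(
        plane=plane,
        total_area_mm2=float(mesh.area),
        bump_footprint_fractions=fractions,
        expected_gsi=expected_gsi,
        injected_transform=injected,
        vault_face_mask=vault_mask,
    )
    return mesh, truth


def _bumps_overlap(bumps: tuple[Bump, ...], sphere_radius: float) -> bool:
    """Do any two bump footprints (including mirror ghosts) intersect?"""
    centers = []
    radii = []
    for b in bumps:
        c = np.asarray(b.center_direction, dtype=np.float64)
        c = c / np.linalg.norm(c)
        if b.side == "left" and c[0] > 0:
            c = c * np.array([-1.0, 1.0, 1.0])
        r = max(bump_band_crossing_radius(b), 1e-9)
        centers += [c, c * np.array([-1.0, 1.0, 1.0])]  # ghost
        radii += [r, r]
    for i in range(len(centers)):
        for j in range(i + 1, len(centers)):
            sep = sphere_radius * np.arccos(np.clip(centers[i] @ centers[j], -1, 1))
            if sep < radii[i] + radii[j]:
                return True
    return False


def _numeric_union_fraction(
    mesh: trimesh.Trimesh, spec: PhantomSpec, disp: np.ndarray, band: float
) -> float:
    """Out-of-band area fraction from the known displacement field,
    including mirror ghosts, using the same face-majority rule as the
    band segmentation."""
    v = np.asarray(mesh.vertices)
    mirrored = v * np.array([-1.0, 1.0, 1.0])
    # displacement the mirrored surface shows at each true vertex
    base = _base_mesh(spec)
    ghost = np.zeros(len(v))
    bv = np.asarray(base.vertices)
    from scipy.spatial import cKDTree

    tree = cKDTree(bv)
    _, nearest = tree.query(mirrored)
    ghost = disp[nearest]
    out_vertex = (np.abs(disp) > band) | (np.abs(ghost) > band)
    out_face = out_vertex[mesh.faces].sum(axis=1) >= 2
    areas = np.asarray(mesh.area_faces)
    return float(areas[out_face].sum() / areas.sum())


def vault_submesh(mesh: trimesh.Trimesh, truth: GroundTruth) -> trimesh.Trimesh:
    """The bump-free polar cap used as the registration reference."""
    if truth.vault_face_mask is None:
        raise ValueError("this phantom has no vault reference region")
    return mesh.submesh([np.flatnonzero(truth.vault_face_mask)], append=True)


def _random_bump_direction(
    rng: np.random.Generator, taper_angle_rad: float, margin_rad: float = 0.03
) -> np.ndarray:
    """Random bump center on the right (+x) side whose *entire* taper stays
    clear of the midplane.

    If the taper crossed x=0 the bump and its mirror ghost would partially
    cancel in the deviation field and the closed-form footprint would no
    longer hold, so the center is drawn uniformly inside the cone around +x
    of half-angle ``pi/2 - taper - margin``.
    """
    alpha_max = np.pi / 2.0 - taper_angle_rad - margin_rad
    if alpha_max <= 0:
        raise ValueError(
            "bump taper too large to fit on one side of the midplane; "
            "reduce the footprint fraction or increase the amplitude"
        )
    # uniform on the spherical cap of half-angle alpha_max around +x
    cos_a = rng.uniform(np.cos(alpha_max), 1.0)
    sin_a = np.sqrt(1.0 - cos_a**2)
    phi = rng.uniform(0.0, 2.0 * np.pi)
    return np.array([cos_a, sin_a * np.cos(phi), sin_a * np.sin(phi)])


def make_bump_phantom(
    footprint_fraction: float,
    amplitude_mm: float = 3.0,
    radius_mm: float = DEFAULT_RADIUS,
    subdivisions: int = DEFAULT_SUBDIVISIONS,
    seed: int = 0,
    band_halfwidth: float = 1.0,
) -> tuple[trimesh.Trimesh, GroundTruth]:
    """Single-bump phantom with a prescribed out-of-band footprint fraction.

    The bump is placed at a seeded random direction on the right side, with
    its whole taper clear of the midplane so the closed-form footprint
    applies.
    """
    rng = np.random.default_rng(seed)
    bump_radius = solve_bump_radius(
        footprint_fraction, amplitude_mm, radius_mm, band_halfwidth
    )
    d = _random_bump_direction(rng, bump_radius / radius_mm)
    bump = Bump(
        side="right",
        center_direction=tuple(d),
        radius_mm=bump_radius,
        amplitude_mm=amplitude_mm,
    )
    spec = PhantomSpec(
        seed=seed, base_shape="sphere", radius_mm=radius_mm,
        subdivisions=subdivisions, bumps=(bump,),
    )
    return make_phantom(spec, band_halfwidth)


# ---------------------------------------------------------------------------
# HU volumes


def make_phantom_volume(
    shape: tuple[int, int, int] = (96, 96, 64),
    spacing: tuple[float, float, float] = (0.4, 0.4, 0.6),
    hu_classes: dict[str, float] | None = None,
    fat_radius_mm: float = 5.0,
    muscle_radius_mm: float = 3.0,
    bone_outer_mm: float = 15.0,
    bone_thickness_mm: float = 2.0,
) -> tuple[VolumeImage, dict[str, np.ndarray]]:
    """Nested-sphere HU phantom on the clinical CT voxel grid.

    A bone shell encloses a fat sphere and a muscle sphere in air
    background.  Returns the volume and the exact per-class voxel masks, so
    threshold windows can be checked for exact recovery.  Class HU values
    default to points inside the standard orbital windows (fat -100 in
    [-200, 15]; muscle 60 in [-30, 205]; bone 700 outside all soft-tissue
    windows).
    """
    hu = dict(DEFAULT_HU_CLASSES)
    if hu_classes:
        hu.update(hu_classes)
    nx, ny, nz = shape
    sp = np.asarray(spacing, dtype=np.float64)
    center = (np.asarray(shape) - 1) / 2.0 * sp
    x = np.arange(nx) * sp[0] - center[0]
    y = np.arange(ny) * sp[1] - center[1]
    z = np.arange(nz) * sp[2] - center[2]
    X, Y, Z = np.meshgrid(x, y, z, indexing="ij")
    r = np.sqrt(X**2 + Y**2 + Z**2)
    r_fat = np.sqrt((X + 6.0) ** 2 + Y**2 + Z**2)
    r_musc = np.sqrt((X - 6.0) ** 2 + Y**2 + Z**2)

    masks = {
        "bone": (r <= bone_outer_mm) & (r > bone_outer_mm - bone_thickness_mm),
        "fat": r_fat <= fat_radius_mm,
        "muscle": r_musc <= muscle_radius_mm,
    }
    voxels = np.full(shape, hu["background"])
    for name in ("bone", "fat", "muscle"):
        voxels[masks[name]] = hu[name]
    # make masks exclusive in drawing order (later classes win)
    masks["bone"] &= ~(masks["fat"] | masks["muscle"])
    masks["background"] = ~(masks["bone"] | masks["fat"] | masks["muscle"])
    vol = VolumeImage(voxels=voxels, spacing=tuple(float(s) for s in sp))
    return vol, masks


# ---------------------------------------------------------------------------
# cohorts


def make_cohort(
    n_subjects: int,
    hard_gsi_mean: float = 0.85,
    soft_gsi_mean: float = 0.92,
    gsi_sd: float = 0.05,
    amplitude_mm: float = 3.0,
    amplitude_jitter_sd: float = 0.3,
    seed: int = 0,
    radius_mm: float = DEFAULT_RADIUS,
    subdivisions: int = DEFAULT_SUBDIVISIONS,
) -> tuple[list[dict[str, PhantomSpec]], pd.DataFrame]:
    """Cohort of paired hard/soft-tissue phantom specs plus the expected
    symmetry table.

    Per subject and structure, a target GSI is drawn from a normal
    truncated to (0, 1]; the asymmetry is injected as a single bump whose
    footprint fraction is ``1 - GSI`` at a jittered ~3 mm amplitude.  The
    expected table carries the analytically known GSI and whole-surface
    deviation RMS, which are structurally negatively coupled (a larger
    footprint lowers GSI and raises RMS).
    """
    if n_subjects < 2:
        raise ValueError("a cohort needs at least 2 subjects")
    for m in (hard_gsi_mean, soft_gsi_mean):
        if not 0.0 < m <= 1.0:
            raise ValueError("GSI means must lie in (0, 1]")
    rng = np.random.default_rng(seed)
    specs: list[dict[str, PhantomSpec]] = []
    rows = []
    means = {"hard_tissue": hard_gsi_mean, "soft_tissue": soft_gsi_mean}
    for subject in range(n_subjects):
        pair: dict[str, PhantomSpec] = {}
        for structure, mean in means.items():
            for attempt in range(1000):
                gsi = rng.normal(mean, gsi_sd)
                amp = max(2.0, rng.normal(amplitude_mm, amplitude_jitter_sd))
                fraction = 1.0 - gsi
                if not 0.0 <= fraction < 0.95:
                    continue  # resample infeasible draws
                if fraction == 0.0:
                    spec = PhantomSpec(
                        seed=int(rng.integers(2**31 - 1)), radius_mm=radius_mm,
                        subdivisions=subdivisions,
                    )
                    rms = 0.0
                    break
                try:
                    bump_radius = solve_bump_radius(fraction, amp, radius_mm)
                    bump_seed = int(rng.integers(2**31 - 1))
                    d = _random_bump_direction(rng, bump_radius / radius_mm)
                except ValueError:
                    log.debug("resampling infeasible GSI draw %.3f", gsi)
                    continue
                spec = PhantomSpec(
                    seed=bump_seed, radius_mm=radius_mm,
                    subdivisions=subdivisions,
                    bumps=(Bump("right", tuple(d), bump_radius, amp),),
                )
                rms = expected_bump_rms(fraction, amp, radius_mm, bump_radius)
                break
            else:
                raise RuntimeError("could not draw a feasible GSI")
            pair[structure] = spec
            rows.append(
                dict(subject=f"S{subject:03d}", structure=structure,
                     expected_gsi=gsi, expected_rms_mm=rms,
                     amplitude_mm=amp, footprint_fraction=max(0.0, 1.0 - gsi))
            )
        specs.append(pair)
    return specs, pd.DataFrame(rows)


#: mean of ``(1 + cos(pi u))^2 / 4`` weighted by ``2u`` on the unit disk
_COSINE_BUMP_MS_FACTOR = 0.75 - 4.0 / np.pi**2


def expected_bump_rms(
    footprint_fraction: float,
    amplitude_mm: float,
    sphere_radius: float,
    bump_radius: float,
) -> float:
    """Whole-surface deviation RMS expected from one bump (flat-patch
    approximation of the cosine taper, counting the mirror ghost)."""
    total = 4.0 * np.pi * sphere_radius**2
    patch = _cap_area(bump_radius, sphere_radius)
    mean_square = 2.0 * (patch / total) * _COSINE_BUMP_MS_FACTOR * amplitude_mm**2
    return float(np.sqrt(mean_square))
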