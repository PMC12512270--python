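"""Midsagittal-plane estimation, mesh mirroring and rigid ICP registration.

The mirror-and-register paradigm quantifies bilateral asymmetry: a mesh is
reflected across its (estimated) midsagittal plane and the reflected copy
is rigidly aligned back onto the original with iterative closest point
(ICP); the residual distances between the two surfaces measure left-right
asymmetry.  Registration can be computed on a reference sub-mesh (e.g. the
upper skull vault, which is unaffected by orbital pathology) and the
resulting transform applied unchanged to the structures of interest.

ICP here is point-to-surface: a fixed, area-weighted random sample of
points on the moving surface is matched each iteration to exact closest
points on the fixed surface, and the rigid transform is re-solved in
closed form (SVD/Kabsch).  Because the sample is fixed, the surface RMS
residual is non-increasing across iterations.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import trimesh

from .proximity import MeshProximity

log = logging.getLogger(__name__)


class DegeneratePlaneError(ValueError):
    """Mirror-plane estimation is ambiguous (multiple near-perfect planes)."""


@dataclass(frozen=True)
class Plane:
    """Oriented plane ``{x : normal . x = offset}`` with unit normal."""

    normal: np.ndarray
    offset: float

    def __post_init__(self) -> None:
        n = np.asarray(self.normal, dtype=np.float64)
        norm = np.linalg.norm(n)
        if not np.isfinite(norm) or norm == 0:
            raise ValueError("plane normal must be a nonzero finite vector")
        object.__setattr__(self, "normal", n / norm)
        # keep the plane equation n.x = offset consistent after normalising n
        object.__setattr__(self, "offset", float(self.offset) / norm)

    def signed_distance(self, points: np.ndarray) -> np.ndarray:
        return np.asarray(points, dtype=np.float64) @ self.normal - self.offset

    def reflect(self, points: np.ndarray) -> np.ndarray:
        d = self.signed_distance(points)
        return points - 2.0 * d[:, None] * self.normal

    def transformed(self, transform: "RigidTransform") -> "Plane":
        """The image of this plane under a rigid motion."""
        n = transform.rotation @ self.normal
        point_on_plane = self.offset * self.normal
        o = float(n @ transform.apply(point_on_plane[None, :])[0])
        return Plane(normal=n, offset=o)


@dataclass(frozen=True)
class RigidTransform:
    """Proper rigid motion ``x -> R x + t`` (rotation + translation, mm)."""

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self) -> None:
        R = np.asarray(self.rotation, dtype=np.float64)
        t = np.asarray(self.translation, dtype=np.float64).reshape(3)
        if R.shape != (3, 3):
            raise ValueError("rotation must be 3x3")
        if not np.allclose(R.T @ R, np.eye(3), atol=1e-9):
            raise ValueError("rotation must be orthonormal")
        if np.linalg.det(R) < 0:
            raise ValueError("rotation must be proper (det = +1)")
        object.__setattr__(self, "rotation", R)
        object.__setattr__(self, "translation", t)

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))

    @classmethod
    def from_axis_angle(
        cls, axis, angle_deg: float, translation=(0.0, 0.0, 0.0)
    ) -> "RigidTransform":
        axis = np.asarray(axis, dtype=np.float64)
        axis = axis / np.linalg.norm(axis)
        theta = np.deg2rad(angle_deg)
        K = np.array(
            [
                [0, -axis[2], axis[1]],
                [axis[2], 0, -axis[0]],
                [-axis[1], axis[0], 0],
            ]
        )
        R = np.eye(3) + np.sin(theta) * K + (1 - np.cos(theta)) * (K @ K)
        return cls(R, np.asarray(translation, dtype=np.float64))

    def apply(self, points: np.ndarray) -> np.ndarray:
        return np.asarray(points, dtype=np.float64) @ self.rotation.T + self.translation

    def apply_mesh(self, mesh: trimesh.Trimesh) -> trimesh.Trimesh:
        return trimesh.Trimesh(
            vertices=self.apply(mesh.vertices), faces=mesh.faces.copy(), process=False
        )

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """``self.compose(other)`` applies ``other`` first, then ``self``."""
        return RigidTransform(
            self.rotation @ other.rotation,
            self.rotation @ other.translation + self.translation,
        )

    def inverse(self) -> "RigidTransform":
        return RigidTransform(self.rotation.T, -self.rotation.T @ self.translation)

    def rotation_angle_deg(self) -> float:
        c = (np.trace(self.rotation) - 1.0) / 2.0
        return float(np.rad2deg(np.arccos(np.clip(c, -1.0, 1.0))))

    def to_matrix(self) -> np.ndarray:
        m = np.eye(4)
        m[:3, :3] = self.rotation
        m[:3, 3] = self.translation
        return m

    @classmethod
    def from_matrix(cls, m: np.ndarray) -> "RigidTransform":
        m = np.asarray(m, dtype=np.float64)
        return cls(m[:3, :3], m[:3, 3])

    def save_json(self, path) -> None:
        Path(path).write_text(json.dumps({"matrix": self.to_matrix().tolist()}))

    @classmethod
    def load_json(cls, path) -> "RigidTransform":
        return cls.from_matrix(np.array(json.loads(Path(path).read_text())["matrix"]))


@dataclass
class RegistrationResult:
    """Outcome of an ICP run: transform plus residual statistics (mm)."""

    transform: RigidTransform
    residual_mean: float
    residual_sd: float
    residual_rms: float
    iterations: int
    converged: bool
    rms_trace: list[float] = field(default_factory=list)


def mirror_mesh(mesh: trimesh.Trimesh, plane: Plane) -> trimesh.Trimesh:
    """Reflect a mesh across a plane; winding is flipped so normals stay outward."""
    vertices = plane.reflect(np.asarray(mesh.vertices, dtype=np.float64))
    faces = np.asarray(mesh.faces)[:, ::-1]
    return trimesh.Trimesh(vertices=vertices, faces=faces, process=False)


def _area_weighted_pca(mesh: trimesh.Trimesh) -> tuple[np.ndarray, np.ndarray]:
    """Area-weighted centroid and principal axes (columns, descending variance)."""
    centers = mesh.triangles_center
    weights = mesh.area_faces
    weights = weights / weights.sum()
    centroid = weights @ centers
    centered = centers - centroid
    cov = (centered * weights[:, None]).T @ centered
    eigvals, eigvecs = np.linalg.eigh(cov)
    order = np.argsort(eigvals)[::-1]
    return centroid, eigvecs[:, order]


def _mirror_score(mesh: trimesh.Trimesh, plane: Plane, prox: MeshProximity,
                  samples: np.ndarray) -> float:
    """RMS distance from mirrored sample points to the original surface."""
    _, d, _ = prox.query(plane.reflect(samples))
    return float(np.sqrt(np.mean(d**2)))


def estimate_midsagittal_plane(
    mesh: trimesh.Trimesh,
    refine_rounds: int = 20,
    sample_count: int = 2000,
    seed: int = 0,
    ambiguity_tol: float | None = None,
) -> Plane:
    """Estimate the bilateral symmetry (midsagittal) plane of a mesh.

    Candidate planes through the area-weighted centroid along each
    principal axis are scored by the RMS mirror misfit; the best one is
    refined with symmetric ICP (alternately mirror, register the mirror
    back, and re-extract the reflection plane from the combined improper
    transform).  If more than one candidate explains the mesh essentially
    perfectly the geometry has multiple symmetry planes and a
    :class:`DegeneratePlaneError` is raised.
    """
    if len(mesh.vertices) < 3:
        raise ValueError("plane estimation needs at least 3 vertices")
    centroid, axes = _area_weighted_pca(mesh)
    prox = MeshProximity(mesh)
    samples, _ = trimesh.sample.sample_surface(mesh, sample_count, seed=seed)
    samples = np.asarray(samples, dtype=np.float64)

    candidates = [
        Plane(axes[:, i], float(axes[:, i] @ centroid)) for i in range(3)
    ]
    scores = np.array(
        [_mirror_score(mesh, p, prox, samples) for p in candidates]
    )
    scale = float(np.ptp(mesh.bounds, axis=0).max())
    if ambiguity_tol is None:
        ambiguity_tol = 1e-6 * scale
    if (scores < ambiguity_tol).sum() > 1:
        raise DegeneratePlaneError(
            "multiple symmetry planes fit the mesh equally well; "
            "supply the midsagittal plane explicitly"
        )
    plane = candidates[int(np.argmin(scores))]

    for _ in range(refine_rounds):
        mirrored = mirror_mesh(mesh, plane)
        result = icp_register(
            mirrored, mesh, max_iterations=10, sample_count=sample_count, seed=seed
        )
        T = result.transform
        # combined improper map F = T o Reflect(plane); nearest reflection:
        H = np.eye(3) - 2.0 * np.outer(plane.normal, plane.normal)
        RF = T.rotation @ H
        tF = T.rotation @ (2.0 * plane.offset * plane.normal) + T.translation
        eigvals, eigvecs = np.linalg.eig(RF)
        k = int(np.argmin(np.abs(eigvals + 1.0)))
        normal = np.real(eigvecs[:, k])
        normal /= np.linalg.norm(normal)
        if normal @ plane.normal < 0:
            normal = -normal
        offset = float(normal @ tF) / 2.0
        new_plane = Plane(normal, offset)
        shift = np.linalg.norm(new_plane.normal - plane.normal) + abs(
            new_plane.offset - plane.offset
        ) / max(scale, 1.0)
        plane = new_plane
        if shift < 1e-10:
            break
    return plane


def _kabsch(source: np.ndarray, target: np.ndarray) -> RigidTransform:
    """Least-squares rigid transform mapping source points onto target points."""
    s_mean = source.mean(axis=0)
    t_mean = target.mean(axis=0)
    H = (source - s_mean).T @ (target - t_mean)
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    R = Vt.T @ np.diag([1.0, 1.0, d]) @ U.T
    return RigidTransform(R, t_mean - R @ s_mean)


def _point_to_plane_step(
    points: np.ndarray, closest: np.ndarray, normals: np.ndarray
) -> RigidTransform:
    """Small incremental rigid motion minimising the linearised
    point-to-plane error ``sum(n . (dR p + dt - q))^2``."""
    a = np.cross(points, normals)  # rotational lever arms
    J = np.concatenate([a, normals], axis=1)  # (n, 6)
    b = -np.einsum("ij,ij->i", normals, points - closest)
    x, *_ = np.linalg.lstsq(J, b, rcond=None)
    omega, dt = x[:3], x[3:]
    angle = np.linalg.norm(omega)
    if angle < 1e-16:
        return RigidTransform(np.eye(3), dt)
    return RigidTransform.from_axis_angle(
        omega / angle, np.rad2deg(angle), dt
    )


def icp_register(
    moving: trimesh.Trimesh,
    fixed: trimesh.Trimesh,
    max_iterations: int = 100,
    tolerance: float = 1e-6,
    sample_count: int = 10_000,
    seed: int = 0,
    initial: RigidTransform | None = None,
    trim_fraction: float = 0.0,
) -> RegistrationResult:
    """Rigid point-to-surface ICP aligning ``moving`` onto ``fixed``.

    A fixed area-weighted sample of ``sample_count`` points on the moving
    surface is drawn once (seeded).  Each iteration matches the currently
    transformed samples to exact closest points on the fixed surface and
    re-solves the rigid transform in closed form.  Iteration stops when the
    relative RMS change drops below ``tolerance`` or after
    ``max_iterations`` (then ``converged=False``).  ``trim_fraction``
    optionally discards that fraction of worst correspondences each
    iteration (trimmed ICP); off by default.
    """
    if len(moving.faces) == 0 or len(fixed.faces) == 0:
        raise ValueError("both meshes must be nonempty")
    if sample_count < 100:
        raise ValueError("sample_count must be at least 100")
    if not 0.0 <= trim_fraction < 1.0:
        raise ValueError("trim_fraction must lie in [0, 1)")

    samples, _ = trimesh.sample.sample_surface(moving, sample_count, seed=seed)
    samples = np.asarray(samples, dtype=np.float64)
    prox = MeshProximity(fixed)
    face_normals = np.asarray(fixed.face_normals, dtype=np.float64)
    transform = initial if initial is not None else RigidTransform.identity()

    keep_n = max(3, int(round((1.0 - trim_fraction) * len(samples))))

    def _rms(d: np.ndarray) -> float:
        return float(np.sqrt(np.mean(d**2)))

    current = transform.apply(samples)
    closest, distances, tri = prox.query(current)
    rms_trace: list[float] = [_rms(distances)]
    converged = False
    for _ in range(max_iterations - 1):
        if rms_trace[-1] < 1e-12:
            converged = True
            break
        if trim_fraction > 0.0:
            keep = np.argsort(distances)[:keep_n]
        else:
            keep = slice(None)
        # point-to-plane step (fast convergence), with a point-to-point
        # (Kabsch) fallback that can never increase the residual
        candidate = _point_to_plane_step(
            current[keep], closest[keep], face_normals[tri][keep]
        ).compose(transform)
        cand_pts = candidate.apply(samples)
        cand_closest, cand_dist, cand_tri = prox.query(cand_pts)
        if _rms(cand_dist) > rms_trace[-1]:
            candidate = _kabsch(samples[keep], closest[keep])
            cand_pts = candidate.apply(samples)
            cand_closest, cand_dist, cand_tri = prox.query(cand_pts)
        transform = candidate
        current, closest, distances, tri = cand_pts, cand_closest, cand_dist, cand_tri
        rms_trace.append(_rms(distances))
        prev, rms = rms_trace[-2], rms_trace[-1]
        if abs(prev - rms) <= tolerance * max(prev, 1e-12):
            converged = True
            break
    iterations = len(rms_trace)

    mean = float(np.mean(distances))
    sd = float(np.std(distances, ddof=1)) if len(distances) > 1 else 0.0
    return RegistrationResult(
        transform=transform,
        residual_mean=mean,
        residual_sd=sd,
        residual_rms=rms_trace[-1],
        iterations=iterations,
        converged=converged,
        rms_trace=rms_trace,
    )


def register_via_reference(
    true_ref: trimesh.Trimesh,
    mirrored_ref: trimesh.Trimesh,
    targets: list[trimesh.Trimesh],
    true_targets: list[trimesh.Trimesh] | None = None,
    **icp_params,
) -> tuple[RegistrationResult, list[trimesh.Trimesh], list[RegistrationResult] | None]:
    """Register the mirrored reference onto the true reference, then apply
    the same transform to every (mirrored) target mesh.

    When ``true_targets`` is given, per-target residual statistics of the
    transformed targets against their true counterparts are returned as
    well (no further fitting — the reference transform is applied
    unchanged, the way a skull-vault reference registration works).
    """
    if not targets:
        raise ValueError("target list is empty")
    result = icp_register(mirrored_ref, true_ref, **icp_params)
    transformed = [result.transform.apply_mesh(t) for t in targets]

    per_target: list[RegistrationResult] | None = None
    if true_targets is not None:
        if len(true_targets) != len(targets):
            raise ValueError("true_targets must match targets in length")
        per_target = []
        for moved, truth in zip(transformed, true_targets):
            prox = MeshProximity(truth)
            _, d, _ = prox.query(np.asarray(moved.vertices, dtype=np.float64))
            per_target.append(
                RegistrationResult(
                    transform=result.transform,
                    residual_mean=float(np.mean(d)),
                    residual_sd=float(np.std(d, ddof=1)) if len(d) > 1 else 0.0,
                    residual_rms=float(np.sqrt(np.mean(d**2))),
                    iterations=result.iterations,
                    converged=result.converged,
                )
            )
    return result, transformed, per_target
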