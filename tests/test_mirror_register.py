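import numpy as np
import pytest

from orbisym.mirror_register import (
    DegeneratePlaneError,
    Plane,
    RegistrationResult,
    RigidTransform,
    estimate_midsagittal_plane,
    icp_register,
    mirror_mesh,
    register_via_reference,
)
from orbisym.phantom import PhantomSpec, make_phantom, vault_submesh

X_PLANE = Plane(np.array([1.0, 0.0, 0.0]), 0.0)


# ---------------------------------------------------------------------------
# Plane


def test_plane_normalizes_and_keeps_equation():
    p = Plane(np.array([2.0, 0.0, 0.0]), 4.0)
    assert np.allclose(p.normal, [1, 0, 0])
    assert np.isclose(p.offset, 2.0)  # same plane x = 2
    assert np.isclose(p.signed_distance(np.array([[5.0, 0, 0]]))[0], 3.0)


def test_plane_zero_normal_raises():
    with pytest.raises(ValueError):
        Plane(np.zeros(3), 0.0)


def test_plane_reflect():
    pts = np.array([[1.0, 2.0, 3.0]])
    assert np.allclose(X_PLANE.reflect(pts), [[-1.0, 2.0, 3.0]])


def test_plane_transformed():
    t = RigidTransform.from_axis_angle([0, 0, 1], 90.0, [0.0, 5.0, 0.0])
    moved = X_PLANE.transformed(t)
    # x=0 plane rotated 90 deg about z becomes y=const through t
    assert np.allclose(np.abs(moved.normal), [0, 1, 0], atol=1e-12)
    pts_on_plane = np.array([[0.0, 0.0, 0.0], [0.0, 0.0, 7.0]])
    assert np.allclose(moved.signed_distance(t.apply(pts_on_plane)), 0.0,
                       atol=1e-12)


# ---------------------------------------------------------------------------
# RigidTransform


def test_transform_validation():
    with pytest.raises(ValueError):
        RigidTransform(np.eye(3) * 2.0, np.zeros(3))  # not orthonormal
    reflection = np.diag([-1.0, 1.0, 1.0])
    with pytest.raises(ValueError):
        RigidTransform(reflection, np.zeros(3))  # improper


def test_transform_compose_inverse():
    a = RigidTransform.from_axis_angle([1, 2, 3], 33.0, [1.0, -2.0, 0.5])
    b = RigidTransform.from_axis_angle([0, 1, 0], -70.0, [0.0, 3.0, 1.0])
    pts = np.random.default_rng(0).normal(size=(10, 3))
    assert np.allclose(a.compose(b).apply(pts), a.apply(b.apply(pts)))
    ident = a.compose(a.inverse())
    assert np.allclose(ident.rotation, np.eye(3), atol=1e-12)
    assert np.allclose(ident.translation, 0.0, atol=1e-12)


def test_transform_angle_and_matrix_roundtrip():
    t = RigidTransform.from_axis_angle([0, 0, 1], 10.0, [5.0, 0.0, 0.0])
    assert np.isclose(t.rotation_angle_deg(), 10.0)
    back = RigidTransform.from_matrix(t.to_matrix())
    assert np.allclose(back.rotation, t.rotation)
    assert np.allclose(back.translation, t.translation)


def test_transform_json_roundtrip(tmp_path):
    t = RigidTransform.from_axis_angle([1, 1, 0], 45.0, [1.0, 2.0, 3.0])
    path = tmp_path / "t.json"
    t.save_json(path)
    back = RigidTransform.load_json(path)
    assert np.allclose(back.to_matrix(), t.to_matrix())


# ---------------------------------------------------------------------------
# mirroring


def test_mirror_point_and_involution(small_sphere):
    mirrored = mirror_mesh(small_sphere, X_PLANE)
    assert np.allclose(
        mirrored.vertices,
        np.asarray(small_sphere.vertices) * [-1, 1, 1],
    )
    twice = mirror_mesh(mirrored, X_PLANE)
    assert np.array_equal(twice.vertices, small_sphere.vertices)
    assert np.array_equal(twice.faces, small_sphere.faces)


def test_mirror_preserves_area_and_distances(orbit_mesh):
    mirrored = mirror_mesh(orbit_mesh, Plane(np.array([1.0, 2.0, 0.5]), 3.0))
    assert abs(mirrored.area - orbit_mesh.area) <= 1e-12 * orbit_mesh.area
    v0 = np.asarray(orbit_mesh.vertices)[:50]
    v1 = np.asarray(mirrored.vertices)[:50]
    d0 = np.linalg.norm(v0[:, None] - v0[None, :], axis=2)
    d1 = np.linalg.norm(v1[:, None] - v1[None, :], axis=2)
    assert np.allclose(d0, d1, atol=1e-9)


def test_mirror_keeps_normals_outward(small_sphere):
    mirrored = mirror_mesh(small_sphere, X_PLANE)
    assert mirrored.volume > 0


# ---------------------------------------------------------------------------
# midsagittal plane estimation


def test_estimate_plane_symmetric_mesh(orbit_mesh):
    plane = estimate_midsagittal_plane(orbit_mesh, seed=0)
    assert abs(abs(plane.normal[0]) - 1.0) < 1e-6
    assert abs(plane.offset) < 1e-6


def test_estimate_plane_after_rigid_motion(orbit_mesh):
    t = RigidTransform.from_axis_angle([1, 2, 0.5], 25.0, [10.0, -5.0, 3.0])
    moved = t.apply_mesh(orbit_mesh)
    plane = estimate_midsagittal_plane(moved, seed=0)
    expected = X_PLANE.transformed(t)
    normal_err = min(
        np.linalg.norm(plane.normal - expected.normal),
        np.linalg.norm(plane.normal + expected.normal),
    )
    assert normal_err < 1e-4
    # compare plane positions via a point on the expected plane
    pt = expected.offset * expected.normal
    assert abs(plane.signed_distance(pt[None, :])[0]) < 1e-4


def test_estimate_plane_permutation_invariant(orbit_mesh):
    rng = np.random.default_rng(3)
    perm = rng.permutation(len(orbit_mesh.vertices))
    inv = np.empty_like(perm)
    inv[perm] = np.arange(len(perm))
    import trimesh

    shuffled = trimesh.Trimesh(
        vertices=np.asarray(orbit_mesh.vertices)[perm],
        faces=inv[np.asarray(orbit_mesh.faces)],
        process=False,
    )
    p1 = estimate_midsagittal_plane(orbit_mesh, seed=0)
    p2 = estimate_midsagittal_plane(shuffled, seed=0)
    assert min(np.linalg.norm(p1.normal - p2.normal),
               np.linalg.norm(p1.normal + p2.normal)) < 1e-6
    assert abs(abs(p1.offset) - abs(p2.offset)) < 1e-6


def test_estimate_plane_degenerate_raises(small_sphere):
    # a sphere has infinitely many symmetry planes; with a tolerance above
    # the discretisation error every candidate fits and estimation must
    # refuse rather than pick one arbitrarily
    with pytest.raises(DegeneratePlaneError):
        estimate_midsagittal_plane(small_sphere, ambiguity_tol=1.0)


def test_estimate_plane_too_few_vertices():
    import trimesh

    empty = trimesh.Trimesh(
        vertices=np.zeros((0, 3)), faces=np.zeros((0, 3), dtype=np.int64),
        process=False,
    )
    with pytest.raises(ValueError):
        estimate_midsagittal_plane(empty)


# ---------------------------------------------------------------------------
# ICP


def test_icp_already_aligned(orbit_mesh):
    result = icp_register(orbit_mesh, orbit_mesh, sample_count=2000, seed=0)
    assert result.residual_rms < 1e-9
    assert result.converged
    assert np.allclose(result.transform.rotation, np.eye(3), atol=1e-6)


def test_icp_recovers_known_transform(orbit_mesh):
    t = RigidTransform.from_axis_angle([0.3, 1.0, -0.2], 10.0,
                                       5.0 * np.array([0.6, -0.64, 0.48]))
    moved = t.apply_mesh(orbit_mesh)
    result = icp_register(moved, orbit_mesh, sample_count=3000, seed=0)
    recovered = result.transform
    err = recovered.compose(t)
    assert err.rotation_angle_deg() < 0.1
    assert np.linalg.norm(err.translation) < 0.05
    assert result.residual_rms < 1e-3


def test_icp_rms_trace_non_increasing(orbit_mesh):
    t = RigidTransform.from_axis_angle([0, 0, 1], 15.0, [4.0, 2.0, -1.0])
    result = icp_register(t.apply_mesh(orbit_mesh), orbit_mesh,
                          sample_count=2000, seed=0)
    trace = np.asarray(result.rms_trace)
    assert (np.diff(trace) <= 1e-12).all()
    assert result.iterations == len(trace)
    assert result.iterations <= 100


def test_icp_noise_envelope(orbit_mesh):
    import trimesh

    rms_values = []
    for seed in range(5):
        rng = np.random.default_rng(seed)
        noisy = trimesh.Trimesh(
            vertices=np.asarray(orbit_mesh.vertices)
            + rng.normal(0, 0.1, (len(orbit_mesh.vertices), 3)),
            faces=orbit_mesh.faces,
            process=False,
        )
        result = icp_register(noisy, orbit_mesh, sample_count=2000, seed=seed)
        rms_values.append(result.residual_rms)
    assert all(0.05 <= r <= 0.2 for r in rms_values)


def test_icp_input_validation(orbit_mesh):
    import trimesh

    empty = trimesh.Trimesh(vertices=np.zeros((0, 3)), faces=np.zeros((0, 3)))
    with pytest.raises(ValueError):
        icp_register(empty, orbit_mesh)
    with pytest.raises(ValueError):
        icp_register(orbit_mesh, orbit_mesh, sample_count=50)
    with pytest.raises(ValueError):
        icp_register(orbit_mesh, orbit_mesh, trim_fraction=1.0)


# ---------------------------------------------------------------------------
# reference registration


def test_reference_identity_propagation(orbit_mesh, small_sphere):
    result, moved, _ = register_via_reference(
        orbit_mesh, orbit_mesh, [small_sphere], sample_count=1000, seed=0
    )
    assert np.allclose(moved[0].vertices, small_sphere.vertices, atol=1e-6)


def test_reference_shared_transform(orbit_mesh):
    truth = make_phantom(PhantomSpec(seed=1, base_shape="orbit_like",
                                     subdivisions=5))
    mesh, gt = truth
    ref = vault_submesh(mesh, gt)
    t = RigidTransform.from_axis_angle([0.1, 1.0, 0.3], 8.0, [3.0, -1.0, 2.0])
    moved_ref = t.apply_mesh(ref)
    moved_target = t.apply_mesh(mesh)
    result, aligned, per_target = register_via_reference(
        ref, moved_ref, [moved_target], true_targets=[mesh],
        sample_count=3000, seed=0,
    )
    assert per_target[0].residual_rms < 1e-3
    assert np.abs(np.asarray(aligned[0].vertices) - mesh.vertices).max() < 1e-3


def test_reference_order_and_errors(orbit_mesh, small_sphere, sheet_50mm):
    targets = [small_sphere, sheet_50mm, orbit_mesh]
    _, moved, _ = register_via_reference(
        orbit_mesh, orbit_mesh, targets, sample_count=1000, seed=0
    )
    assert len(moved) == 3
    for out, src in zip(moved, targets):
        assert len(out.faces) == len(src.faces)
    with pytest.raises(ValueError):
        register_via_reference(orbit_mesh, orbit_mesh, [])
    with pytest.raises(ValueError):
        register_via_reference(orbit_mesh, orbit_mesh, [small_sphere],
                               true_targets=[small_sphere, orbit_mesh])
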