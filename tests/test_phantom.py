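import numpy as np
import pytest

from orbisym.deviation_map import band_segment, signed_deviation
from orbisym.mirror_register import mirror_mesh
from orbisym.phantom import (
    Bump,
    PhantomSpec,
    bump_band_crossing_radius,
    bump_footprint_fraction,
    expected_bump_rms,
    make_bump_phantom,
    make_cohort,
    make_phantom,
    make_phantom_volume,
    solve_bump_radius,
    vault_submesh,
)
from orbisym.symmetry_indices import global_symmetry_index
from orbisym.volume_segmentation import (
    STANDARD_WINDOWS,
    measure_volume,
    threshold_segment,
)


def test_spec_validation():
    with pytest.raises(ValueError):
        PhantomSpec(subdivisions=2)
    with pytest.raises(ValueError):
        Bump("nowhere", (1, 0, 0), 5.0, 1.0)
    with pytest.raises(ValueError):
        Bump("right", (1, 0, 0), -5.0, 1.0)


def test_spec_json_roundtrip():
    spec = PhantomSpec(
        seed=3, base_shape="sphere", subdivisions=4,
        bumps=(Bump("right", (1.0, 0.0, 0.0), 8.0, 2.5),),
        rigid_perturbation=(5.0, 2.0), noise_sd_mm=0.1,
    )
    assert PhantomSpec.from_json(spec.to_json()) == spec


def test_determinism():
    a, _ = make_phantom(PhantomSpec(seed=5, subdivisions=4,
                                    noise_sd_mm=0.05,
                                    rigid_perturbation=(3.0, 1.0)))
    b, _ = make_phantom(PhantomSpec(seed=5, subdivisions=4,
                                    noise_sd_mm=0.05,
                                    rigid_perturbation=(3.0, 1.0)))
    assert np.asarray(a.vertices).tobytes() == np.asarray(b.vertices).tobytes()
    assert np.array_equal(a.faces, b.faces)


@pytest.mark.parametrize("shape", ["sphere", "orbit_like", "hemisphere_pair",
                                   "flat_sheet"])
def test_base_meshes_exactly_symmetric(shape):
    mesh, truth = make_phantom(PhantomSpec(seed=0, base_shape=shape,
                                           subdivisions=4))
    v = np.asarray(mesh.vertices)
    reflected = v * np.array([-1.0, 1.0, 1.0])
    # the reflected vertex set equals the original set bit-for-bit
    original = {tuple(row) for row in v}
    assert {tuple(row) for row in reflected} == original
    assert truth.expected_gsi == 1.0
    assert np.allclose(truth.plane.normal, [1, 0, 0])


def test_unknown_shape_raises():
    with pytest.raises(ValueError):
        make_phantom(PhantomSpec(base_shape="torus"))


def test_bumps_only_on_sphere():
    spec = PhantomSpec(base_shape="flat_sheet",
                       bumps=(Bump("right", (1, 0, 0), 5.0, 2.0),))
    with pytest.raises(ValueError):
        make_phantom(spec)


def test_footprint_closed_forms():
    bump = Bump("right", (1, 0, 0), 10.0, 3.0)
    r_cross = bump_band_crossing_radius(bump, 1.0)
    # displacement at r_cross equals the band half-width
    disp = 3.0 / 2.0 * (1 + np.cos(np.pi * r_cross / 10.0))
    assert np.isclose(disp, 1.0)
    # solve_bump_radius inverts bump_footprint_fraction
    for f in (0.05, 0.12, 0.3):
        radius = solve_bump_radius(f, 3.0, 40.0)
        back = bump_footprint_fraction(
            Bump("right", (1, 0, 0), radius, 3.0), 40.0
        )
        assert np.isclose(back, f, rtol=1e-12)


def test_sub_band_bump_has_zero_footprint():
    bump = Bump("right", (1, 0, 0), 10.0, 0.8)
    assert bump_band_crossing_radius(bump) == 0.0
    assert bump_footprint_fraction(bump, 40.0) == 0.0
    mesh, truth = make_phantom(
        PhantomSpec(seed=0, subdivisions=4, bumps=(bump,))
    )
    assert truth.expected_gsi == 1.0


def test_solve_bump_radius_validation():
    with pytest.raises(ValueError):
        solve_bump_radius(0.0, 3.0, 40.0)
    with pytest.raises(ValueError):
        solve_bump_radius(0.1, 0.5, 40.0)  # amplitude below band


def test_single_bump_gsi_recovered():
    mesh, truth = make_bump_phantom(0.12, amplitude_mm=3.0, subdivisions=5,
                                    seed=2)
    field = signed_deviation(mesh, mirror_mesh(mesh, truth.plane))
    gsi = global_symmetry_index(band_segment(field))
    assert abs((1.0 - gsi) - 0.12) <= 0.02
    assert np.isclose(truth.expected_gsi, 0.88)


def test_depression_bump():
    mesh, truth = make_phantom(
        PhantomSpec(seed=0, subdivisions=4,
                    bumps=(Bump("right", (1, 0, 0), 10.0, -3.0),))
    )
    assert truth.bump_footprint_fractions[0] > 0
    # surface is pushed inward at the bump center
    v = np.asarray(mesh.vertices)
    r = np.linalg.norm(v, axis=1)
    assert r.min() < 40.0 - 1.0


def test_overlapping_bumps_warn_and_union():
    bumps = (
        Bump("right", (1.0, 0.05, 0.0), 10.0, 3.0),
        Bump("right", (1.0, -0.05, 0.0), 10.0, 3.0),
    )
    with pytest.warns(UserWarning):
        _, truth = make_phantom(PhantomSpec(seed=0, subdivisions=4,
                                            bumps=bumps))
    naive_sum = sum(
        bump_footprint_fraction(b, 40.0) for b in bumps
    )
    assert len(truth.bump_footprint_fractions) == 1
    assert truth.bump_footprint_fractions[0] < naive_sum


def test_rigid_perturbation_recorded():
    mesh, truth = make_phantom(
        PhantomSpec(seed=4, subdivisions=4, rigid_perturbation=(10.0, 5.0))
    )
    assert truth.injected_transform is not None
    assert np.isclose(truth.injected_transform.rotation_angle_deg(), 10.0)
    assert np.isclose(np.linalg.norm(truth.injected_transform.translation), 5.0)


def test_vault_submesh():
    mesh, truth = make_phantom(PhantomSpec(seed=0, base_shape="orbit_like",
                                           subdivisions=4))
    vault = vault_submesh(mesh, truth)
    assert 0 < len(vault.faces) < len(mesh.faces)
    # the vault is the +z polar cap
    assert np.asarray(vault.vertices)[:, 2].min() > 0

    sheet, sheet_truth = make_phantom(PhantomSpec(seed=0,
                                                  base_shape="flat_sheet"))
    with pytest.raises(ValueError):
        vault_submesh(sheet, sheet_truth)


# ---------------------------------------------------------------------------
# volumes


def test_phantom_volume_classes_recovered_exactly():
    vol, masks = make_phantom_volume()
    fat = threshold_segment(vol, STANDARD_WINDOWS["orbital_fat"])
    assert np.array_equal(fat.voxels, masks["fat"])
    muscle = threshold_segment(
        vol, STANDARD_WINDOWS["extraocular_muscles_optic_nerve"]
    )
    assert np.array_equal(muscle.voxels, masks["muscle"])
    # the wide soft-tissue window selects exactly fat + muscle
    total = threshold_segment(vol, STANDARD_WINDOWS["total_orbital_volume"])
    assert np.array_equal(total.voxels, masks["fat"] | masks["muscle"])


def test_phantom_volume_bone_excluded_from_soft_windows():
    vol, masks = make_phantom_volume()
    for name in ("orbital_fat", "extraocular_muscles_optic_nerve",
                 "lacrimal_gland", "total_orbital_volume"):
        mask = threshold_segment(vol, STANDARD_WINDOWS[name])
        assert not (mask.voxels & masks["bone"]).any()


def test_phantom_volume_analytic_volumes():
    vol, masks = make_phantom_volume()
    fat_cm3 = measure_volume(
        threshold_segment(vol, STANDARD_WINDOWS["orbital_fat"])
    )
    analytic = 4.0 / 3.0 * np.pi * 5.0**3 / 1000.0
    assert abs(fat_cm3 - analytic) / analytic < 0.03


def test_phantom_volume_spacing_is_clinical():
    vol, _ = make_phantom_volume()
    assert vol.spacing == (0.4, 0.4, 0.6)


# ---------------------------------------------------------------------------
# cohorts


def test_make_cohort_shape_and_determinism():
    specs, table = make_cohort(5, seed=1)
    specs2, table2 = make_cohort(5, seed=1)
    assert len(specs) == 5
    assert len(table) == 10  # 2 structures per subject
    assert set(table.structure) == {"hard_tissue", "soft_tissue"}
    assert table.equals(table2)
    assert all(
        pair["hard_tissue"] == pair2["hard_tissue"]
        for pair, pair2 in zip(specs, specs2)
    )


def test_make_cohort_seeds_below_2_31():
    specs, _ = make_cohort(10, seed=0)
    for pair in specs:
        for spec in pair.values():
            assert 0 <= spec.seed < 2**31


def test_make_cohort_gsi_rms_coupling():
    _, table = make_cohort(30, seed=2)
    asym = table[table.footprint_fraction > 0]
    r = np.corrcoef(asym.expected_gsi, asym.expected_rms_mm)[0, 1]
    assert r < 0  # lower GSI (bigger bump) means higher RMS


def test_make_cohort_preconditions():
    with pytest.raises(ValueError):
        make_cohort(1)
    with pytest.raises(ValueError):
        make_cohort(5, hard_gsi_mean=1.5)


def test_expected_bump_rms_order_of_magnitude():
    # the flat-patch closed form overestimates the measured closest-point
    # RMS (the nearest mirrored point is closer than the radial gap along
    # the taper) but must stay within a factor of two
    mesh, truth = make_bump_phantom(0.15, subdivisions=5, seed=3)
    field = signed_deviation(mesh, mirror_mesh(mesh, truth.plane))
    measured = float(np.sqrt(np.mean(field.values**2)))
    radius = solve_bump_radius(0.15, 3.0, 40.0)
    predicted = expected_bump_rms(0.15, 3.0, 40.0, radius)
    assert measured < predicted < 2.0 * measured
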