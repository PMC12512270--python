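# orbisym

Surface-based bilateral symmetry analysis for cranio-orbital anatomy.

`orbisym` quantifies how symmetric a 3-D anatomical surface is about its
midsagittal plane. It mirrors the surface across the plane, rigidly
registers the mirror back onto the original (optionally through a stable
reference such as the skull vault), computes an exact signed closest-point
deviation map, segments it at a clinical ±1 mm band, and reduces it to a
**global symmetry index** (GSI: fraction of surface area whose mirror
deviation lies within the band) and per-zone **local symmetry indices**
(LSI) over ~25 mm² grid cells grouped into named anatomical zones. A
companion layer segments CT volumes by Hounsfield-unit windows, measures
structure volumes, and runs cohort-level statistics. A phantom generator
produces surfaces and CT volumes with *analytic* ground truth (known
symmetry plane, known asymmetric footprint, known volumes), which is how
the whole pipeline is validated.

See [docs/methods.md](docs/methods.md) for the model, numerical choices
and limitations.

## Quick start

```python
from orbisym.phantom import make_bump_phantom
from orbisym.pipeline import run_symmetry_on_mesh

# a 40 mm sphere with a 3 mm bump over 12% of its surface (expected GSI 0.88)
mesh, truth = make_bump_phantom(footprint_fraction=0.12, amplitude_mm=3.0,
                                seed=0)

run = run_symmetry_on_mesh(mesh, plane=truth.plane, seed=0)
print(run.report.gsi)        # 0.927 (rigid registration absorbs some deformity)
print(run.report.rms_mm)     # 0.574 mm
```

Typical printed output of `examples/01_single_surface_symmetry.py`:

```
phantom: 32768 faces, expected GSI = 0.880
midsagittal plane normal: [1. 0. 0.]
registration RMS        : 5.63e-01 mm
GSI (area within band)  : 0.927
deviation RMS           : 0.574 mm
asymmetric area         : 1473 mm2 of 20267 mm2
GSI vs unregistered mirror: 0.875 (expected 0.880)
```

The last line illustrates a real methodological trade-off: registering a
genuinely asymmetric surface absorbs part of the deformity into the
alignment. When the midsagittal plane is known, comparing against the
unregistered mirror recovers the planted asymmetric fraction to ~0.005.

## Command line

Each pipeline stage is exposed as a subcommand; each writes its artifacts
into an output directory and prints a one-line JSON summary:

```bash
orbisym simulate --out sim --footprint 0.1 --seed 1   # phantom + ground truth
orbisym segment  --volume ct.nii.gz --window orbital_fat --out seg
orbisym register --moving model.stl --out-transform t.json
orbisym compare  --true-mesh a.stl --other b.stl --out cmp
orbisym grid     --mesh model.stl --out grid
orbisym indices  --mesh model.stl --out run          # full single-model run
orbisym cohort   run1/report.json run2/report.json --out cohort
```

## Library layout

| module                | contents                                             |
|-----------------------|------------------------------------------------------|
| `mesh_io`             | STL/PLY read/write, welding, annotated PLY maps      |
| `mirror_register`     | planes, rigid transforms, plane estimation, ICP      |
| `proximity`           | exact point-to-surface closest-point queries         |
| `deviation_map`       | signed deviation fields, band segmentation, colormaps|
| `surface_grid`        | ~25 mm² grid cells, named zones                      |
| `symmetry_indices`    | GSI, LSI, zone RMS, reports                          |
| `volume_segmentation` | HU windows, volume measurement, marching cubes, NIfTI|
| `phantom`             | ground-truth phantoms: meshes, CT volumes, cohorts   |
| `cohort_stats`        | normality, two/multi-group tests, correlations       |
| `pipeline`            | orchestration: configs, runs, artifacts, cohort stats|

## Testing and validation

```bash
python -m pytest            # full suite, ~40 s
```

`tests/test_acceptance.py` contains one test per package-level acceptance
property (exactness on symmetric phantoms, rigid-transform recovery,
equivalence with an exhaustive distance oracle, GSI recovery against
analytic footprints, partition identities, HU-window exactness, statistical
oracle agreement, type-I error calibration, and power on planted effects).

The same quantities can be recomputed and written as JSON:

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

which produces, for example:

```json
{
  "null_gsi": 1.0,
  "icp_rotation_error_deg": 0.0,
  "gsi_recovery_max_abs_error": 0.0085,
  "type_one_error_rate": 0.057,
  "paired_effect_power": 1.0
}
```

All pipeline stages are deterministic given a seed: reruns are
byte-identical.

## Examples

Narrative scripts in [examples/](examples/):

1. `01_single_surface_symmetry.py` — full pipeline on a bump phantom, with
   the registration-bias caveat shown numerically.
2. `02_reference_based_registration.py` — propagating a vault-estimated
   transform to target structures.
3. `03_ct_volume_segmentation.py` — HU windowing, volume measurement and
   surface extraction on a synthetic CT.
4. `04_cohort_statistics.py` — paired hard- vs soft-tissue contrast and
   GSI–RMS correlation on a synthetic cohort.
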