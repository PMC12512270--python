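"""Shared fixtures for the test suite.

Phantom resolutions here are chosen small (subdivisions 4-5, a few
thousand faces) so individual tests run in well under a second; the
acceptance tests use the package default resolution.
"""

import numpy as np
import pytest
import trimesh

from orbisym.phantom import PhantomSpec, make_phantom


@pytest.fixture(scope="session")
def small_sphere():
    """~2k-face exactly symmetric sphere phantom (mesh only)."""
    mesh, _ = make_phantom(PhantomSpec(seed=0, subdivisions=4))
    return mesh


@pytest.fixture(scope="session")
def orbit_mesh():
    """~8k-face orbit-like phantom: symmetric only about x=0."""
    mesh, _ = make_phantom(PhantomSpec(seed=0, base_shape="orbit_like",
                                       subdivisions=5))
    return mesh


@pytest.fixture(scope="session")
def sheet_50mm():
    """Flat 50x50 mm sheet (z=0 plane), exactly symmetric about x=0."""
    mesh, _ = make_phantom(PhantomSpec(seed=0, base_shape="flat_sheet",
                                       radius_mm=25.0, subdivisions=5))
    return mesh


def random_mesh(seed: int, max_faces: int = 500) -> trimesh.Trimesh:
    """Random small closed mesh: convex hull of random points, optionally
    anisotropically scaled so triangles vary in shape."""
    rng = np.random.default_rng(seed)
    n_pts = int(rng.integers(8, 120))
    pts = rng.normal(size=(n_pts, 3)) * rng.uniform(0.5, 20.0, size=3)
    hull = trimesh.convex.convex_hull(pts)
    if len(hull.faces) > max_faces:
        hull = trimesh.convex.convex_hull(pts[: max_faces // 2])
    return trimesh.Trimesh(vertices=hull.vertices.copy(),
                           faces=hull.faces.copy(), process=False)
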