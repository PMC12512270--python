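"""Closest-point queries from points to a triangle mesh surface.

The deviation map and ICP registration both reduce to the same primitive:
for a batch of query points, find the nearest point on a triangulated
surface, the distance to it, and the triangle it lies on.  The query is
exact: a KD-tree on the mesh vertices gives an upper bound on the surface
distance for each query point, and every triangle whose centroid lies
within ``upper_bound + R`` (``R`` = largest centroid-to-vertex distance of
any triangle) is then tested with an exact point-to-triangle computation.
No triangle that could contain the true closest point is ever pruned.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial import cKDTree


def closest_point_on_triangles(
    points: np.ndarray, triangles: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Exact closest point on each triangle for each (point, triangle) pair.

    Parameters
    ----------
    points : (n, 3) float array
    triangles : (n, 3, 3) float array, one triangle per point

    Returns
    -------
    closest : (n, 3) closest points on the triangles
    distance : (n,) Euclidean distances
    """
    points = np.asarray(points, dtype=np.float64)
    triangles = np.asarray(triangles, dtype=np.float64)
    a, b, c = triangles[:, 0], triangles[:, 1], triangles[:, 2]

    e0 = b - a
    e1 = c - a
    pa = points - a
    d00 = np.einsum("ij,ij->i", e0, e0)
    d01 = np.einsum("ij,ij->i", e0, e1)
    d11 = np.einsum("ij,ij->i", e1, e1)
    d20 = np.einsum("ij,ij->i", pa, e0)
    d21 = np.einsum("ij,ij->i", pa, e1)
    denom = d00 * d11 - d01 * d01

    ok = denom > 1e-300
    inv = np.where(ok, denom, 1.0)
    v = (d11 * d20 - d01 * d21) / inv
    w = (d00 * d21 - d01 * d20) / inv
    inside = ok & (v >= 0.0) & (w >= 0.0) & (v + w <= 1.0)

    proj = a + v[:, None] * e0 + w[:, None] * e1

    def _segment(p0: np.ndarray, p1: np.ndarray) -> np.ndarray:
        d = p1 - p0
        dd = np.einsum("ij,ij->i", d, d)
        t = np.einsum("ij,ij->i", points - p0, d) / np.where(dd > 0.0, dd, 1.0)
        t = np.clip(np.where(dd > 0.0, t, 0.0), 0.0, 1.0)
        return p0 + t[:, None] * d

    # candidates: in-plane projection (when inside) plus the three edges
    cands = np.stack(
        [
            np.where(inside[:, None], proj, np.inf),
            _segment(a, b),
            _segment(b, c),
            _segment(c, a),
        ],
        axis=1,
    )  # (n, 4, 3)
    diff = cands - points[:, None, :]
    d2 = np.einsum("ijk,ijk->ij", diff, diff)
    best = np.argmin(d2, axis=1)
    idx = np.arange(len(points))
    closest = cands[idx, best]
    return closest, np.sqrt(d2[idx, best])


class MeshProximity:
    """Reusable exact closest-point structure for one triangle mesh.

    Build once per mesh; ``query`` may be called repeatedly (e.g. every
    ICP iteration).
    """

    def __init__(self, mesh) -> None:
        self.mesh = mesh
        self._triangles = np.asarray(mesh.triangles, dtype=np.float64)
        self._centroids = self._triangles.mean(axis=1)
        # largest centroid-to-vertex distance over all triangles: the
        # pruning radius must cover it for the search to stay exact
        self._radius = float(
            np.sqrt(
                ((self._triangles - self._centroids[:, None, :]) ** 2)
                .sum(axis=2)
                .max()
            )
        )
        self._vertex_tree = cKDTree(np.asarray(mesh.vertices, dtype=np.float64))
        self._centroid_tree = cKDTree(self._centroids)

    def query(
        self, points: np.ndarray
    ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Closest surface point, distance and triangle index per query.

        Returns ``(closest, distance, triangle_id)``.
        """
        points = np.atleast_2d(np.asarray(points, dtype=np.float64))
        n = len(points)
        upper, _ = self._vertex_tree.query(points)
        # tiny slack keeps boundary candidates when upper bound is tight
        radii = upper + self._radius + 1e-9 + 1e-12 * np.abs(upper)
        cand_lists = self._centroid_tree.query_ball_point(points, radii)

        lengths = np.fromiter((len(c) for c in cand_lists), dtype=np.intp, count=n)
        if lengths.min() == 0:  # cannot happen with a valid bound; be safe
            raise RuntimeError("closest-point candidate search returned no triangles")
        flat_tri = np.concatenate([np.asarray(c, dtype=np.intp) for c in cand_lists])
        owner = np.repeat(np.arange(n), lengths)

        cpts, dists = closest_point_on_triangles(
            points[owner], self._triangles[flat_tri]
        )
        # per-query argmin over its candidate block
        order = np.lexsort((dists, owner))
        starts = np.zeros(n, dtype=np.intp)
        starts[1:] = np.cumsum(lengths)[:-1]
        pick = order[starts]
        return cpts[pick], dists[pick], flat_tri[pick]
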