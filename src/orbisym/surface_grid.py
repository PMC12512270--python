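"""Surface grid cells (~25 mm² patches) and named anatomical zones.

Clinical surface tools divide a model into approximately equal grid cells
(5 x 5 mm nominal) for local bookkeeping; named anatomical zones (orbital
apex, medial/lateral wall, floor + inferior rim, roof + superior rim,
upper/lower eyelid) are then built from grid cells.  Exactly equal square
cells do not exist on a curved surface, so cells are produced as connected,
area-balanced face patches: planar meshes get an exact square tiling, and
curved meshes get farthest-point seeding at ``round(area / target)`` seeds
followed by area-balanced region growing over the face adjacency graph.
Both constructions are deterministic.
"""

from __future__ import annotations

import heapq
import json
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import trimesh
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components

log = logging.getLogger(__name__)

#: canonical zone vocabulary; users may extend it
HARD_TISSUE_ZONES = (
    "orbital_apex",
    "medial_wall",
    "lateral_wall",
    "floor_inferior_rim",
    "roof_superior_rim",
)
SOFT_TISSUE_ZONES = ("upper_eyelid", "lower_eyelid")
CANONICAL_ZONES = HARD_TISSUE_ZONES + SOFT_TISSUE_ZONES

UNLABELED = "none"


@dataclass
class GridCellMap:
    """Partition of mesh faces into connected, roughly equal-area cells."""

    mesh: trimesh.Trimesh
    cell_of_face: np.ndarray  # int cell id per face
    target_cell_area: float = 25.0

    @property
    def n_cells(self) -> int:
        return int(self.cell_of_face.max()) + 1

    @property
    def cell_areas(self) -> np.ndarray:
        return np.bincount(
            self.cell_of_face,
            weights=np.asarray(self.mesh.area_faces),
            minlength=self.n_cells,
        )


@dataclass
class ZoneMap:
    """Zone name per cell (and therefore per face)."""

    cells: GridCellMap
    zone_of_cell: np.ndarray  # str array, UNLABELED where unassigned

    @property
    def zone_of_face(self) -> np.ndarray:
        return self.zone_of_cell[self.cells.cell_of_face]

    @property
    def zones(self) -> list[str]:
        names = set(self.zone_of_cell.tolist()) - {UNLABELED}
        return sorted(names)

    def zone_area(self, zone: str) -> float:
        mask = self.zone_of_face == zone
        if not mask.any():
            raise KeyError(f"zone {zone!r} is empty or unknown")
        return float(np.asarray(self.cells.mesh.area_faces)[mask].sum())


def _face_adjacency_graph(mesh: trimesh.Trimesh) -> list[list[int]]:
    adj = [[] for _ in range(len(mesh.faces))]
    for a, b in mesh.face_adjacency:
        adj[a].append(int(b))
        adj[b].append(int(a))
    return adj


def _planar_tiling(mesh: trimesh.Trimesh, side: float) -> np.ndarray | None:
    """Exact square tiling for planar meshes; None when the mesh is curved."""
    normals = np.asarray(mesh.face_normals)
    if np.abs(normals @ normals[0] - 1.0).max() > 1e-9:
        return None
    n = normals[0]
    # build an in-plane orthonormal basis
    u = np.cross(n, [1.0, 0.0, 0.0])
    if np.linalg.norm(u) < 1e-6:
        u = np.cross(n, [0.0, 1.0, 0.0])
    u /= np.linalg.norm(u)
    v = np.cross(n, u)
    centers = np.asarray(mesh.triangles_center)
    origin = np.asarray(mesh.vertices).min(axis=0)
    iu = np.floor((centers - origin) @ u / side + 1e-9).astype(np.int64)
    iv = np.floor((centers - origin) @ v / side + 1e-9).astype(np.int64)
    _, cell = np.unique(np.column_stack([iu, iv]), axis=0, return_inverse=True)
    return cell


def _split_disconnected_cells(mesh: trimesh.Trimesh, cell: np.ndarray) -> np.ndarray:
    """Ensure each cell's faces are edge-connected by splitting stragglers."""
    pairs = mesh.face_adjacency
    same = cell[pairs[:, 0]] == cell[pairs[:, 1]]
    pairs = pairs[same]
    n = len(mesh.faces)
    graph = coo_matrix(
        (np.ones(len(pairs)), (pairs[:, 0], pairs[:, 1])), shape=(n, n)
    )
    _, comp = connected_components(graph, directed=False)
    _, out = np.unique(comp, return_inverse=True)
    return out


def grid_segment(
    mesh: trimesh.Trimesh, target_cell_area: float = 25.0, seed: int = 0
) -> GridCellMap:
    """Partition the surface into connected ~``target_cell_area`` mm² cells.

    Planar meshes are tiled with exact squares of side
    ``sqrt(target_cell_area)``.  Curved meshes are seeded by deterministic
    farthest-point sampling of face centroids at ``round(area / target)``
    seeds and grown area-balanced over the face adjacency graph (the
    smallest cell always grows first).  ``seed`` selects the first
    farthest-point sample and is part of the deterministic recipe.
    """
    total_area = float(mesh.area)
    if total_area < target_cell_area:
        warnings.warn(
            "mesh smaller than one grid cell; returning a single cell",
            stacklevel=2,
        )
        return GridCellMap(mesh, np.zeros(len(mesh.faces), dtype=np.int64),
                           target_cell_area)

    cell = _planar_tiling(mesh, float(np.sqrt(target_cell_area)))
    if cell is None:
        cell = _grow_balanced_cells(mesh, target_cell_area, seed)
    cell = _split_disconnected_cells(mesh, cell)
    # splitting can strand small fragments (e.g. staircase boundaries that
    # touch only at vertices); fold them back into an adjacent cell
    cell = _rebalance_cells(
        cell,
        _face_adjacency_graph(mesh),
        np.asarray(mesh.area_faces, dtype=np.float64),
        np.asarray(mesh.triangles_center, dtype=np.float64),
        target_cell_area,
    )
    return GridCellMap(mesh, cell.astype(np.int64), target_cell_area)


def _farthest_point_seeds(centers: np.ndarray, areas: np.ndarray,
                          n_seeds: int, seed: int) -> np.ndarray:
    rng = np.random.default_rng(seed)
    first = int(rng.integers(len(centers)))
    seeds = [first]
    dist = np.linalg.norm(centers - centers[first], axis=1)
    for _ in range(n_seeds - 1):
        nxt = int(np.argmax(dist))
        seeds.append(nxt)
        dist = np.minimum(dist, np.linalg.norm(centers - centers[nxt], axis=1))
    return np.array(seeds, dtype=np.int64)


def _grow_balanced_cells(
    mesh: trimesh.Trimesh, target_cell_area: float, seed: int,
) -> np.ndarray:
    """Farthest-point seeding + area-balanced growth, then merge/split
    rebalancing so cell areas concentrate around the target."""
    areas = np.asarray(mesh.area_faces, dtype=np.float64)
    centers = np.asarray(mesh.triangles_center, dtype=np.float64)
    n_cells = max(1, int(round(float(mesh.area) / target_cell_area)))
    seeds = _farthest_point_seeds(centers, areas, n_cells, seed)
    adj = _face_adjacency_graph(mesh)

    cell = _grow_from_seeds(seeds, adj, areas, centers, n_cells)
    return _rebalance_cells(cell, adj, areas, centers, target_cell_area)


def _rebalance_cells(
    cell: np.ndarray,
    adj: list[list[int]],
    areas: np.ndarray,
    centers: np.ndarray,
    target: float,
    max_rounds: int = 10,
) -> np.ndarray:
    """Merge under-sized cells into an adjacent cell and bisect over-sized
    ones until areas lie (mostly) within [0.5, 1.5] x target.

    Merging two edge-adjacent connected patches keeps connectivity;
    splitting regrows two balanced halves inside the cell from its farthest
    face pair, so both halves stay connected too.
    """
    cell = cell.copy()
    for _ in range(max_rounds):
        changed = False
        cell_area = _areas_by_label(cell, areas)
        # merge small cells into their smallest adjacent neighbour
        neighbours = _cell_adjacency(cell, adj)
        for c in sorted(cell_area, key=cell_area.get):
            if cell_area[c] >= 0.5 * target:
                continue
            nbs = [n for n in neighbours.get(c, ()) if n in cell_area and n != c]
            if not nbs:
                continue
            best = min(nbs, key=lambda n: (cell_area[n], n))
            cell[cell == c] = best
            cell_area[best] += cell_area.pop(c)
            neighbours.setdefault(best, set()).update(neighbours.get(c, set()))
            changed = True
        # split big cells into two balanced connected halves
        next_label = int(cell.max()) + 1
        for c, a in list(cell_area.items()):
            if a <= 1.5 * target:
                continue
            members = np.flatnonzero(cell == c)
            d = ((centers[members] - centers[members[0]]) ** 2).sum(axis=1)
            s0 = members[int(np.argmax(d))]
            d = ((centers[members] - centers[s0]) ** 2).sum(axis=1)
            s1 = members[int(np.argmax(d))]
            local = set(members.tolist())
            sub_adj = {f: [n for n in adj[f] if n in local] for f in local}
            half = _grow_two_halves(s0, s1, sub_adj, areas)
            cell[np.fromiter(half, dtype=np.int64)] = next_label
            next_label += 1
            changed = True
        if not changed:
            break
    _, out = np.unique(cell, return_inverse=True)
    return out


def _areas_by_label(cell: np.ndarray, areas: np.ndarray) -> dict[int, float]:
    labels = np.unique(cell)
    sums = np.bincount(
        np.searchsorted(labels, cell), weights=areas, minlength=len(labels)
    )
    return {int(l): float(s) for l, s in zip(labels, sums)}


def _cell_adjacency(cell: np.ndarray, adj: list[list[int]]) -> dict[int, set]:
    out: dict[int, set] = {}
    for f, nbs in enumerate(adj):
        cf = int(cell[f])
        for n in nbs:
            cn = int(cell[n])
            if cn != cf:
                out.setdefault(cf, set()).add(cn)
    return out


def _grow_two_halves(
    s0: int, s1: int, sub_adj: dict[int, list[int]], areas: np.ndarray
) -> set[int]:
    """Area-balanced bipartition of a connected face set; returns the faces
    of the half grown from ``s1``."""
    owner = {s0: 0, s1: 1}
    half_area = [areas[s0], areas[s1]]
    heap: list[tuple[float, int, int]] = []
    for h, s in ((0, s0), (1, s1)):
        for nb in sub_adj[s]:
            if nb not in owner:
                heapq.heappush(heap, (half_area[h] + areas[nb], h, nb))
    while heap:
        prio, h, f = heapq.heappop(heap)
        if f in owner:
            continue
        fresh = half_area[h] + areas[f]
        if fresh > prio + 1e-12:
            heapq.heappush(heap, (fresh, h, f))
            continue
        owner[f] = h
        half_area[h] = fresh
        for nb in sub_adj[f]:
            if nb not in owner:
                heapq.heappush(heap, (half_area[h] + areas[nb], h, nb))
    # faces unreachable from either seed stay with half 0
    return {f for f, h in owner.items() if h == 1}


def _grow_from_seeds(
    seeds: np.ndarray, adj: list[list[int]], areas: np.ndarray,
    centers: np.ndarray, n_cells: int,
) -> np.ndarray:
    cell = np.full(len(areas), -1, dtype=np.int64)
    cell_area = np.zeros(n_cells)
    heap: list[tuple[float, float, int, int]] = []
    for c, f in enumerate(seeds):
        if cell[f] == -1:
            cell[f] = c
            cell_area[c] = areas[f]
            for nb in adj[f]:
                # priority: area the cell would have after absorbing nb;
                # distance to the seed breaks ties deterministically
                heapq.heappush(
                    heap,
                    (cell_area[c] + areas[nb],
                     float(np.linalg.norm(centers[nb] - centers[f])), c, nb),
                )
    while heap:
        prio, tie, c, f = heapq.heappop(heap)
        if cell[f] != -1:
            continue
        fresh = cell_area[c] + areas[f]
        if fresh > prio + 1e-12:
            # the cell grew since this entry was pushed; re-queue so the
            # currently smallest cell gets to grow first
            heapq.heappush(heap, (fresh, tie, c, f))
            continue
        cell[f] = c
        cell_area[c] += areas[f]
        for nb in adj[f]:
            if cell[nb] == -1:
                heapq.heappush(
                    heap,
                    (cell_area[c] + areas[nb],
                     float(np.linalg.norm(centers[nb] - centers[f])), c, nb),
                )
    # isolated faces (no adjacency path to any seed) become their own cells
    orphan = np.flatnonzero(cell == -1)
    if len(orphan):
        cell[orphan] = n_cells + np.arange(len(orphan))
    return cell


def assign_zones(
    cells: GridCellMap,
    seeds: dict[str, list],
    max_distance: float | None = None,
) -> ZoneMap:
    """Assign zone names to grid cells from per-zone seeds.

    ``seeds`` maps zone name to either face indices or 3D points (each
    point labels the cell of its nearest face centroid).  Unseeded cells
    take the zone of the nearest seeded cell centroid within the same
    connected surface component; with ``max_distance`` set (mm), cells
    farther than that from every seeded cell stay unlabeled.
    """
    mesh = cells.mesh
    n_cells = cells.n_cells
    centers = np.asarray(mesh.triangles_center)
    areas = np.asarray(mesh.area_faces)

    # area-weighted cell centroids
    cell_centroid = np.zeros((n_cells, 3))
    for k in range(3):
        cell_centroid[:, k] = np.bincount(
            cells.cell_of_face, weights=centers[:, k] * areas, minlength=n_cells
        )
    cell_centroid /= cells.cell_areas[:, None]

    zone_of_cell = np.full(n_cells, UNLABELED, dtype=object)
    for zone, spec in seeds.items():
        spec = np.asarray(spec)
        if spec.ndim == 2 and spec.shape[1] == 3:  # points
            d = np.linalg.norm(
                centers[None, :, :] - spec[:, None, :].astype(float), axis=2
            )
            face_idx = d.argmin(axis=1)
        else:  # face indices
            face_idx = spec.astype(np.int64).ravel()
            if (face_idx < 0).any() or (face_idx >= len(mesh.faces)).any():
                raise ValueError(f"zone {zone!r} references nonexistent faces")
        for f in face_idx:
            zone_of_cell[cells.cell_of_face[f]] = zone

    labeled = np.flatnonzero(zone_of_cell != UNLABELED)
    if len(labeled) == 0:
        raise ValueError("no zone seeds provided")

    # connected components of cells (via face adjacency crossing cells)
    pairs = mesh.face_adjacency
    ca, cb = cells.cell_of_face[pairs[:, 0]], cells.cell_of_face[pairs[:, 1]]
    graph = coo_matrix(
        (np.ones(len(ca)), (ca, cb)), shape=(n_cells, n_cells)
    )
    _, comp = connected_components(graph, directed=False)

    unlabeled = np.flatnonzero(zone_of_cell == UNLABELED)
    for c in unlabeled:
        same = labeled[comp[labeled] == comp[c]]
        if len(same) == 0:
            continue
        d = np.linalg.norm(cell_centroid[same] - cell_centroid[c], axis=1)
        k = int(np.argmin(d))
        if max_distance is not None and d[k] > max_distance:
            continue
        zone_of_cell[c] = zone_of_cell[same[k]]
    return ZoneMap(cells=cells, zone_of_cell=np.asarray(zone_of_cell, dtype=object))


def load_zone_seeds(path) -> dict[str, list]:
    """Read a zone seed file: JSON ``{zone: [face indices] | [[x,y,z], ...]}``."""
    with open(path) as fh:
        return json.load(fh)


def zone_area_table(
    zonemaps: dict[str, dict[str, ZoneMap]]
) -> pd.DataFrame:
    """Long-format table of zone areas: subject x zone x side.

    ``zonemaps`` maps subject id -> side ('right'/'left') -> ZoneMap.
    Missing sides produce rows flagged ``missing``.  The output feeds the
    cohort right-vs-left comparisons.
    """
    vocab: set[str] = set()
    for sides in zonemaps.values():
        for zm in sides.values():
            vocab |= set(zm.zones)
    rows = []
    for subject, sides in zonemaps.items():
        for side in ("right", "left"):
            zm = sides.get(side)
            for zone in sorted(vocab):
                if zm is None:
                    rows.append(
                        dict(subject=subject, zone=zone, side=side,
                             area_mm2=np.nan, missing=True)
                    )
                    continue
                try:
                    area = zm.zone_area(zone)
                except KeyError:
                    area, miss = np.nan, True
                else:
                    miss = False
                rows.append(
                    dict(subject=subject, zone=zone, side=side,
                         area_mm2=area, missing=miss)
                )
    return pd.DataFrame(rows)
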