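"""Cortical-unit parcellation and subcortical seed-layer extraction.

The GM-WM mesh is partitioned into K connected, approximately equal-area
surface patches (cortical units, CUs): K vertices are chosen by geodesic
farthest-point sampling, faces are assigned by area-balanced multi-source
region growing from the seeds (the smallest patch claims the next adjacent
face, keeping areas near-equal and patches connected by construction), and
a repair pass reattaches any stray disconnected face groups.  The whole
procedure is deterministic given ``rng_seed``.

Each CU's tracking seed mask is the subcortical voxel layer beneath it:
voxels whose centers lie within ``thickness`` mm of the surface on the
inward-normal (white-matter) side, each voxel assigned to the CU owning its
nearest surface point, so masks are pairwise disjoint by construction.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
import scipy.sparse as sp
from scipy.sparse.csgraph import connected_components, dijkstra
from scipy.spatial import cKDTree
from trimesh.triangles import closest_point as _triangle_closest_point

from .core import SurfaceMesh, TensorVolume


@dataclasses.dataclass
class CorticalUnit:
    """One connected surface patch and its volume-space seed mask."""

    id: int
    vertex_ids: np.ndarray
    face_ids: np.ndarray
    area: float
    seed_voxels: np.ndarray | None = None  # (N, 3) voxel indices
    seed_volume: float = np.nan  # |seed voxels| * voxel volume, mm^3

    @property
    def n_seed_voxels(self) -> int:
        return 0 if self.seed_voxels is None else len(self.seed_voxels)


class Parcellation:
    """An ordered list of cortical units forming a face partition of a mesh."""

    def __init__(self, mesh: SurfaceMesh, units: list[CorticalUnit], face_labels: np.ndarray):
        self.mesh = mesh
        self.units = units
        self.face_labels = np.asarray(face_labels, dtype=int)
        self._vertex_labels: np.ndarray | None = None

    @property
    def K(self) -> int:
        return len(self.units)

    def __iter__(self):
        return iter(self.units)

    def __getitem__(self, i: int) -> CorticalUnit:
        return self.units[i]

    @property
    def vertex_labels(self) -> np.ndarray:
        """Owning CU per vertex: majority over incident faces, ties broken by
        the lower CU id."""
        if self._vertex_labels is None:
            V, K = self.mesh.n_vertices, self.K
            counts = np.zeros((V, K), dtype=np.int32)
            faces = self.mesh.faces
            for c in range(3):
                np.add.at(counts, (faces[:, c], self.face_labels), 1)
            self._vertex_labels = np.argmax(counts, axis=1)  # argmax -> lowest id on ties
        return self._vertex_labels


def _farthest_point_seeds(graph: sp.csr_matrix, k: int, rng_seed: int) -> np.ndarray:
    rng = np.random.default_rng(rng_seed)
    n = graph.shape[0]
    seeds = [int(rng.integers(n))]
    dist = dijkstra(graph, directed=False, indices=seeds[0])
    for _ in range(k - 1):
        nxt = int(np.argmax(dist))
        seeds.append(nxt)
        dist = np.minimum(dist, dijkstra(graph, directed=False, indices=nxt))
    return np.asarray(seeds)


def _patch_medoids(mesh: SurfaceMesh, labels: np.ndarray, K: int) -> np.ndarray:
    """Per patch, the mesh vertex nearest the patch's area-weighted centroid."""
    centroids = mesh.face_centroids
    areas = mesh.face_areas
    seeds = np.empty(K, dtype=int)
    for k in range(K):
        fids = np.flatnonzero(labels == k)
        center = np.average(centroids[fids], axis=0, weights=areas[fids])
        vids = np.unique(mesh.faces[fids])
        seeds[k] = vids[np.argmin(np.linalg.norm(mesh.vertices[vids] - center, axis=1))]
    return seeds


def _balanced_face_growth(mesh: SurfaceMesh, seed_vertices: np.ndarray) -> np.ndarray:
    """Area-balanced multi-source region growing over the face graph.

    Each patch starts at a face incident to its seed vertex; patches then
    claim unclaimed adjacent faces in order of current patch area (smallest
    first, lazy heap), which keeps patches connected by construction and
    their areas close to equal.
    """
    import heapq

    n_faces = mesh.n_faces
    areas = mesh.face_areas
    fadj = mesh.face_adjacency
    neighbors: list[list[int]] = [[] for _ in range(n_faces)]
    for a, b in fadj:
        neighbors[a].append(int(b))
        neighbors[b].append(int(a))
    vertex_faces = [[] for _ in range(mesh.n_vertices)]
    for fid, face in enumerate(mesh.faces):
        for v in face:
            vertex_faces[v].append(fid)

    labels = np.full(n_faces, -1, dtype=int)
    patch_area = np.zeros(len(seed_vertices))
    heap: list[tuple[float, int, int, int]] = []
    counter = 0
    for k, sv in enumerate(seed_vertices):
        # nearest unclaimed face to the seed vertex (tiny BFS fallback)
        start = next((fid for fid in vertex_faces[sv] if labels[fid] == -1), None)
        if start is None:
            frontier = list(vertex_faces[sv])
            seen = set(frontier)
            while frontier and start is None:
                nxt = []
                for f in frontier:
                    for nb in neighbors[f]:
                        if nb in seen:
                            continue
                        if labels[nb] == -1:
                            start = nb
                            break
                        seen.add(nb)
                        nxt.append(nb)
                    if start is not None:
                        break
                frontier = nxt
            if start is None:
                raise RuntimeError("could not place a patch seed on an unclaimed face")
        labels[start] = k
        patch_area[k] = areas[start]
        for nb in neighbors[start]:
            if labels[nb] == -1:
                heapq.heappush(heap, (patch_area[k], counter, k, nb))
                counter += 1
    while heap:
        a, _, k, fid = heapq.heappop(heap)
        if labels[fid] != -1:
            continue
        if a < patch_area[k] - 1e-12:  # stale priority: re-queue at current area
            heapq.heappush(heap, (patch_area[k], counter, k, fid))
            counter += 1
            continue
        labels[fid] = k
        patch_area[k] += areas[fid]
        for nb in neighbors[fid]:
            if labels[nb] == -1:
                heapq.heappush(heap, (patch_area[k], counter, k, nb))
                counter += 1
    if (labels == -1).any():
        raise RuntimeError("region growing left unassigned faces (mesh disconnected?)")
    return labels


def _balance_patches(
    mesh: SurfaceMesh,
    labels: np.ndarray,
    K: int,
    target_ratio: float = 2.5,
    max_moves: int = 20000,
) -> np.ndarray:
    """Even out patch areas by moving single boundary faces from larger to
    smaller patches, never breaking the donor's face connectivity."""
    labels = labels.copy()
    areas = mesh.face_areas
    fadj = mesh.face_adjacency
    neighbors: list[list[int]] = [[] for _ in range(mesh.n_faces)]
    for a, b in fadj:
        neighbors[a].append(int(b))
        neighbors[b].append(int(a))
    patch_area = np.bincount(labels, weights=areas, minlength=K)
    patch_faces: list[set[int]] = [set() for _ in range(K)]
    for fid, lab in enumerate(labels):
        patch_faces[lab].add(fid)

    def donor_stays_connected(q: int, fid: int) -> bool:
        rest = patch_faces[q] - {fid}
        if not rest:
            return False
        start = next(iter(rest))
        seen = {start}
        stack = [start]
        while stack:
            f = stack.pop()
            for nb in neighbors[f]:
                if nb in rest and nb not in seen:
                    seen.add(nb)
                    stack.append(nb)
        return len(seen) == len(rest)

    for _ in range(max_moves):
        order = np.argsort(patch_area)
        if patch_area[order[-1]] <= target_ratio * patch_area[order[0]]:
            break
        moved = False
        for s in order[: K // 20 + 1]:  # a few smallest patches per round
            best = None
            for f in patch_faces[s]:
                for nb in neighbors[f]:
                    q = labels[nb]
                    if q == s:
                        continue
                    gain = patch_area[q] - patch_area[s] - 2.0 * areas[nb]
                    if gain > 0 and (best is None or gain > best[0]):
                        if donor_stays_connected(q, nb):
                            best = (gain, nb, q)
            if best is not None:
                _, fid, q = best
                labels[fid] = s
                patch_faces[q].discard(fid)
                patch_faces[s].add(fid)
                patch_area[q] -= areas[fid]
                patch_area[s] += areas[fid]
                moved = True
        if not moved:
            break
    return labels


def _face_subgraph(face_adjacency: np.ndarray, member: np.ndarray, n_faces: int) -> sp.csr_matrix:
    """Adjacency over faces restricted to ``member`` (boolean over faces)."""
    keep = member[face_adjacency[:, 0]] & member[face_adjacency[:, 1]]
    pairs = face_adjacency[keep]
    data = np.ones(len(pairs) * 2)
    rows = np.concatenate([pairs[:, 0], pairs[:, 1]])
    cols = np.concatenate([pairs[:, 1], pairs[:, 0]])
    return sp.csr_matrix((data, (rows, cols)), shape=(n_faces, n_faces))


def _repair_connectivity(mesh: SurfaceMesh, labels: np.ndarray) -> np.ndarray:
    """Keep, per label, the largest face-connected component; iteratively
    reattach every orphan face to an adjacent surviving label."""
    labels = labels.copy()
    n_faces = mesh.n_faces
    fadj = mesh.face_adjacency
    areas = mesh.face_areas
    orphan = np.zeros(n_faces, dtype=bool)
    for lab in np.unique(labels):
        member = labels == lab
        sub = _face_subgraph(fadj, member, n_faces)
        idx = np.flatnonzero(member)
        n_comp, comp = connected_components(sub[idx][:, idx], directed=False)
        if n_comp <= 1:
            continue
        comp_areas = np.bincount(comp, weights=areas[idx])
        keep = int(np.argmax(comp_areas))
        orphan[idx[comp != keep]] = True
    # grow surviving labels into orphan faces, nearest-adjacent first
    while orphan.any():
        changed = False
        adj_a, adj_b = fadj[:, 0], fadj[:, 1]
        for a, b in ((adj_a, adj_b), (adj_b, adj_a)):
            take = orphan[a] & ~orphan[b]
            if take.any():
                # last write wins within one pass; deterministic given fixed order
                labels[a[take]] = labels[b[take]]
                orphan[a[take]] = False
                changed = True
        if not changed:
            raise RuntimeError("disconnected orphan faces cannot be reattached")
    return labels


def parcellate_surface(mesh: SurfaceMesh, K: int, rng_seed: int = 0) -> Parcellation:
    """Partition a manifold mesh into K connected cortical units.

    Deterministic given ``rng_seed``; patch areas are near-equal on regular
    meshes (farthest-point sampling spreads seeds approximately uniformly).
    """
    if K < 1:
        raise ValueError("K must be >= 1")
    if K > mesh.n_faces:
        raise ValueError(f"K = {K} exceeds the face count {mesh.n_faces}")
    if K == 1:
        labels = np.zeros(mesh.n_faces, dtype=int)
    else:
        seeds = _farthest_point_seeds(mesh.vertex_graph, K, rng_seed)
        labels = _balanced_face_growth(mesh, seeds)
        # Lloyd-style refinement (reseed at patch medoids, regrow), then a
        # boundary-rebalancing pass that equalizes areas without breaking
        # connectivity
        for _ in range(3):
            seeds = _patch_medoids(mesh, labels, K)
            labels = _balanced_face_growth(mesh, seeds)
        labels = _balance_patches(mesh, labels, K)
        labels = _repair_connectivity(mesh, labels)
        present = np.unique(labels)
        if len(present) != K:
            raise RuntimeError(f"parcellation produced {len(present)} non-empty units, expected {K}")
    units = []
    for lab in range(int(labels.max()) + 1):
        fids = np.flatnonzero(labels == lab)
        vids = np.unique(mesh.faces[fids])
        units.append(
            CorticalUnit(
                id=lab, vertex_ids=vids, face_ids=fids, area=float(mesh.face_areas[fids].sum())
            )
        )
    return Parcellation(mesh, units, labels)


# ---------------------------------------------------------------------------
# seed-layer extraction

def _box_corners(lo: np.ndarray, hi: np.ndarray) -> np.ndarray:
    """The 8 corners of an axis-aligned world box (robust to any affine)."""
    return np.array([[(lo, hi)[bool(b)][a] for a, b in enumerate(bits)] for bits in np.ndindex(2, 2, 2)])

def nearest_surface_points(
    mesh: SurfaceMesh, points: np.ndarray, k_candidates: int = 12
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per point: (distance, nearest face id, closest point on the surface).

    Candidate faces come from the ``k_candidates`` nearest face centroids
    (KD-tree); the exact point-triangle distance is evaluated on candidates
    only.  Exact for points much closer to the surface than the centroid
    spacing, which holds for seed-layer voxels.
    """
    points = np.asarray(points, dtype=float).reshape(-1, 3)
    tree_key = ("face_centroid_tree",)
    if tree_key not in mesh._cache:
        mesh._cache[tree_key] = cKDTree(mesh.face_centroids)
    tree = mesh._cache[tree_key]
    k = min(k_candidates, mesh.n_faces)
    _, cand = tree.query(points, k=k)
    cand = np.atleast_2d(cand)
    n = len(points)
    tris = mesh.trimesh().triangles[cand.ravel()]
    rep = np.repeat(points, k, axis=0)
    cp = _triangle_closest_point(tris, rep).reshape(n, k, 3)
    d = np.linalg.norm(cp - points[:, None, :], axis=2)
    best = np.argmin(d, axis=1)
    rows = np.arange(n)
    return d[rows, best], cand[rows, best], cp[rows, best]


def seed_layer_for_faces(
    mesh: SurfaceMesh,
    face_ids: np.ndarray,
    vol: TensorVolume,
    thickness: float,
    owned_by_faces: np.ndarray | None = None,
) -> np.ndarray:
    """Voxel indices of the subcortical layer beneath a set of faces.

    A voxel belongs to the layer when its center's nearest surface point (on
    the *whole* mesh) lies on one of ``face_ids``, its distance is <=
    ``thickness`` and it sits on the inward side (against the outward face
    normal).  ``owned_by_faces`` optionally restricts which whole-mesh faces
    count as "these" faces (used by the per-CU masks).
    """
    face_ids = np.asarray(face_ids, dtype=int)
    if thickness <= 0 or len(face_ids) == 0:
        return np.empty((0, 3), dtype=int)
    verts = mesh.vertices[np.unique(mesh.faces[face_ids])]
    margin = thickness + float(mesh.edge_lengths.max())
    # candidate voxels: centers within `margin` of any patch vertex
    corners = np.array(
        [vol.world_to_voxel(c) for c in _box_corners(verts.min(axis=0) - margin, verts.max(axis=0) + margin)]
    )
    lo = np.maximum(np.floor(corners.min(axis=0)).astype(int), 0)
    hi = np.minimum(np.ceil(corners.max(axis=0)).astype(int) + 1, np.asarray(vol.shape))
    ranges = [np.arange(lo[a], hi[a]) for a in range(3)]
    if any(len(r) == 0 for r in ranges):
        return np.empty((0, 3), dtype=int)
    ijk = np.stack(np.meshgrid(*ranges, indexing="ij"), axis=-1).reshape(-1, 3)
    centers = vol.voxel_to_world(ijk)
    vtree = cKDTree(verts)
    near = vtree.query_ball_point(centers, margin, return_length=True) > 0
    ijk, centers = ijk[near], centers[near]
    if len(ijk) == 0:
        return np.empty((0, 3), dtype=int)
    dist, nearest_face, cp = nearest_surface_points(mesh, centers)
    inward = np.einsum("ij,ij->i", centers - cp, mesh.face_normals[nearest_face]) < 0
    in_set = np.isin(nearest_face, face_ids)
    keep = (dist <= thickness) & inward & in_set
    return ijk[keep]


def extract_seed_layer(
    cu: CorticalUnit, mesh: SurfaceMesh, vol: TensorVolume, thickness: float
) -> np.ndarray:
    """Seed-voxel mask of one CU (voxels contested between CUs go to the CU
    with the nearest surface point, so per-CU masks are disjoint)."""
    voxels = seed_layer_for_faces(mesh, cu.face_ids, vol, thickness)
    if len(voxels) == 0:
        warnings.warn(f"CU {cu.id} has an empty seed layer; FiCD undefined", stacklevel=2)
    cu.seed_voxels = voxels
    cu.seed_volume = len(voxels) * vol.voxel_volume
    return voxels


def assign_seed_layers(parc: Parcellation, vol: TensorVolume, thickness: float) -> None:
    """Compute every CU's seed mask in one pass over near-surface voxels."""
    mesh = parc.mesh
    all_vox = seed_layer_for_faces(mesh, np.arange(mesh.n_faces), vol, thickness)
    if len(all_vox) == 0:
        for cu in parc:
            cu.seed_voxels = np.empty((0, 3), dtype=int)
            cu.seed_volume = 0.0
        return
    centers = vol.voxel_to_world(all_vox)
    _, nearest_face, _ = nearest_surface_points(mesh, centers)
    vox_label = parc.face_labels[nearest_face]
    for cu in parc:
        cu.seed_voxels = all_vox[vox_label == cu.id]
        cu.seed_volume = len(cu.seed_voxels) * vol.voxel_volume
        if cu.seed_volume == 0.0:
            warnings.warn(f"CU {cu.id} has an empty seed layer; FiCD undefined", stacklevel=2)
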