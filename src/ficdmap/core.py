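"""In-memory containers shared across the pipeline.

All world coordinates are millimetres.  Voxel indexing is 0-based and a
voxel's world position is the position of its *center*: world = A[:3,:3] @
(i,j,k) + A[:3,3] for the volume affine ``A``.  Diffusion tensors are stored
as their six unique components in the order (Dxx, Dyy, Dzz, Dxy, Dxz, Dyz).
"""

from __future__ import annotations

import dataclasses
import numpy as np
import pandas as pd
import scipy.sparse as sp
import trimesh

#: index pairs mapping the 6-component storage order onto a symmetric 3x3
TENSOR_COMPONENTS = ((0, 0), (1, 1), (2, 2), (0, 1), (0, 2), (1, 2))


def tensors_to_matrices(components: np.ndarray) -> np.ndarray:
    """Expand (..., 6) unique components into (..., 3, 3) symmetric matrices."""
    components = np.asarray(components)
    out = np.zeros(components.shape[:-1] + (3, 3), dtype=components.dtype)
    for c, (i, j) in enumerate(TENSOR_COMPONENTS):
        out[..., i, j] = components[..., c]
        out[..., j, i] = components[..., c]
    return out


def matrices_to_tensors(matrices: np.ndarray) -> np.ndarray:
    """Collapse (..., 3, 3) symmetric matrices into (..., 6) unique components."""
    matrices = np.asarray(matrices)
    out = np.empty(matrices.shape[:-2] + (6,), dtype=matrices.dtype)
    for c, (i, j) in enumerate(TENSOR_COMPONENTS):
        out[..., c] = matrices[..., i, j]
    return out


def fa_from_eigenvalues(evals: np.ndarray) -> np.ndarray:
    """Fractional anisotropy from (..., 3) eigenvalues.

    FA = sqrt(3/2) * ||lambda - mean(lambda)|| / ||lambda||, clipped to [0, 1];
    an all-zero tensor has FA 0 by convention.
    """
    evals = np.asarray(evals, dtype=float)
    mean = evals.mean(axis=-1, keepdims=True)
    num = np.linalg.norm(evals - mean, axis=-1)
    den = np.linalg.norm(evals, axis=-1)
    with np.errstate(invalid="ignore", divide="ignore"):
        fa = np.sqrt(1.5) * num / den
    return np.clip(np.where(den > 0, fa, 0.0), 0.0, 1.0)


class TensorVolume:
    """A gridded diffusion-tensor field with a voxel-to-world affine.

    Parameters
    ----------
    tensors:
        Array of shape (nx, ny, nz, 6) holding the unique tensor components
        in :data:`TENSOR_COMPONENTS` order.
    affine:
        4x4 voxel-index -> world-mm transform (voxel centers).
    provenance:
        Free-form dict recorded by generators (e.g. overlap diagnostics).
    """

    def __init__(self, tensors: np.ndarray, affine: np.ndarray, provenance: dict | None = None):
        tensors = np.asarray(tensors, dtype=np.float64)
        if tensors.ndim != 4 or tensors.shape[-1] != 6:
            raise ValueError(
                f"tensor grid must have shape (nx, ny, nz, 6); last axis has size "
                f"{tensors.shape[-1] if tensors.ndim == 4 else 'n/a'}"
            )
        affine = np.asarray(affine, dtype=np.float64)
        if affine.shape != (4, 4):
            raise ValueError("affine must be 4x4")
        if abs(np.linalg.det(affine[:3, :3])) < 1e-12:
            raise ValueError("affine is not invertible")
        self.tensors = tensors
        self.affine = affine
        self.provenance = dict(provenance or {})
        self._inv = np.linalg.inv(affine)
        self._fa: np.ndarray | None = None
        self._dirs: np.ndarray | None = None

    # -- geometry ---------------------------------------------------------
    @property
    def shape(self) -> tuple[int, int, int]:
        return self.tensors.shape[:3]

    @property
    def voxel_size(self) -> np.ndarray:
        return np.linalg.norm(self.affine[:3, :3], axis=0)

    @property
    def voxel_volume(self) -> float:
        return float(abs(np.linalg.det(self.affine[:3, :3])))

    def voxel_to_world(self, ijk: np.ndarray) -> np.ndarray:
        ijk = np.asarray(ijk, dtype=float)
        return ijk @ self.affine[:3, :3].T + self.affine[:3, 3]

    def world_to_voxel(self, xyz: np.ndarray) -> np.ndarray:
        xyz = np.asarray(xyz, dtype=float)
        return xyz @ self._inv[:3, :3].T + self._inv[:3, 3]

    def voxel_centers(self) -> np.ndarray:
        """World coordinates of every voxel center, shape (*shape, 3)."""
        grid = np.stack(
            np.meshgrid(*[np.arange(n) for n in self.shape], indexing="ij"), axis=-1
        )
        return self.voxel_to_world(grid.reshape(-1, 3)).reshape(self.shape + (3,))

    def in_bounds(self, xyz: np.ndarray) -> np.ndarray:
        """True where a world point lies inside the grid of voxel centers."""
        v = self.world_to_voxel(xyz)
        hi = np.asarray(self.shape) - 1
        return np.all((v >= 0) & (v <= hi), axis=-1)

    # -- derived fields ---------------------------------------------------
    def _decompose(self) -> None:
        mats = tensors_to_matrices(self.tensors)
        evals, evecs = np.linalg.eigh(mats)
        self._fa = fa_from_eigenvalues(evals)
        self._dirs = evecs[..., -1]  # eigenvector of the largest eigenvalue

    @property
    def fa(self) -> np.ndarray:
        if self._fa is None:
            self._decompose()
        return self._fa

    @property
    def principal_directions(self) -> np.ndarray:
        """Unit principal eigenvectors, shape (*shape, 3); sign is arbitrary."""
        if self._dirs is None:
            self._decompose()
        return self._dirs


class SurfaceMesh:
    """A triangulated GM-WM interface with per-vertex scalar maps.

    Thin wrapper over :class:`trimesh.Trimesh` (``process=False``: vertex
    order and indices are preserved exactly) adding vertex areas, adjacency
    structures and named per-vertex maps.
    """

    def __init__(
        self,
        vertices: np.ndarray,
        faces: np.ndarray,
        maps: dict[str, np.ndarray] | None = None,
    ):
        vertices = np.asarray(vertices, dtype=np.float64)
        faces = np.asarray(faces, dtype=np.int64)
        if vertices.ndim != 2 or vertices.shape[1] != 3:
            raise ValueError("vertices must be (V, 3)")
        if faces.ndim != 2 or faces.shape[1] != 3:
            raise ValueError("faces must be (F, 3)")
        if faces.size and (faces.min() < 0 or faces.max() >= len(vertices)):
            raise ValueError("faces index out of range")
        self._tm = trimesh.Trimesh(vertices=vertices, faces=faces, process=False)
        self.maps: dict[str, np.ndarray] = {}
        for name, values in (maps or {}).items():
            self.set_map(name, values)
        self._cache: dict = {}

    # -- basic accessors ---------------------------------------------------
    @property
    def vertices(self) -> np.ndarray:
        return np.asarray(self._tm.vertices)

    @property
    def faces(self) -> np.ndarray:
        return np.asarray(self._tm.faces)

    @property
    def n_vertices(self) -> int:
        return len(self._tm.vertices)

    @property
    def n_faces(self) -> int:
        return len(self._tm.faces)

    def set_map(self, name: str, values: np.ndarray) -> None:
        values = np.asarray(values, dtype=np.float64)
        if values.shape != (self.n_vertices,):
            raise ValueError(
                f"map {name!r} has length {values.shape}, expected ({self.n_vertices},)"
            )
        self.maps[name] = values

    # -- geometry ----------------------------------------------------------
    @property
    def face_areas(self) -> np.ndarray:
        return np.asarray(self._tm.area_faces)

    @property
    def area(self) -> float:
        return float(self._tm.area)

    @property
    def vertex_areas(self) -> np.ndarray:
        """One third of the summed incident triangle areas (sums to total area)."""
        if "vertex_areas" not in self._cache:
            va = np.zeros(self.n_vertices)
            np.add.at(va, self.faces.ravel(), np.repeat(self.face_areas / 3.0, 3))
            self._cache["vertex_areas"] = va
        return self._cache["vertex_areas"]

    @property
    def face_normals(self) -> np.ndarray:
        return np.asarray(self._tm.face_normals)

    @property
    def vertex_normals(self) -> np.ndarray:
        return np.asarray(self._tm.vertex_normals)

    @property
    def face_centroids(self) -> np.ndarray:
        return np.asarray(self._tm.triangles_center)

    @property
    def edges(self) -> np.ndarray:
        """Unique undirected edges as an (E, 2) vertex-id array."""
        return np.asarray(self._tm.edges_unique)

    @property
    def edge_lengths(self) -> np.ndarray:
        return np.asarray(self._tm.edges_unique_length)

    @property
    def euler_number(self) -> int:
        return int(self._tm.euler_number)

    @property
    def is_closed(self) -> bool:
        return bool(self._tm.is_watertight)

    @property
    def is_manifold(self) -> bool:
        """Every edge shared by exactly two faces."""
        edges = self._tm.edges_sorted
        _, counts = np.unique(edges, axis=0, return_counts=True)
        return bool(np.all(counts == 2))

    # -- adjacency ---------------------------------------------------------
    @property
    def vertex_adjacency(self) -> sp.csr_matrix:
        """Unweighted symmetric vertex adjacency (CSR)."""
        if "vadj" not in self._cache:
            e = self.edges
            data = np.ones(len(e) * 2)
            rows = np.concatenate([e[:, 0], e[:, 1]])
            cols = np.concatenate([e[:, 1], e[:, 0]])
            self._cache["vadj"] = sp.csr_matrix(
                (data, (rows, cols)), shape=(self.n_vertices, self.n_vertices)
            )
        return self._cache["vadj"]

    @property
    def vertex_graph(self) -> sp.csr_matrix:
        """Vertex adjacency weighted by Euclidean edge length (geodesic graph)."""
        if "vgraph" not in self._cache:
            e, w = self.edges, self.edge_lengths
            rows = np.concatenate([e[:, 0], e[:, 1]])
            cols = np.concatenate([e[:, 1], e[:, 0]])
            self._cache["vgraph"] = sp.csr_matrix(
                (np.concatenate([w, w]), (rows, cols)),
                shape=(self.n_vertices, self.n_vertices),
            )
        return self._cache["vgraph"]

    @property
    def face_adjacency(self) -> np.ndarray:
        """(N, 2) pairs of face ids sharing an edge."""
        return np.asarray(self._tm.face_adjacency)

    def trimesh(self) -> trimesh.Trimesh:
        return self._tm


@dataclasses.dataclass
class Streamline:
    """An ordered polyline in world mm with its summary statistics."""

    points: np.ndarray
    mean_fa: float = np.nan
    seed_cu: int | None = None

    def __post_init__(self):
        self.points = np.asarray(self.points, dtype=np.float64)
        if self.points.ndim != 2 or self.points.shape[1] != 3 or len(self.points) < 2:
            raise ValueError("a streamline needs >= 2 points of shape (N, 3)")

    @property
    def length(self) -> float:
        return float(np.linalg.norm(np.diff(self.points, axis=0), axis=1).sum())


@dataclasses.dataclass
class Tractogram:
    """A bag of streamlines plus the tracking parameters that produced them."""

    streamlines: list[Streamline]
    params: object | None = None

    def __len__(self) -> int:
        return len(self.streamlines)

    def __iter__(self):
        return iter(self.streamlines)

    @property
    def mean_fas(self) -> np.ndarray:
        return np.array([s.mean_fa for s in self.streamlines])

    @property
    def lengths(self) -> np.ndarray:
        return np.array([s.length for s in self.streamlines])


class CohortTable:
    """Per-subject surface maps and covariates on a shared mesh.

    ``table`` columns: subject, group, total_brain_volume, severity.
    ``ficd_maps`` / ``gm_maps``: (n_subjects, n_vertices) arrays aligned with
    ``table`` rows.  Inter-subject vertex correspondence is by shared mesh
    topology.
    """

    def __init__(
        self,
        table: pd.DataFrame,
        ficd_maps: np.ndarray,
        gm_maps: np.ndarray | None = None,
        mesh: SurfaceMesh | None = None,
    ):
        required = {"subject", "group", "total_brain_volume", "severity"}
        missing = required - set(table.columns)
        if missing:
            raise ValueError(f"cohort table missing columns: {sorted(missing)}")
        if table["group"].isna().any():
            bad = table.index[table["group"].isna()].tolist()
            raise ValueError(f"cohort table has missing group labels at rows {bad}")
        ficd_maps = np.asarray(ficd_maps, dtype=np.float64)
        if ficd_maps.shape[0] != len(table):
            raise ValueError("ficd_maps rows must match cohort table rows")
        if mesh is not None and ficd_maps.shape[1] != mesh.n_vertices:
            raise ValueError("map length must equal mesh vertex count")
        self.table = table.reset_index(drop=True)
        self.ficd_maps = ficd_maps
        self.gm_maps = None if gm_maps is None else np.asarray(gm_maps, dtype=np.float64)
        self.mesh = mesh

    def __len__(self) -> int:
        return len(self.table)

    @property
    def n_vertices(self) -> int:
        return self.ficd_maps.shape[1]

    @property
    def group_levels(self) -> list:
        """Group labels in order of first appearance (the first level is the
        "group A" of every contrast: positive t means A > B)."""
        return self.table["group"].drop_duplicates().tolist()

    def group_mask(self, level) -> np.ndarray:
        return (self.table["group"] == level).to_numpy()

    def with_maps(self, ficd_maps: np.ndarray) -> "CohortTable":
        """A copy of this cohort with replaced FiCD maps (covariates shared)."""
        return CohortTable(self.table.copy(), ficd_maps, self.gm_maps, self.mesh)
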