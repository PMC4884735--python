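"""Synthetic tensor-field, cortical-mesh and cohort generators.

Every downstream stage (parcellation, tractography, FiCD mapping, group
statistics) is exercised on phantoms with known ground truth: tensor volumes
containing straight/curved/crossing fiber bundles of prescribed FA, closed
star-shaped cortical meshes, and two-group cohorts carrying a localized,
configurable FiCD effect.  All generators are pure functions of their spec
including its ``rng_seed``.

Bundles have hard cylindrical cross-sections (a voxel is inside iff its
center lies within ``radius`` of the centerline, no partial-volume
blending), which keeps analytic expectations exact.  Eigenvector sign is
arbitrary throughout (+v and -v describe the same tensor).
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
import pandas as pd
import trimesh
from scipy.interpolate import make_interp_spline
from scipy.optimize import brentq
from scipy.sparse.csgraph import breadth_first_order

from .core import CohortTable, SurfaceMesh, TensorVolume, matrices_to_tensors

#: mean diffusivity of every phantom tensor, mm^2/s (typical brain tissue)
MEAN_DIFFUSIVITY = 0.7e-3


@dataclasses.dataclass
class Bundle:
    """One fiber bundle: a centerline polyline (mm) with a hard tube radius."""

    centerline: np.ndarray
    radius: float
    fa: float

    def __post_init__(self):
        self.centerline = np.asarray(self.centerline, dtype=float)
        if self.centerline.ndim != 2 or self.centerline.shape[1] != 3 or len(self.centerline) < 2:
            raise ValueError("centerline must be (N>=2, 3) control points in mm")
        if self.radius <= 0:
            raise ValueError("bundle radius must be > 0")
        if not 0.0 <= self.fa <= 1.0:
            raise ValueError("bundle FA must be in [0, 1]")


@dataclasses.dataclass
class PhantomSpec:
    """Geometry and contrast of one synthetic subject.

    The volume grid is centered on the world origin; the mesh (when
    requested) must fit inside the grid.
    """

    grid_shape: tuple[int, int, int] = (60, 60, 60)
    voxel_size: tuple[float, float, float] = (1.0, 1.0, 1.0)
    bundles: Sequence[Bundle] = ()
    fa_background: float = 0.05
    mesh_kind: str = "sphere"
    mesh_radius: float = 20.0
    mesh_amplitude: float = 2.0
    mesh_subdivisions: int = 3
    rng_seed: int = 0

    def __post_init__(self):
        self.grid_shape = tuple(int(n) for n in self.grid_shape)
        if np.isscalar(self.voxel_size):
            self.voxel_size = (float(self.voxel_size),) * 3
        self.voxel_size = tuple(float(v) for v in self.voxel_size)
        if any(n < 2 for n in self.grid_shape) or any(v <= 0 for v in self.voxel_size):
            raise ValueError("grid_shape must be >= 2 and voxel_size > 0 per axis")
        if not 0.0 <= self.fa_background <= 1.0:
            raise ValueError("background FA must be in [0, 1]")
        if self.mesh_kind not in ("sphere", "folded"):
            raise ValueError(f"unsupported mesh_kind {self.mesh_kind!r}")
        if self.mesh_radius <= 0:
            raise ValueError("mesh_radius must be > 0")
        extent = (np.array(self.grid_shape) - 1) * np.array(self.voxel_size) / 2.0
        reach = self.mesh_radius + (self.mesh_amplitude if self.mesh_kind == "folded" else 0.0)
        if np.any(reach > extent):
            raise ValueError("grid does not contain the mesh bounding box")

    @property
    def affine(self) -> np.ndarray:
        """Voxel-center affine placing the grid center at the world origin."""
        a = np.eye(4)
        a[:3, :3] = np.diag(self.voxel_size)
        a[:3, 3] = -(np.array(self.grid_shape) - 1) * np.array(self.voxel_size) / 2.0
        return a


@dataclasses.dataclass
class CohortSpec:
    """A two-group synthetic cohort with a cluster-localized FiCD effect.

    Defaults mirror a small two-group imaging study (20 affected vs. 18
    control subjects).  ``effect_size`` is an additive shift, in FiCD units,
    applied to ``effect_vertices`` of every group-A ("patient") subject.
    Severity is coupled to each subject's realized effect so correlation
    analyses have a known sign: severity = baseline + coupling * (realized
    mean shift at the effect vertices) + noise.
    """

    n_group_a: int = 20
    n_group_b: int = 18
    effect_vertices: np.ndarray = dataclasses.field(default_factory=lambda: np.array([], dtype=int))
    effect_size: float = 0.0
    between_subject_sd: float = 0.1
    base_level: float = 1.0
    base_pattern_amplitude: float = 0.6
    severity_baseline: float = 13.0
    severity_coupling: float = 0.0
    severity_noise_sd: float = 8.0
    gm_thickness_mm: float = 2.5
    gm_noise_frac: float = 0.1
    brain_volume_mm3: float = 1.2e6
    brain_volume_sd: float = 6.0e4
    group_labels: tuple[str, str] = ("patient", "control")
    rng_seed: int = 0

    def __post_init__(self):
        self.effect_vertices = np.asarray(self.effect_vertices, dtype=int)
        if self.n_group_a < 2 or self.n_group_b < 2:
            raise ValueError("each group needs at least 2 subjects")
        if self.effect_size != 0.0 and self.effect_vertices.size == 0:
            raise ValueError("nonzero effect_size requires effect_vertices")
        if self.between_subject_sd < 0:
            raise ValueError("between_subject_sd must be >= 0")


# ---------------------------------------------------------------------------
# tensor construction helpers

def _eigenvalue_ratio_for_fa(fa: float) -> float:
    """lambda_perp / lambda_parallel of an axially symmetric tensor with the
    requested FA: FA = (1 - r) / sqrt(1 + 2 r^2), solved for r in (0, 1]."""
    if fa <= 0:
        return 1.0
    if fa >= 1:
        return 0.0
    return brentq(lambda r: (1 - r) / np.sqrt(1 + 2 * r**2) - fa, 0.0, 1.0, xtol=1e-14)


def axially_symmetric_tensor(direction: np.ndarray, fa: float, md: float = MEAN_DIFFUSIVITY) -> np.ndarray:
    """A symmetric 3x3 tensor with principal axis ``direction``, the given FA
    and mean diffusivity ``md``."""
    d = np.asarray(direction, dtype=float)
    d = d / np.linalg.norm(d)
    r = _eigenvalue_ratio_for_fa(fa)
    lam1 = 3.0 * md / (1.0 + 2.0 * r)
    lam2 = r * lam1
    return lam2 * np.eye(3) + (lam1 - lam2) * np.outer(d, d)


def resample_centerline(points: np.ndarray, step_mm: float = 0.5) -> np.ndarray:
    """Resample a control polyline with a cubic spline at roughly ``step_mm``
    arc-length spacing (helper for building smooth curved bundles)."""
    points = np.asarray(points, dtype=float)
    seg = np.linalg.norm(np.diff(points, axis=0), axis=1)
    t = np.concatenate([[0.0], np.cumsum(seg)])
    k = min(3, len(points) - 1)
    spline = make_interp_spline(t, points, k=k)
    n = max(int(np.ceil(t[-1] / step_mm)) + 1, 2)
    return spline(np.linspace(0.0, t[-1], n))


def arc_centerline(radius: float, angle_deg: float, center=(0.0, 0.0, 0.0), n: int = 181) -> np.ndarray:
    """A circular arc in the xy-plane starting at +x, for curved phantoms."""
    theta = np.deg2rad(np.linspace(0.0, angle_deg, n))
    c = np.asarray(center, dtype=float)
    return c + radius * np.stack([np.cos(theta), np.sin(theta), np.zeros_like(theta)], axis=1)


def _segment_distances(points: np.ndarray, centerline: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Exact distance from each point to a polyline and the unit tangent of
    the nearest segment.  Vectorized over points, looped over segments."""
    a = centerline[:-1]
    b = centerline[1:]
    ab = b - a
    seg_len = np.linalg.norm(ab, axis=1)
    keep = seg_len > 0
    a, ab, seg_len = a[keep], ab[keep], seg_len[keep]
    tangents = ab / seg_len[:, None]
    best = np.full(len(points), np.inf)
    best_seg = np.zeros(len(points), dtype=int)
    for s in range(len(a)):
        ap = points - a[s]
        t = np.clip(ap @ ab[s] / seg_len[s] ** 2, 0.0, 1.0)
        d = np.linalg.norm(ap - t[:, None] * ab[s], axis=1)
        closer = d < best
        best[closer] = d[closer]
        best_seg[closer] = s
    return best, tangents[best_seg]


# ---------------------------------------------------------------------------
# generators

def make_tensor_phantom(spec: PhantomSpec) -> TensorVolume:
    """Build a tensor volume from the spec's bundles over a low-FA background.

    Inside each bundle tube the principal eigenvector is tangent to the
    centerline with the bundle's FA; elsewhere the field is a weakly
    anisotropic background (axis +z, FA = ``fa_background``).  Overlapping
    bundles with conflicting directions resolve last-writer-wins; the
    affected voxel count is recorded in ``provenance['overlap_voxels']``.
    """
    affine = spec.affine
    shape = spec.grid_shape
    n_vox = int(np.prod(shape))
    background = axially_symmetric_tensor([0.0, 0.0, 1.0], spec.fa_background)
    tensors = np.tile(matrices_to_tensors(background), (n_vox, 1))

    ijk = np.stack(np.meshgrid(*[np.arange(n) for n in shape], indexing="ij"), axis=-1).reshape(-1, 3)
    centers = ijk @ affine[:3, :3].T + affine[:3, 3]

    owner = np.full(n_vox, -1, dtype=int)
    overlap = 0
    for b_idx, bundle in enumerate(spec.bundles):
        dist, tangent = _segment_distances(centers, bundle.centerline)
        inside = np.flatnonzero(dist <= bundle.radius)
        overlap += int(np.count_nonzero(owner[inside] >= 0))
        owner[inside] = b_idx
        r = _eigenvalue_ratio_for_fa(bundle.fa)
        lam1 = 3.0 * MEAN_DIFFUSIVITY / (1.0 + 2.0 * r)
        lam2 = r * lam1
        t_in = tangent[inside]
        mats = lam2 * np.eye(3)[None] + (lam1 - lam2) * np.einsum("ni,nj->nij", t_in, t_in)
        tensors[inside] = matrices_to_tensors(mats)

    provenance = {
        "generator": "make_tensor_phantom",
        "rng_seed": spec.rng_seed,
        "overlap_voxels": overlap,
        "overlap_policy": "last-writer-wins",
    }
    return TensorVolume(tensors.reshape(shape + (6,)), affine, provenance=provenance)


def make_cortex_mesh(spec: PhantomSpec) -> SurfaceMesh:
    """Build a closed, manifold, outward-normal GM-WM interface mesh.

    ``sphere``: an icosphere of the requested radius (vertices exactly on the
    sphere).  ``folded``: the icosphere displaced radially by a smooth
    angular modulation of amplitude ``mesh_amplitude`` — star-shaped, so
    topology (genus 0) is preserved.
    """
    ico = trimesh.creation.icosphere(subdivisions=spec.mesh_subdivisions, radius=spec.mesh_radius)
    vertices = np.asarray(ico.vertices)
    if spec.mesh_kind == "folded":
        x, y, z = vertices.T
        r = np.linalg.norm(vertices, axis=1)
        theta = np.arccos(np.clip(z / r, -1.0, 1.0))
        phi = np.arctan2(y, x)
        bump = np.sin(4.0 * theta) * np.cos(4.0 * phi) + 0.5 * np.cos(3.0 * theta)
        scale = 1.0 + (spec.mesh_amplitude / spec.mesh_radius) * bump / 1.5
        vertices = vertices * scale[:, None]
    return SurfaceMesh(vertices, np.asarray(ico.faces))


def contiguous_patch(mesh: SurfaceMesh, center_vertex: int, n_vertices: int) -> np.ndarray:
    """The first ``n_vertices`` vertex ids reached by breadth-first search
    from ``center_vertex`` — a connected patch for effect injection."""
    order = breadth_first_order(mesh.vertex_adjacency, center_vertex, directed=False, return_predecessors=False)
    if len(order) < n_vertices:
        raise ValueError("patch larger than the mesh component")
    return np.sort(order[:n_vertices])


def base_ficd_pattern(mesh: SurfaceMesh, level: float, amplitude: float) -> np.ndarray:
    """A smooth deterministic base FiCD pattern (low-order angular harmonics
    of the vertex positions) shared by every subject of a cohort."""
    v = mesh.vertices
    scale = np.linalg.norm(v, axis=1).mean()
    u = v / scale
    return level + amplitude * (np.sin(2.0 * u[:, 0]) + 0.5 * np.cos(3.0 * u[:, 1]) + 0.3 * np.sin(2.0 * u[:, 2]))


def make_cohort(mesh: SurfaceMesh, spec: CohortSpec) -> CohortTable:
    """Generate a two-group cohort of vertex-wise FiCD and GM-volume maps.

    Subject maps = smooth base pattern + (group A only) ``effect_size`` on
    ``effect_vertices`` + i.i.d. N(0, between_subject_sd^2) vertex noise.
    GM-volume maps are vertex-area * cortical thickness with multiplicative
    noise; severity follows the linear coupling model in :class:`CohortSpec`.
    """
    if spec.effect_vertices.size and (
        spec.effect_vertices.min() < 0 or spec.effect_vertices.max() >= mesh.n_vertices
    ):
        raise ValueError("effect_vertices outside the mesh")
    rng = np.random.default_rng(spec.rng_seed)
    n = spec.n_group_a + spec.n_group_b
    V = mesh.n_vertices
    base = base_ficd_pattern(mesh, spec.base_level, spec.base_pattern_amplitude)

    maps = base[None, :] + spec.between_subject_sd * rng.standard_normal((n, V))
    group_a = np.arange(n) < spec.n_group_a
    if spec.effect_vertices.size:
        maps[np.ix_(group_a, spec.effect_vertices)] += spec.effect_size

    if spec.effect_vertices.size:
        realized = maps[:, spec.effect_vertices].mean(axis=1) - base[spec.effect_vertices].mean()
    else:
        realized = np.zeros(n)
    severity = (
        spec.severity_baseline
        + spec.severity_coupling * realized
        + spec.severity_noise_sd * rng.standard_normal(n)
    )

    gm_base = mesh.vertex_areas * spec.gm_thickness_mm
    gm_maps = gm_base[None, :] * (1.0 + spec.gm_noise_frac * rng.standard_normal((n, V)))
    tbv = spec.brain_volume_mm3 + spec.brain_volume_sd * rng.standard_normal(n)

    label_a, label_b = spec.group_labels
    table = pd.DataFrame(
        {
            "subject": [f"sub-{i:03d}" for i in range(n)],
            "group": np.where(group_a, label_a, label_b),
            "total_brain_volume": tbv,
            "severity": severity,
        }
    )
    return CohortTable(table, maps, gm_maps=gm_maps, mesh=mesh)
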