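"""Deterministic streamline tractography on a tensor field.

The tracker integrates the principal-eigenvector field bidirectionally from
each seed with fixed-step Euler updates.  At every step the tensor is
trilinearly interpolated (component-wise) at the current point and
eigen-decomposed; the field direction is sign-aligned with the direction of
travel (tensors are +/- symmetric).  A branch terminates when interpolated
FA drops below ``fa_threshold``, when the raw field direction turns by more
than ``turning_angle_deg`` relative to the previous step, or when the point
leaves the grid of voxel centers.  The advanced direction blends the field
direction with momentum: d_new = normalize((1 - s) * v_field + s * d_prev)
with s = ``smoothing``, the standard convention for a scalar smoothing
parameter in deterministic trackers.

Defaults follow common deterministic-DTI practice for this kind of
GM-WM-seeded mapping: FA threshold 0.14, turning angle 45 deg, step 0.5 mm,
smoothing 0.5, one seed per voxel (placed at the voxel center for
determinism), and a 30-300 mm fiber length filter (closed interval).
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .core import Streamline, TensorVolume, Tractogram, fa_from_eigenvalues, tensors_to_matrices

#: sentinel returned by sample_field outside the grid
OUT_OF_BOUNDS = (np.nan, None)


@dataclasses.dataclass
class TrackingParams:
    """Streamline-integration and filtering parameters."""

    fa_threshold: float = 0.14
    turning_angle_deg: float = 45.0
    step_mm: float = 0.5
    smoothing: float = 0.5
    seeds_per_voxel: int = 1
    min_len_mm: float = 30.0
    max_len_mm: float = 300.0
    rng_seed: int = 0

    def __post_init__(self):
        if not 0.0 <= self.fa_threshold <= 1.0:
            raise ValueError("fa_threshold must be in [0, 1]")
        if not 0.0 < self.turning_angle_deg <= 90.0:
            raise ValueError("turning_angle_deg must be in (0, 90]")
        if self.step_mm <= 0:
            raise ValueError("step_mm must be > 0")
        if not 0.0 <= self.smoothing < 1.0:
            raise ValueError("smoothing must be in [0, 1)")
        if self.seeds_per_voxel < 1:
            raise ValueError("seeds_per_voxel must be >= 1")
        if self.min_len_mm > self.max_len_mm:
            raise ValueError("min_len_mm must be <= max_len_mm")

    @property
    def cos_angle(self) -> float:
        return float(np.cos(np.deg2rad(self.turning_angle_deg)))


def _interpolate_tensor(vol: TensorVolume, voxel_coords: np.ndarray) -> np.ndarray:
    """Trilinear interpolation of the 6 tensor components at fractional
    voxel coordinates (caller guarantees in-bounds)."""
    f = np.floor(voxel_coords).astype(int)
    hi = np.asarray(vol.shape) - 1
    f = np.minimum(f, hi - 1)  # keep the 2x2x2 block inside the grid
    f = np.maximum(f, 0)
    w = voxel_coords - f
    out = np.zeros(6)
    for dx in (0, 1):
        wx = w[0] if dx else 1.0 - w[0]
        if wx == 0.0:
            continue
        for dy in (0, 1):
            wy = w[1] if dy else 1.0 - w[1]
            if wy == 0.0:
                continue
            for dz in (0, 1):
                wz = w[2] if dz else 1.0 - w[2]
                if wz == 0.0:
                    continue
                out += wx * wy * wz * vol.tensors[f[0] + dx, f[1] + dy, f[2] + dz]
    return out


def sample_field(
    vol: TensorVolume, point: np.ndarray, reference_direction: np.ndarray | None = None
) -> tuple[float, np.ndarray | None]:
    """FA and principal direction of the interpolated tensor at a world point.

    The principal eigenvector's sign is chosen to align with
    ``reference_direction`` when given.  Outside the grid of voxel centers
    returns ``(nan, None)``, which terminates tracks.
    """
    point = np.asarray(point, dtype=float)
    v = vol.world_to_voxel(point)
    hi = np.asarray(vol.shape) - 1
    if np.any(v < 0) or np.any(v > hi):
        return OUT_OF_BOUNDS
    tensor = _interpolate_tensor(vol, v)
    evals, evecs = np.linalg.eigh(tensors_to_matrices(tensor))
    fa = float(fa_from_eigenvalues(evals))
    direction = evecs[:, -1]
    if reference_direction is not None and float(direction @ reference_direction) < 0:
        direction = -direction
    return fa, direction


def _walk(
    vol: TensorVolume,
    start: np.ndarray,
    direction: np.ndarray,
    params: TrackingParams,
) -> tuple[list[np.ndarray], list[float]]:
    """Integrate one branch; returns points/FAs *after* the seed point."""
    points: list[np.ndarray] = []
    fas: list[float] = []
    p = np.asarray(start, dtype=float)
    d_prev = np.asarray(direction, dtype=float)
    s = params.smoothing
    max_steps = int(np.ceil(params.max_len_mm / params.step_mm))
    for _ in range(max_steps):
        p_next = p + params.step_mm * d_prev
        fa, v_field = sample_field(vol, p_next, reference_direction=d_prev)
        if v_field is None or fa < params.fa_threshold:
            break
        if float(v_field @ d_prev) < params.cos_angle:
            break
        d_new = (1.0 - s) * v_field + s * d_prev
        norm = np.linalg.norm(d_new)
        if norm == 0.0:
            break
        d_prev = d_new / norm
        p = p_next
        points.append(p.copy())
        fas.append(fa)
    return points, fas


def track_streamline(
    vol: TensorVolume, seed: np.ndarray, params: TrackingParams | None = None
) -> Streamline | None:
    """Track bidirectionally from one world-mm seed point.

    Returns ``None`` when the seed itself fails the FA threshold, lies
    outside the grid, or neither branch advances a single step.  The two
    branches (along +/- the seed's principal direction) are concatenated.
    """
    params = params or TrackingParams()
    seed = np.asarray(seed, dtype=float)
    fa0, v0 = sample_field(vol, seed)
    if v0 is None or fa0 < params.fa_threshold:
        return None
    fwd_pts, fwd_fas = _walk(vol, seed, v0, params)
    bwd_pts, bwd_fas = _walk(vol, seed, -v0, params)
    points = bwd_pts[::-1] + [seed] + fwd_pts
    fas = bwd_fas[::-1] + [fa0] + fwd_fas
    if len(points) < 2:
        return None
    return Streamline(points=np.asarray(points), mean_fa=float(np.mean(fas)))


def track_from_mask(
    vol: TensorVolume,
    mask: np.ndarray,
    params: TrackingParams | None = None,
    seed_cu: int | None = None,
) -> Tractogram:
    """Track from every voxel of a seed mask and length-filter the result.

    ``mask`` is an (N, 3) array of voxel indices.  Seeds are placed at voxel
    centers (``seeds_per_voxel = 1``); additional seeds per voxel, if
    requested, are uniform jitter within the voxel drawn from
    ``params.rng_seed``.  Streamlines with length outside
    [min_len_mm, max_len_mm] (closed interval, small numerical slack) are
    discarded.  An empty mask yields an empty tractogram.
    """
    params = params or TrackingParams()
    mask = np.asarray(mask, dtype=int).reshape(-1, 3)
    if len(mask):  # stable seed order regardless of mask construction
        order = np.lexsort((mask[:, 2], mask[:, 1], mask[:, 0]))
        mask = mask[order]
    seeds = [vol.voxel_to_world(mask)] if len(mask) else []
    if params.seeds_per_voxel > 1 and len(mask):
        rng = np.random.default_rng(params.rng_seed)
        for _ in range(params.seeds_per_voxel - 1):
            jitter = rng.uniform(-0.5, 0.5, size=(len(mask), 3))
            seeds.append(vol.voxel_to_world(mask + jitter))
    streamlines: list[Streamline] = []
    tol = 1e-9
    for seed_block in seeds:
        for seed in seed_block:
            s = track_streamline(vol, seed, params)
            if s is None:
                continue
            length = s.length
            if params.min_len_mm - tol <= length <= params.max_len_mm + tol:
                s.seed_cu = seed_cu
                streamlines.append(s)
    return Tractogram(streamlines=streamlines, params=params)


def check_streamline(streamline: Streamline, vol: TensorVolume, params: TrackingParams) -> bool:
    """Re-walk a polyline and verify its own invariants: consecutive-segment
    turning angle within threshold and FA at every point >= threshold."""
    pts = streamline.points
    dirs = np.diff(pts, axis=0)
    dirs = dirs / np.linalg.norm(dirs, axis=1, keepdims=True)
    cos = np.einsum("ij,ij->i", dirs[:-1], dirs[1:])
    if np.any(cos < params.cos_angle - 1e-9):
        return False
    for p in pts:
        fa, _ = sample_field(vol, p)
        if not np.isfinite(fa) or fa < params.fa_threshold - 1e-9:
            return False
    return True
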