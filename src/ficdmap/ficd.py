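"""The fiber connectivity density (FiCD) statistic and subject map assembly.

FiCD of a cortical unit = (sum over its seeded, length-filtered fibers of
each fiber's mean FA) / (the unit's seed-mask volume in mm^3).  Dividing by
seed volume corrects for inhomogeneity in CU size and makes the quantity a
density.  A fiber contributes only to the CU whose mask seeded it.  The
per-CU values are assigned back to the unit's vertices (piecewise-constant
projection; each vertex is owned by exactly one CU via face majority), the
vertex map is smoothed on the surface and finally Z-transformed per
hemisphere to stabilize its distribution before group statistics.
"""

from __future__ import annotations

import numpy as np

from .core import SurfaceMesh, TensorVolume, Tractogram
from .parcellation import Parcellation, assign_seed_layers
from .smoothing import smooth_surface_map
from .tractography import TrackingParams, track_from_mask


def compute_ficd(cu, tracks: Tractogram, per_point: bool = False) -> float:
    """FiCD value of one cortical unit from its seeded tractogram.

    ``per_point = True`` switches the numerator from the sum of per-fiber
    mean FAs (default) to the sum of FA over every tracked point of every
    fiber — an alternative reading of "summed fiber FA" kept as an option.
    """
    if not np.isfinite(cu.seed_volume) or cu.seed_volume <= 0:
        raise ValueError(f"CU {cu.id} has zero/undefined seed volume; FiCD undefined")
    if len(tracks) == 0:
        return 0.0
    if per_point:
        total = sum(s.mean_fa * len(s.points) for s in tracks)
    else:
        total = float(np.sum(tracks.mean_fas))
    return total / cu.seed_volume


def ficd_per_cu(
    parc: Parcellation,
    vol: TensorVolume,
    params: TrackingParams | None = None,
    thickness: float | None = None,
    keep_tracks: bool = False,
):
    """Track from every CU's seed mask and compute its FiCD.

    Returns ``(values, tractograms)``; ``values[i]`` is NaN for CUs with an
    empty seed mask (excluded from statistics downstream).  ``thickness``
    defaults to one voxel (the subcortical voxel layer).
    """
    params = params or TrackingParams()
    if parc.units and parc.units[0].seed_voxels is None:
        assign_seed_layers(parc, vol, thickness or float(np.min(vol.voxel_size)))
    values = np.full(parc.K, np.nan)
    tractograms: list[Tractogram | None] = []
    for cu in parc:
        if cu.n_seed_voxels == 0:
            tractograms.append(None)
            continue
        tracks = track_from_mask(vol, cu.seed_voxels, params, seed_cu=cu.id)
        values[cu.id] = compute_ficd(cu, tracks)
        tractograms.append(tracks if keep_tracks else None)
    return values, tractograms


def project_to_vertices(parc: Parcellation, values_per_cu: np.ndarray) -> np.ndarray:
    """Expand per-CU values into a per-vertex map (piecewise constant).

    Vertices on CU boundaries take the value of their owning CU (face
    majority, ties to the lower CU id).  CUs with missing (NaN) values
    propagate NaN, flagging those vertices undefined.
    """
    values_per_cu = np.asarray(values_per_cu, dtype=float)
    if values_per_cu.shape != (parc.K,):
        raise ValueError(f"expected one value per CU ({parc.K}), got {values_per_cu.shape}")
    return values_per_cu[parc.vertex_labels]


def z_transform_hemisphere(values: np.ndarray) -> np.ndarray:
    """Z-transform a hemisphere map: subtract the mean and divide by the
    sample SD (ddof=1) over defined (finite) vertices.

    Invariant to affine rescaling of the input; a constant map raises.
    """
    values = np.asarray(values, dtype=float)
    defined = np.isfinite(values)
    if defined.sum() < 2:
        raise ValueError("need at least 2 defined vertices")
    sd = float(np.std(values[defined], ddof=1))
    if sd == 0.0:
        raise ValueError("constant map: Z-transform undefined (SD = 0)")
    out = np.full_like(values, np.nan)
    out[defined] = (values[defined] - values[defined].mean()) / sd
    return out


def subject_ficd_map(
    parc: Parcellation,
    vol: TensorVolume,
    params: TrackingParams | None = None,
    fwhm_mm: float = 10.0,
    z_transform: bool = True,
    thickness: float | None = None,
) -> np.ndarray:
    """Full single-subject map: track -> FiCD per CU -> project -> smooth ->
    Z-transform (smoothing precedes the Z-transform in the pipeline order)."""
    values, _ = ficd_per_cu(parc, vol, params, thickness=thickness)
    vertex_map = project_to_vertices(parc, values)
    if fwhm_mm > 0 and np.all(np.isfinite(vertex_map)):
        vertex_map = smooth_surface_map(parc.mesh, vertex_map, fwhm_mm)
    if z_transform:
        vertex_map = z_transform_hemisphere(vertex_map)
    return vertex_map
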