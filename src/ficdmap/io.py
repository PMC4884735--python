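"""Readers and writers for the on-disk artifacts of the pipeline.

Formats: NIfTI-1 for tensor / scalar / vector volumes, GIFTI for surfaces
and per-vertex maps (written with 64-bit floats so round trips are lossless
at double precision), TRK for tractograms (world RAS mm), and TSV for the
cohort table.  All coordinates share one world frame in millimetres; voxel
(i, j, k) maps to the world position of its center through the NIfTI
affine.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import nibabel as nib
import nibabel.gifti as gifti
import nibabel.streamlines as nib_streamlines
import numpy as np
import pandas as pd

from .core import CohortTable, Streamline, SurfaceMesh, TensorVolume, Tractogram

__all__ = [
    "read_volume",
    "write_volume",
    "read_scalar_volume",
    "write_scalar_volume",
    "write_fa_volume",
    "write_direction_volume",
    "read_surface",
    "write_surface",
    "read_vertex_map",
    "write_vertex_map",
    "read_trk",
    "write_trk",
    "read_cohort_tsv",
    "write_cohort_tsv",
]


# ---------------------------------------------------------------------------
# NIfTI volumes

def write_volume(vol: TensorVolume, path: str | Path) -> None:
    """Write the 6-component tensor grid as a 4D float32 NIfTI-1 file."""
    img = nib.Nifti1Image(vol.tensors.astype(np.float32), vol.affine)
    img.to_filename(str(path))


def read_volume(path: str | Path) -> TensorVolume:
    """Read a 4D tensor NIfTI (last axis: the 6 unique components)."""
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim != 4:
        raise ValueError(f"expected 4 axes (3 spatial + components), file has {data.ndim}")
    if data.shape[3] != 6:
        raise ValueError(f"component axis (axis 3) has size {data.shape[3]}, expected 6")
    return TensorVolume(np.asarray(data, dtype=np.float64), np.asarray(img.affine))


def write_scalar_volume(data: np.ndarray, affine: np.ndarray, path: str | Path) -> None:
    nib.Nifti1Image(np.asarray(data, dtype=np.float32), affine).to_filename(str(path))


def read_scalar_volume(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise ValueError(f"expected a 3D scalar volume, file has {data.ndim} axes")
    return np.asarray(data, dtype=np.float64), np.asarray(img.affine)


def write_fa_volume(vol: TensorVolume, path: str | Path) -> None:
    write_scalar_volume(vol.fa, vol.affine, path)


def write_direction_volume(vol: TensorVolume, path: str | Path) -> None:
    """Principal eigenvectors as a 4D (x, y, z, 3) NIfTI (sign arbitrary)."""
    nib.Nifti1Image(vol.principal_directions.astype(np.float32), vol.affine).to_filename(str(path))


# ---------------------------------------------------------------------------
# GIFTI surfaces and per-vertex maps

def _write_gifti(darrays: list, path: str | Path) -> None:
    img = gifti.GiftiImage(darrays=darrays)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # float64 is outside the base GIFTI set
        img.to_filename(str(path), mode="force")


def write_surface(mesh: SurfaceMesh, path: str | Path) -> None:
    """Write vertices (float64) and faces (int32) as a GIFTI surface."""
    pts = gifti.GiftiDataArray(
        mesh.vertices, intent="NIFTI_INTENT_POINTSET", datatype="NIFTI_TYPE_FLOAT64"
    )
    tri = gifti.GiftiDataArray(
        mesh.faces.astype(np.int32), intent="NIFTI_INTENT_TRIANGLE", datatype="NIFTI_TYPE_INT32"
    )
    _write_gifti([pts, tri], path)


def read_surface(path: str | Path) -> SurfaceMesh:
    img = nib.load(str(path))
    pts = tri = None
    from nibabel.nifti1 import intent_codes

    for da in img.darrays:
        if da.intent == intent_codes["NIFTI_INTENT_POINTSET"]:
            pts = da.data
        elif da.intent == intent_codes["NIFTI_INTENT_TRIANGLE"]:
            tri = da.data
    if pts is None or tri is None:
        raise ValueError(f"{path}: GIFTI surface needs POINTSET and TRIANGLE arrays")
    return SurfaceMesh(np.asarray(pts, dtype=np.float64), np.asarray(tri, dtype=np.int64))


def write_vertex_map(values: np.ndarray, path: str | Path) -> None:
    da = gifti.GiftiDataArray(
        np.asarray(values, dtype=np.float64), intent="NIFTI_INTENT_NONE", datatype="NIFTI_TYPE_FLOAT64"
    )
    _write_gifti([da], path)


def read_vertex_map(path: str | Path, mesh: SurfaceMesh | None = None) -> np.ndarray:
    img = nib.load(str(path))
    values = np.asarray(img.darrays[0].data, dtype=np.float64)
    if mesh is not None and values.shape != (mesh.n_vertices,):
        raise ValueError(
            f"{path}: map has {values.shape[0]} values but the mesh has {mesh.n_vertices} vertices"
        )
    return values


# ---------------------------------------------------------------------------
# TRK tractograms

def write_trk(tractogram: Tractogram, path: str | Path) -> None:
    """Write streamlines in world RAS mm (TRK voxel-order bookkeeping is
    handled by nibabel; the reader recovers world mm)."""
    streams = [s.points.astype(np.float32) for s in tractogram.streamlines]
    data_per_streamline = {
        "mean_fa": np.asarray([[s.mean_fa] for s in tractogram.streamlines], dtype=np.float32),
        "seed_cu": np.asarray(
            [[-1 if s.seed_cu is None else s.seed_cu] for s in tractogram.streamlines],
            dtype=np.float32,
        ),
    }
    t = nib_streamlines.Tractogram(
        streams, data_per_streamline=data_per_streamline, affine_to_rasmm=np.eye(4)
    )
    nib_streamlines.save(t, str(path))


def read_trk(path: str | Path) -> Tractogram:
    f = nib_streamlines.load(str(path))
    t = f.tractogram
    streamlines = []
    mean_fa = t.data_per_streamline.get("mean_fa")
    seed_cu = t.data_per_streamline.get("seed_cu")
    for i, pts in enumerate(t.streamlines):
        fa = float(mean_fa[i][0]) if mean_fa is not None else np.nan
        cu = int(seed_cu[i][0]) if seed_cu is not None else None
        streamlines.append(
            Streamline(np.asarray(pts, dtype=np.float64), mean_fa=fa, seed_cu=None if cu == -1 else cu)
        )
    return Tractogram(streamlines=streamlines)


# ---------------------------------------------------------------------------
# cohort TSV (+ per-subject GIFTI maps)

def write_cohort_tsv(cohort: CohortTable, path: str | Path, write_maps: bool = True) -> None:
    """Write the cohort covariate table as TSV; per-subject FiCD / GM-volume
    maps go to sibling GIFTI files referenced by relative path."""
    path = Path(path)
    table = cohort.table.copy()
    if write_maps:
        map_dir = path.parent / (path.stem + "_maps")
        map_dir.mkdir(parents=True, exist_ok=True)
        ficd_paths, gm_paths = [], []
        for i, sub in enumerate(table["subject"]):
            fp = map_dir / f"{sub}.ficd.gii"
            write_vertex_map(cohort.ficd_maps[i], fp)
            ficd_paths.append(str(fp.relative_to(path.parent)))
            if cohort.gm_maps is not None:
                gp = map_dir / f"{sub}.gmvol.gii"
                write_vertex_map(cohort.gm_maps[i], gp)
                gm_paths.append(str(gp.relative_to(path.parent)))
        table["ficd_map"] = ficd_paths
        if cohort.gm_maps is not None:
            table["gm_map"] = gm_paths
    table.to_csv(path, sep="\t", index=False)


def read_cohort_tsv(path: str | Path, mesh: SurfaceMesh | None = None) -> CohortTable:
    path = Path(path)
    table = pd.read_csv(path, sep="\t")
    required = ["subject", "group", "total_brain_volume", "severity"]
    missing = [c for c in required if c not in table.columns]
    if missing:
        raise ValueError(f"{path}: cohort TSV missing columns {missing}")
    bad = table.index[table["group"].isna()].tolist()
    if bad:
        raise ValueError(f"{path}: missing group label in rows {bad}")
    if "ficd_map" not in table.columns:
        raise ValueError(f"{path}: cohort TSV has no ficd_map column")
    ficd = np.vstack([read_vertex_map(path.parent / p, mesh) for p in table["ficd_map"]])
    gm = None
    if "gm_map" in table.columns:
        gm = np.vstack([read_vertex_map(path.parent / p, mesh) for p in table["gm_map"]])
    covars = table[required].copy()
    return CohortTable(covars, ficd, gm_maps=gm, mesh=mesh)
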