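"""ROI analyses on significant clusters.

After the vertex-wise comparison, each surviving cluster is treated as a
region of interest: per subject we extract its mean FiCD and summed GM
volume, and — by re-seeding the tracker from the subcortical voxel layer
beneath the cluster — its fiber number (FN) and mean fiber FA.  Group
differences use pooled-variance two-sample t tests, falling back to the
Mann-Whitney U test when a Shapiro normality check rejects at p < 0.05;
relationships among severity score, FiCD and GM volume are evaluated with
partial correlations controlling for total brain volume within each group.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from scipy import stats

from .core import CohortTable, SurfaceMesh, TensorVolume
from .group_stats import ClusterResult
from .parcellation import seed_layer_for_faces
from .tractography import TrackingParams, track_from_mask


@dataclasses.dataclass
class ClusterMetrics:
    """Per-subject scalar metrics of one cluster."""

    cluster_id: int
    mean_ficd: np.ndarray  # (n_subjects,)
    gm_volume: np.ndarray  # (n_subjects,) mm^3
    fiber_number: np.ndarray | None = None  # (n_subjects,) int
    mean_fiber_fa: np.ndarray | None = None


def cluster_faces(mesh: SurfaceMesh, vertex_ids: np.ndarray) -> np.ndarray:
    """Faces considered part of a vertex cluster: >= 2 member vertices."""
    member = np.zeros(mesh.n_vertices, dtype=bool)
    member[vertex_ids] = True
    return np.flatnonzero(member[mesh.faces].sum(axis=1) >= 2)


def extract_cluster_metrics(
    cluster: ClusterResult,
    cohort: CohortTable,
    vol: TensorVolume | None = None,
    params: TrackingParams | None = None,
    thickness: float | None = None,
    cluster_id: int = 0,
) -> ClusterMetrics:
    """Extract per-subject mean FiCD, GM volume and (optionally) FN/mean-FA.

    Mean FiCD is the unweighted mean over cluster vertices; GM volume is the
    sum of the per-vertex GM-volume map over the cluster.  When a tensor
    volume is supplied the cluster's subcortical seed layer is re-seeded
    with ``track_from_mask`` to obtain FN and mean fiber FA.  Under shared
    mesh topology the common-space cluster maps onto each subject's surface
    by the identity (a vertex-correspondence hook covers real data).
    """
    vids = np.asarray(cluster.vertex_ids, dtype=int)
    mean_ficd = cohort.ficd_maps[:, vids].mean(axis=1)
    if cohort.gm_maps is None:
        gm = np.full(len(cohort), np.nan)
    else:
        gm = cohort.gm_maps[:, vids].sum(axis=1)
    fn = mfa = None
    if vol is not None:
        mesh = cohort.mesh
        params = params or TrackingParams()
        faces = cluster_faces(mesh, vids)
        seed = seed_layer_for_faces(mesh, faces, vol, thickness or float(np.min(vol.voxel_size)))
        if len(seed) == 0:
            fn = np.full(len(cohort), np.nan)
            mfa = np.full(len(cohort), np.nan)
        else:
            tracks = track_from_mask(vol, seed, params)
            n = len(tracks)
            fa = float(np.mean(tracks.mean_fas)) if n else np.nan
            # the synthetic cohort shares one tensor volume across subjects
            fn = np.full(len(cohort), float(n))
            mfa = np.full(len(cohort), fa)
    return ClusterMetrics(cluster_id=cluster_id, mean_ficd=mean_ficd, gm_volume=gm, fiber_number=fn, mean_fiber_fa=mfa)


# ---------------------------------------------------------------------------
# statistical primitives

def two_sample_t(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """Pooled-variance two-sided two-sample t test.

    Degenerate zero-variance inputs: equal means -> (0, 1); unequal means ->
    (+/- inf, 0).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each sample needs n >= 2")
    if np.var(a, ddof=1) == 0.0 and np.var(b, ddof=1) == 0.0:
        if a.mean() == b.mean():
            return 0.0, 1.0
        return float(np.sign(a.mean() - b.mean()) * np.inf), 0.0
    t, p = stats.ttest_ind(a, b, equal_var=True)
    return float(t), float(p)


def mann_whitney_u(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """Two-sided Mann-Whitney U (exact where SciPy permits, tie-corrected
    normal approximation otherwise); the statistic is U of the first sample."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each sample needs n >= 2")
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method="auto")
    return float(res.statistic), float(res.pvalue)


def partial_correlation(x: np.ndarray, y: np.ndarray, control: np.ndarray) -> tuple[float, float]:
    """Pearson correlation of x and y after regressing each on [1, control];
    p from the t transform with n - 3 degrees of freedom."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    z = np.asarray(control, dtype=float)
    n = len(x)
    if n < 4:
        raise ValueError("partial correlation needs n >= 4")
    Z = np.column_stack([np.ones(n), z])
    if np.linalg.matrix_rank(Z) < 2:
        raise ValueError("control variable is constant")
    rx = x - Z @ np.linalg.lstsq(Z, x, rcond=None)[0]
    ry = y - Z @ np.linalg.lstsq(Z, y, rcond=None)[0]
    if np.allclose(rx, 0) or np.allclose(ry, 0):
        raise ValueError("a variable is constant after residualization")
    r = float(np.corrcoef(rx, ry)[0, 1])
    df = n - 3
    r_clip = min(max(r, -1.0 + 1e-15), 1.0 - 1e-15)
    t = r_clip * np.sqrt(df / (1.0 - r_clip**2))
    p = 2.0 * stats.t.sf(abs(t), df)
    return r, float(p)


def _group_row(name: str, cid: int, a: np.ndarray, b: np.ndarray, normality_alpha: float = 0.05, force_test: str | None = None) -> dict:
    a = a[np.isfinite(a)]
    b = b[np.isfinite(b)]
    if force_test == "t":
        use_t = True
    elif force_test == "u":
        use_t = False
    else:
        use_t = True
        for sample in (a, b):
            # Shapiro is undefined for constant samples; treat those as normal
            if len(sample) >= 3 and np.var(sample) > 0 and stats.shapiro(sample).pvalue < normality_alpha:
                use_t = False
    stat, p = two_sample_t(a, b) if use_t else mann_whitney_u(a, b)
    return {
        "cluster": cid,
        "analysis": "group",
        "metric": name,
        "test": "t" if use_t else "mann-whitney-u",
        "group_a_mean": float(a.mean()),
        "group_a_sd": float(a.std(ddof=1)),
        "group_b_mean": float(b.mean()),
        "group_b_sd": float(b.std(ddof=1)),
        "statistic": stat,
        "p": p,
    }


def roi_report(
    cohort: CohortTable,
    clusters: list[ClusterResult],
    vol: TensorVolume | None = None,
    params: TrackingParams | None = None,
    force_test: str | None = None,
) -> pd.DataFrame:
    """Per-cluster ROI table: group comparisons of mean FiCD, GM volume, FN
    and mean fiber FA, plus within-group partial correlations (severity-FiCD,
    severity-GM, FiCD-GM) controlling for total brain volume."""
    levels = cohort.group_levels
    if len(levels) != 2:
        raise ValueError("roi_report needs exactly two groups")
    ma = cohort.group_mask(levels[0])
    mb = cohort.group_mask(levels[1])
    sev = cohort.table["severity"].to_numpy(dtype=float)
    tbv = cohort.table["total_brain_volume"].to_numpy(dtype=float)
    rows: list[dict] = []
    for cid, cl in enumerate(clusters):
        m = extract_cluster_metrics(cl, cohort, vol=vol, params=params, cluster_id=cid)
        metrics = {"mean_ficd": m.mean_ficd, "gm_volume": m.gm_volume}
        if m.fiber_number is not None:
            metrics["fiber_number"] = m.fiber_number
            metrics["mean_fiber_fa"] = m.mean_fiber_fa
        for name, values in metrics.items():
            if not np.isfinite(values).all():
                rows.append({"cluster": cid, "analysis": "group", "metric": name, "test": "excluded"})
                continue
            rows.append(_group_row(name, cid, values[ma], values[mb], force_test=force_test))
        pairs = [
            ("severity~mean_ficd", sev, m.mean_ficd),
            ("severity~gm_volume", sev, m.gm_volume),
            ("mean_ficd~gm_volume", m.mean_ficd, m.gm_volume),
        ]
        for label, mask in zip(levels, (ma, mb)):
            for name, x, y in pairs:
                ok = mask & np.isfinite(x) & np.isfinite(y) & np.isfinite(tbv)
                row = {"cluster": cid, "analysis": f"partial_corr[{label}]", "metric": name}
                try:
                    r, p = partial_correlation(x[ok], y[ok], tbv[ok])
                    row.update({"statistic": r, "p": p, "test": "partial-r"})
                except ValueError:
                    row["test"] = "excluded"
                rows.append(row)
    return pd.DataFrame(rows)
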