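"""Implant fit metrics and cohort statistics.

Surface RMSE is the root mean squared Euclidean closest-point distance of
sampled points on one surface to the other, after rigid ICP alignment
(sqrt(sum d_i^2 / N)). Maximum over/underhang (OUH) is the directed
Hausdorff distance h(C, B) = max_{c in C} min_{b in B} d(c, b) between the
component edges C and the resected-bone edges B; OUH >= 3 mm (inclusive)
is flagged as clinically significant. Cohort utilities provide Welch
two-sample t-tests and Spearman correlations with a 1.5 x IQR outlier rule.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import trimesh
from scipy.spatial import cKDTree
from scipy.stats import spearmanr, ttest_ind
from shapely.geometry import LineString, Point

from .geometry import MeshDistance, RigidTransform, kabsch, sample_mesh_surface
from .implant import ImplantComponent, _resample_closed, resect_bone
from .ssm import rigid_icp


@dataclass
class EdgeSet:
    component: np.ndarray  # C, (n, d) mm
    bone: np.ndarray  # B, (m, d) mm

    def __post_init__(self) -> None:
        self.component = np.atleast_2d(np.asarray(self.component, dtype=float))
        self.bone = np.atleast_2d(np.asarray(self.bone, dtype=float))
        if len(self.component) == 0 or len(self.bone) == 0:
            raise ValueError("edge sets must be non-empty")
        if not (np.isfinite(self.component).all() and np.isfinite(self.bone).all()):
            raise ValueError("edge sets must be finite")


@dataclass
class FitReport:
    kind: str
    rmse_mm: float
    max_ouh_mm: float
    ouh_flag: bool
    alignment: RigidTransform | None
    n_samples: int
    region: str = ""

    def as_dict(self) -> dict:
        return {
            "kind": self.kind,
            "rmse_mm": self.rmse_mm,
            "max_ouh_mm": self.max_ouh_mm,
            "ouh_flag": bool(self.ouh_flag),
            "region": self.region,
        }


# ---------------------------------------------------------------------------
# RMSE / OUH primitives
# ---------------------------------------------------------------------------
def rmse_from_distances(dists) -> float:
    """Direct RMSE over paired closest-point distances: sqrt(sum d^2 / N)."""
    d = np.asarray(dists, dtype=float)
    return float(np.sqrt(np.mean(d**2)))


def surface_rmse(
    pred_surface: trimesh.Trimesh,
    gt_surface: trimesh.Trimesh,
    region: tuple[float, float] | None = None,
    n_samples: int = 2000,
    seed: int = 0,
    align: bool = True,
) -> float:
    """Surface-to-surface RMSE of ``pred`` vs ``gt`` in millimetres.

    Points are sampled on the prediction (restricted to the ``region``
    z-band when given — the band covered by the fitted contour stack);
    rigid ICP pre-aligns them to the ground truth unless ``align=False``.
    """
    pts = sample_mesh_surface(pred_surface, n_samples, seed)
    if region is not None:
        lo, hi = region
        sel = (pts[:, 2] >= lo) & (pts[:, 2] <= hi)
        pts = pts[sel]
        if len(pts) == 0:
            raise ValueError("empty region: no sampled points in the z band")
    md = MeshDistance(gt_surface)
    if align:
        T, _ = rigid_icp(pts, md)
        pts = T.apply(pts)
    _, d, _, _ = md.query(pts)
    return rmse_from_distances(d)


def max_ouh(edges: EdgeSet | tuple) -> float:
    """Directed Hausdorff distance h(C, B), exact over the given point sets."""
    es = edges if isinstance(edges, EdgeSet) else EdgeSet(*edges)
    tree = cKDTree(es.bone)
    d, _ = tree.query(es.component)
    return float(d.max())


def ouh_flag(h_mm: float, threshold: float = 3.0) -> bool:
    """Clinical significance flag; the threshold is inclusive (>=)."""
    if h_mm < 0:
        raise ValueError("OUH must be non-negative")
    return bool(h_mm >= threshold)


# ---------------------------------------------------------------------------
# component fit
# ---------------------------------------------------------------------------
def _icp_2d(source: np.ndarray, target: np.ndarray, iters: int = 50) -> np.ndarray:
    """Rigid 2-D ICP of point sets; returns aligned source points."""
    src = source.copy()
    tree = cKDTree(target)
    prev = np.inf
    for _ in range(iters):
        d, idx = tree.query(src)
        if prev - d.mean() < 1e-9:
            break
        prev = d.mean()
        T = kabsch(src, target[idx])
        src = src @ T.rotation[:2, :2].T + T.translation[:2]
    return src


def component_fit(
    component: ImplantComponent,
    gt,
    threshold_mm: float = 3.0,
    n_samples: int = 1500,
    seed: int = 0,
    align: bool = True,
) -> FitReport:
    """Fit of one implant component against ground-truth bone geometry.

    Femur: the component surface (pins excluded) is ICP-aligned to the
    ground-truth mesh; RMSE is computed over the bone-facing surface and
    OUH between the component edge loops and the edges of the ground truth
    resected by the same cut plan. Tibia: RMSE and OUH between the 2-D
    base profile and the equivalent ground-truth profile after rigid 2-D
    alignment.
    """
    if component.kind == "femur_component":
        if not isinstance(gt, trimesh.Trimesh):
            raise ValueError("femur component fit needs a ground-truth mesh")
        md = MeshDistance(gt)
        outer_pts = sample_mesh_surface(component.outer_patch, n_samples, seed)
        T = RigidTransform.identity()
        if align:
            T, _ = rigid_icp(outer_pts, md)
        inner_pts = sample_mesh_surface(component.inner_patch, n_samples, seed + 1)
        _, d, _, _ = md.query(T.apply(inner_pts))
        rmse = rmse_from_distances(d)
        # resect the ground truth with the plan carried into its frame
        resec = resect_bone(gt, component.provenance["plan"].transformed(T))
        B = np.vstack(resec["edge_loops"])
        C = np.vstack([T.apply(loop) for loop in component.edge_loops])
        h = max_ouh(EdgeSet(C, B))
        return FitReport("femur_component", rmse, h, ouh_flag(h, threshold_mm), T,
                         len(inner_pts), region="bone-facing surface")
    if component.kind == "tibia_plate":
        if isinstance(gt, trimesh.Trimesh):
            prof = component.profile
            if align and prof.source_mesh is not None:
                src_pts = sample_mesh_surface(prof.source_mesh, n_samples, seed)
                T3, _ = rigid_icp(src_pts, MeshDistance(gt))
                prof = prof.carried_through(T3)
            gt_profile = resect_bone(gt, prof)["profile"]
        else:
            gt_profile = gt  # already a polygon
        pred_poly = component.profile.polygon
        C = _resample_closed(np.asarray(pred_poly.exterior.coords)[:-1], 0.5)
        Bpts = _resample_closed(np.asarray(gt_profile.exterior.coords)[:-1], 0.5)
        if align:
            C = _icp_2d(C, Bpts)
        bline = LineString(np.vstack([Bpts, Bpts[:1]]))
        d = np.array([bline.distance(Point(p)) for p in C])
        rmse = rmse_from_distances(d)
        h = float(d.max())
        return FitReport("tibia_plate", rmse, h, ouh_flag(h, threshold_mm), None,
                         len(C), region="base profile")
    raise ValueError(f"unknown component kind {component.kind!r}")


def prediction_fit(
    pred_mesh: trimesh.Trimesh,
    gt_mesh: trimesh.Trimesh,
    region: tuple[float, float] | None,
    n_samples: int = 2000,
    seed: int = 0,
) -> FitReport:
    """Surface RMSE of a 3-D bone prediction against ground truth."""
    rmse = surface_rmse(pred_mesh, gt_mesh, region=region, n_samples=n_samples, seed=seed)
    return FitReport("prediction", rmse, 0.0, False, None, n_samples, region="condylar band")


# ---------------------------------------------------------------------------
# heatmaps
# ---------------------------------------------------------------------------
def distance_heatmap(surface: trimesh.Trimesh, reference: trimesh.Trimesh, out_image,
                     out_table=None):
    """Per-vertex closest-point distance map, rendered and dumped.

    Returns the per-vertex distances; the figure colour scale spans
    [0, max distance].
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    _, d, _, _ = MeshDistance(reference).query(surface.vertices)
    fig = plt.figure(figsize=(6, 5))
    ax = fig.add_subplot(projection="3d")
    vmax = float(d.max()) if d.max() > 0 else 1e-9
    sc = ax.scatter(*surface.vertices.T, c=d, s=2, cmap="jet", vmin=0.0, vmax=vmax)
    fig.colorbar(sc, label="distance (mm)")
    ax.set_box_aspect(np.ptp(surface.vertices, axis=0))
    fig.savefig(out_image, dpi=110)
    plt.close(fig)
    if out_table is not None:
        pd.DataFrame(
            {"x": surface.vertices[:, 0], "y": surface.vertices[:, 1],
             "z": surface.vertices[:, 2], "distance_mm": d}
        ).to_csv(out_table, index=False)
    return d


# ---------------------------------------------------------------------------
# cohort statistics
# ---------------------------------------------------------------------------
def remove_outliers_iqr(x: np.ndarray, factor: float = 1.5) -> np.ndarray:
    """Drop values outside [Q1 - f*IQR, Q3 + f*IQR]."""
    x = np.asarray(x, dtype=float)
    q1, q3 = np.percentile(x, [25, 75])
    iqr = q3 - q1
    return x[(x >= q1 - factor * iqr) & (x <= q3 + factor * iqr)]


def cohort_stats(
    df: pd.DataFrame,
    metrics: list[str],
    group_cols: list[str] | None = None,
    continuous_cols: list[str] | None = None,
    p_threshold: float = 0.05,
    r_threshold: float = 0.5,
) -> pd.DataFrame:
    """Group comparisons and covariate correlations for fit metrics.

    For each binary grouping attribute: group means/sds and a Welch
    two-sample t-test (outliers removed per group by the 1.5 x IQR rule).
    For each continuous covariate: Spearman's r. Significance flags use
    p <= 0.05 and |r| >= 0.5.
    """
    rows = []
    group_cols = group_cols or []
    continuous_cols = continuous_cols or []
    for metric in metrics:
        for g in group_cols:
            levels = sorted(df[g].dropna().unique())
            if len(levels) != 2:
                continue
            a = remove_outliers_iqr(df.loc[df[g] == levels[0], metric].dropna())
            b = remove_outliers_iqr(df.loc[df[g] == levels[1], metric].dropna())
            if len(a) < 2 or len(b) < 2:
                rows.append({"metric": metric, "test": f"t:{g}", "statistic": np.nan,
                             "p_or_r": np.nan, "significant": "n/a",
                             "group_a": f"{levels[0]}", "group_b": f"{levels[1]}",
                             "mean_a": np.nan, "mean_b": np.nan, "sd_a": np.nan, "sd_b": np.nan})
                continue
            t, p = ttest_ind(a, b, equal_var=False)
            rows.append({"metric": metric, "test": f"t:{g}", "statistic": float(t),
                         "p_or_r": float(p), "significant": bool(p <= p_threshold),
                         "group_a": f"{levels[0]}", "group_b": f"{levels[1]}",
                         "mean_a": float(a.mean()), "mean_b": float(b.mean()),
                         "sd_a": float(a.std(ddof=1)), "sd_b": float(b.std(ddof=1))})
        for c in continuous_cols:
            sub = df[[c, metric]].dropna()
            if len(sub) < 3:
                rows.append({"metric": metric, "test": f"spearman:{c}", "statistic": np.nan,
                             "p_or_r": np.nan, "significant": "n/a"})
                continue
            r, _ = spearmanr(sub[c], sub[metric])
            rows.append({"metric": metric, "test": f"spearman:{c}", "statistic": float(r),
                         "p_or_r": float(r), "significant": bool(abs(r) >= r_threshold)})
    return pd.DataFrame(rows)
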