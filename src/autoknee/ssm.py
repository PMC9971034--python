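"""Statistical shape models and contour-stack fitting.

A shape model is the mean of a corresponded, rigidly (no scaling)
Procrustes-aligned mesh population plus an orthonormal principal-component
basis of the vertex covariance; absolute size is carried by the modes, not
by a similarity factor. Contour stacks are registered to the base shape by
a coarse centroid/principal-axis initialisation followed by rigid ICP, and
the surface prediction is produced by morphing a limited number of
principal components to minimise the mean squared point-to-surface
distance of the stack to the synthesized mesh.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import trimesh
from scipy.optimize import lsq_linear

from .contours import ContourStack
from .geometry import MeshDistance, RigidTransform, kabsch, rotation_about_axis


class ShapeModelError(RuntimeError):
    pass


@dataclass
class ShapeModel:
    mean_vertices: np.ndarray  # (V, 3) mm
    faces: np.ndarray  # (F, 3)
    components: np.ndarray  # (modes, 3V), orthonormal rows
    variances: np.ndarray  # (modes,), non-increasing
    metadata: dict = field(default_factory=dict)

    @property
    def n_modes_available(self) -> int:
        return len(self.components)

    def base_mesh(self) -> trimesh.Trimesh:
        return trimesh.Trimesh(self.mean_vertices.copy(), self.faces.copy(), process=False)

    def save(self, path: str | Path) -> None:
        np.savez_compressed(
            path,
            mean_vertices=self.mean_vertices,
            faces=self.faces,
            components=self.components,
            variances=self.variances,
        )

    @classmethod
    def load(cls, path: str | Path) -> "ShapeModel":
        d = np.load(path)
        return cls(d["mean_vertices"], d["faces"], d["components"], d["variances"])


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------
def _procrustes_align(stacks: np.ndarray, iters: int = 5) -> np.ndarray:
    """Generalised Procrustes (rigid only, no scaling) on (n, V, 3)."""
    X = stacks - stacks.mean(axis=1, keepdims=True)
    ref = X[0]
    for _ in range(iters):
        for i in range(len(X)):
            T = kabsch(X[i], ref)
            X[i] = T.apply(X[i])
        new_ref = X.mean(axis=0)
        if np.linalg.norm(new_ref - ref) < 1e-10:
            break
        ref = new_ref
    return X


def train_ssm(meshes: list[trimesh.Trimesh], smooth_iters: int = 0) -> ShapeModel:
    """PCA shape model from corresponded meshes.

    Generalised Procrustes alignment (rigid, no scaling) is followed by an
    eigen-decomposition of the vertex covariance; the mean mesh is
    optionally Laplacian-smoothed ``smooth_iters`` times to idealise the
    base shape.
    """
    if len(meshes) < 2:
        raise ShapeModelError("need at least 2 meshes")
    faces0 = meshes[0].faces
    for m in meshes[1:]:
        if m.faces.shape != faces0.shape or not np.array_equal(m.faces, faces0):
            raise ShapeModelError("topology mismatch: meshes are not in correspondence")
    V = np.stack([m.vertices for m in meshes])  # (n, Vv, 3)
    # keep absolute position: GPA centres shapes; re-add the population mean
    centroid = V.mean(axis=(0, 1))
    aligned = _procrustes_align(V.copy())
    X = aligned.reshape(len(meshes), -1)
    mean_flat = X.mean(axis=0)
    Xc = X - mean_flat
    _, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    variances = s**2 / (len(meshes) - 1)
    nz = variances > max(1e-12, variances[0] * 1e-12)
    components = Vt[nz]
    variances = variances[nz]
    mean_vertices = mean_flat.reshape(-1, 3) + centroid
    if smooth_iters > 0:
        mm = trimesh.Trimesh(mean_vertices.copy(), faces0.copy(), process=False)
        trimesh.smoothing.filter_laplacian(mm, iterations=smooth_iters, volume_constraint=True)
        mean_vertices = mm.vertices.copy()
    return ShapeModel(mean_vertices, faces0.copy(), components, variances)


def synthesize(model: ShapeModel, weights) -> trimesh.Trimesh:
    """Base shape plus a weighted sum of principal components."""
    weights = np.asarray(weights, dtype=float)
    if len(weights) > model.n_modes_available:
        raise ShapeModelError(
            f"{len(weights)} weights but only {model.n_modes_available} modes available"
        )
    disp = weights @ model.components[: len(weights)] if len(weights) else 0.0
    verts = model.mean_vertices + np.reshape(disp, (-1, 3)) if len(weights) else model.mean_vertices.copy()
    return trimesh.Trimesh(verts, model.faces.copy(), process=False)


def project_weights(model: ShapeModel, mesh: trimesh.Trimesh, n_modes: int | None = None) -> np.ndarray:
    """Least-squares mode weights reproducing a corresponded mesh."""
    flat = (mesh.vertices - model.mean_vertices).reshape(-1)
    comps = model.components if n_modes is None else model.components[:n_modes]
    return comps @ flat


# ---------------------------------------------------------------------------
# registration
# ---------------------------------------------------------------------------
def rigid_icp(
    source_points: np.ndarray,
    target: trimesh.Trimesh | MeshDistance,
    max_iters: int = 100,
    tol_mm: float = 1e-6,
    init: RigidTransform | None = None,
) -> tuple[RigidTransform, float]:
    """Rigid ICP of points onto a mesh surface.

    Alternates exact closest-point correspondence with a least-squares
    rigid (Kabsch) solve until the mean-distance improvement drops below
    ``tol_mm``. Returns the best transform found and its mean distance.
    """
    pts = np.asarray(source_points, dtype=float)
    if len(pts) < 3 or np.linalg.matrix_rank(pts - pts.mean(axis=0)) < 2:
        raise ShapeModelError("degenerate source: need >= 3 non-collinear points")
    md = target if isinstance(target, MeshDistance) else MeshDistance(target)
    T = init if init is not None else RigidTransform.identity()
    cur = T.apply(pts)
    best_T, best_d = T, np.inf
    prev_d = np.inf
    for _ in range(max_iters):
        closest, dists, _, _ = md.query(cur)
        mean_d = float(dists.mean())
        if mean_d < best_d:
            best_d, best_T = mean_d, T
        if prev_d - mean_d < tol_mm:
            break
        prev_d = mean_d
        step = kabsch(cur, closest)
        T = step.compose(T)
        cur = T.apply(pts)
    return best_T, best_d


def align_stack_to_base(
    stack: ContourStack | np.ndarray,
    model: ShapeModel,
    max_iters: int = 100,
    tol_mm: float = 1e-6,
    max_points: int = 800,
    seed: int = 0,
) -> tuple[np.ndarray, RigidTransform]:
    """Register stack points to the base shape: coarse init + rigid ICP.

    Initialisation matches centroids and in-plane (xy) principal axes while
    keeping z as the slice normal; the pi-ambiguous axis flip is resolved by
    the lower post-ICP residual.
    """
    pts_all = stack.points() if isinstance(stack, ContourStack) else np.asarray(stack, dtype=float)
    if len(pts_all) == 0:
        raise ShapeModelError("empty stack")
    rng = np.random.default_rng(seed)
    pts = pts_all[rng.choice(len(pts_all), size=min(max_points, len(pts_all)), replace=False)]
    base = model.base_mesh()
    md = MeshDistance(base)

    def principal_angle(p2d: np.ndarray) -> float:
        c = p2d - p2d.mean(axis=0)
        cov = c.T @ c
        evals, evecs = np.linalg.eigh(cov)
        v = evecs[:, np.argmax(evals)]
        return float(np.arctan2(v[1], v[0]))

    ang_src = principal_angle(pts[:, :2])
    ang_tgt = principal_angle(base.vertices[:, :2])
    best = None
    for extra in (0.0, np.pi):
        R = rotation_about_axis([0, 0, 1], ang_tgt - ang_src + extra)
        t = base.vertices.mean(axis=0) - R @ pts.mean(axis=0)
        T0 = RigidTransform(R, t)
        T, d = rigid_icp(pts, md, max_iters=max_iters, tol_mm=tol_mm, init=T0)
        if best is None or d < best[1]:
            best = (T, d)
    T = best[0]
    return T.apply(pts_all), T


# ---------------------------------------------------------------------------
# morphing
# ---------------------------------------------------------------------------
def morph_to_stack(
    model: ShapeModel,
    stack_points: np.ndarray,
    n_pc: int = 2,
    max_outer: int = 25,
    tol: float = 1e-8,
    weight_bound_sd: float = 3.0,
    max_points: int = 800,
    seed: int = 0,
) -> tuple[trimesh.Trimesh, np.ndarray, dict]:
    """Morph the base shape to fit an aligned contour stack.

    Alternates (a) exact closest-point correspondence of the stack points
    on the current synthesized surface — recorded as barycentric
    coordinates, which makes the surface point linear in the weights — and
    (b) a bound-constrained linear least-squares solve for the ``n_pc``
    weights (|w_i| <= weight_bound_sd * sd_i). The mean squared distance is
    non-increasing across outer iterations; returns the synthesized mesh at
    the optimum, the weights, and an info dict (converged flag, objective).
    """
    if n_pc > model.n_modes_available:
        raise ShapeModelError("n_pc exceeds available modes")
    pts_all = np.asarray(stack_points, dtype=float)
    rng = np.random.default_rng(seed)
    pts = pts_all[rng.choice(len(pts_all), size=min(max_points, len(pts_all)), replace=False)]
    if n_pc == 0:
        return model.base_mesh(), np.zeros(0), {"converged": True, "objective_mm2": None}

    comps = model.components[:n_pc]  # (p, 3V)
    comp_verts = comps.reshape(n_pc, -1, 3)  # (p, V, 3)
    sds = np.sqrt(model.variances[:n_pc])
    bounds = weight_bound_sd * sds
    w = np.zeros(n_pc)
    prev_obj = np.inf
    converged = False
    for _ in range(max_outer):
        mesh = synthesize(model, w)
        md = MeshDistance(mesh)
        closest, dists, fids, bary = md.query(pts)
        obj = float(np.mean(dists**2))
        if prev_obj - obj < tol:
            converged = True
            break
        prev_obj = obj
        tri_v = model.faces[fids]  # (n, 3) vertex ids
        # surface point = bary . (mean + sum_j w_j C_j) at those vertices
        mean_pt = np.einsum("nk,nkd->nd", bary, model.mean_vertices[tri_v])
        A = np.einsum("nk,pnkd->ndp", bary, comp_verts[:, tri_v, :])
        A = A.reshape(-1, n_pc)
        b = (pts - mean_pt).reshape(-1)
        res = lsq_linear(A, b, bounds=(-bounds, bounds))
        w = res.x
    mesh = synthesize(model, w)
    final_obj = float(np.mean(MeshDistance(mesh).query(pts)[1] ** 2))
    return mesh, w, {"converged": converged, "objective_mm2": final_obj}
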