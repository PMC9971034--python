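"""Shared mesh/point geometry kernels.

Exact point-to-triangle-surface projection (KD-tree candidate faces +
vectorised clamped-barycentric projection), rigid transforms and Kabsch
solves, open-mesh boundary-loop extraction, and constrained-Delaunay
polygon extrusion. These back the ICP, shape-model morphing, implant
construction and fit-metric modules.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import shapely
import trimesh
from scipy.spatial import cKDTree
from shapely.geometry import Polygon


# ---------------------------------------------------------------------------
# rigid transforms
# ---------------------------------------------------------------------------
@dataclass
class RigidTransform:
    """Proper rigid motion x -> R x + t (millimetres)."""

    rotation: np.ndarray  # (3, 3), det = +1
    translation: np.ndarray  # (3,)

    def __post_init__(self) -> None:
        self.rotation = np.asarray(self.rotation, dtype=float)
        self.translation = np.asarray(self.translation, dtype=float)
        if abs(np.linalg.det(self.rotation) - 1.0) > 1e-6:
            raise ValueError("rotation must be proper orthogonal (det=1)")

    def apply(self, points: np.ndarray) -> np.ndarray:
        return np.asarray(points) @ self.rotation.T + self.translation

    def inverse(self) -> "RigidTransform":
        return RigidTransform(self.rotation.T, -self.rotation.T @ self.translation)

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """self ∘ other: apply ``other`` first, then ``self``."""
        return RigidTransform(
            self.rotation @ other.rotation,
            self.rotation @ other.translation + self.translation,
        )

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))

    @property
    def rotation_angle_rad(self) -> float:
        c = (np.trace(self.rotation) - 1.0) / 2.0
        return float(np.arccos(np.clip(c, -1.0, 1.0)))


def kabsch(source: np.ndarray, target: np.ndarray) -> RigidTransform:
    """Least-squares rigid transform mapping paired ``source`` onto ``target``.

    Works for 2-D or 3-D point sets; reflections are excluded.
    """
    source = np.asarray(source, dtype=float)
    target = np.asarray(target, dtype=float)
    dim = source.shape[1]
    cs, ct = source.mean(axis=0), target.mean(axis=0)
    H = (source - cs).T @ (target - ct)
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.eye(dim)
    D[-1, -1] = d
    R = Vt.T @ D @ U.T
    if dim == 2:  # embed in 3-D for the shared dataclass
        R3 = np.eye(3)
        R3[:2, :2] = R
        t3 = np.zeros(3)
        t3[:2] = ct - R @ cs
        return RigidTransform(R3, t3)
    return RigidTransform(R, ct - R @ cs)


# ---------------------------------------------------------------------------
# exact closest point on a triangle mesh
# ---------------------------------------------------------------------------
def _closest_on_triangles(points: np.ndarray, tri: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Closest point of each ``points[i]`` on each triangle ``tri[i, j]``.

    points: (n, 3); tri: (n, k, 3, 3). Returns (closest (n,k,3), barycentric
    (n,k,3)). Clamped-barycentric: project to the triangle plane; if outside,
    take the best of the three edge projections.
    """
    a, b, c = tri[..., 0, :], tri[..., 1, :], tri[..., 2, :]
    p = points[:, None, :]
    ab, ac, ap = b - a, c - a, p - a
    d00 = np.einsum("...i,...i", ab, ab)
    d01 = np.einsum("...i,...i", ab, ac)
    d11 = np.einsum("...i,...i", ac, ac)
    d20 = np.einsum("...i,...i", ap, ab)
    d21 = np.einsum("...i,...i", ap, ac)
    denom = d00 * d11 - d01 * d01
    denom = np.where(np.abs(denom) < 1e-30, 1e-30, denom)
    v = (d11 * d20 - d01 * d21) / denom
    w = (d00 * d21 - d01 * d20) / denom
    u = 1.0 - v - w
    inside = (u >= 0) & (v >= 0) & (w >= 0)

    def _seg(p0, p1):
        d = p1 - p0
        L2 = np.einsum("...i,...i", d, d)
        L2 = np.where(L2 < 1e-30, 1e-30, L2)
        t = np.clip(np.einsum("...i,...i", p - p0, d) / L2, 0.0, 1.0)
        q = p0 + t[..., None] * d
        dist2 = np.einsum("...i,...i", p - q, p - q)
        return q, t, dist2

    qab, tab, dab = _seg(a, b)
    qbc, tbc, dbc = _seg(b, c)
    qca, tca, dca = _seg(c, a)
    edge_choice = np.argmin(np.stack([dab, dbc, dca], axis=-1), axis=-1)
    q_edge = np.where(
        (edge_choice == 0)[..., None], qab, np.where((edge_choice == 1)[..., None], qbc, qca)
    )
    # barycentric for the chosen edge point
    bary_ab = np.stack([1 - tab, tab, np.zeros_like(tab)], axis=-1)
    bary_bc = np.stack([np.zeros_like(tbc), 1 - tbc, tbc], axis=-1)
    bary_ca = np.stack([tca, np.zeros_like(tca), 1 - tca], axis=-1)
    bary_edge = np.where(
        (edge_choice == 0)[..., None],
        bary_ab,
        np.where((edge_choice == 1)[..., None], bary_bc, bary_ca),
    )
    q_in = a + v[..., None] * ab + w[..., None] * ac
    bary_in = np.stack([u, v, w], axis=-1)
    closest = np.where(inside[..., None], q_in, q_edge)
    bary = np.where(inside[..., None], bary_in, bary_edge)
    return closest, bary


class MeshDistance:
    """Exact closest-point queries against one triangle mesh.

    Candidate faces come from a KD-tree over face centroids (``k`` nearest,
    padded by the largest face circumradius so the true closest face is not
    missed in practice for reasonably uniform meshes); the projection onto
    each candidate triangle is exact.
    """

    def __init__(self, mesh: trimesh.Trimesh, k: int = 24):
        self.mesh = mesh
        self.k = min(k, len(mesh.faces))
        self._tri = mesh.triangles.copy()  # (F, 3, 3)
        self._tree = cKDTree(mesh.triangles_center)
        self._faces = mesh.faces

    def query(self, points: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
        """Return (closest_points, distances, face_ids, barycentric)."""
        points = np.atleast_2d(np.asarray(points, dtype=float))
        _, idx = self._tree.query(points, k=self.k)
        idx = np.atleast_2d(idx)
        tri = self._tri[idx]  # (n, k, 3, 3)
        closest, bary = _closest_on_triangles(points, tri)
        d2 = np.einsum("nki,nki->nk", points[:, None, :] - closest, points[:, None, :] - closest)
        best = np.argmin(d2, axis=1)
        rows = np.arange(len(points))
        return (
            closest[rows, best],
            np.sqrt(d2[rows, best]),
            idx[rows, best],
            bary[rows, best],
        )


def closest_point_on_mesh(mesh: trimesh.Trimesh, points: np.ndarray):
    """One-shot convenience wrapper around :class:`MeshDistance`."""
    return MeshDistance(mesh).query(points)


# ---------------------------------------------------------------------------
# boundary loops of an open mesh
# ---------------------------------------------------------------------------
def boundary_loops(mesh: trimesh.Trimesh) -> list[np.ndarray]:
    """Ordered vertex-index loops of edges used by exactly one face."""
    edges = mesh.edges_sorted
    unique, counts = np.unique(edges, axis=0, return_counts=True)
    boundary = unique[counts == 1]
    if len(boundary) == 0:
        return []
    # walk the boundary graph
    adj: dict[int, list[int]] = {}
    for a, b in boundary:
        adj.setdefault(int(a), []).append(int(b))
        adj.setdefault(int(b), []).append(int(a))
    seen: set[tuple[int, int]] = set()
    loops = []
    for a0, b0 in boundary:
        a0, b0 = int(a0), int(b0)
        if (a0, b0) in seen:
            continue
        loop = [a0]
        prev, cur = a0, b0
        seen.add((min(a0, b0), max(a0, b0)))
        while cur != a0:
            loop.append(cur)
            nxts = [n for n in adj[cur] if n != prev and (min(cur, n), max(cur, n)) not in seen]
            if not nxts:
                break
            nxt = nxts[0]
            seen.add((min(cur, nxt), max(cur, nxt)))
            prev, cur = cur, nxt
        loops.append(np.array(loop, dtype=int))
    return loops


# ---------------------------------------------------------------------------
# polygon extrusion via constrained Delaunay triangulation
# ---------------------------------------------------------------------------
def _triangulate_polygon(poly: Polygon) -> tuple[np.ndarray, np.ndarray]:
    """Triangulate a (possibly concave, possibly holed) polygon."""
    tris = shapely.constrained_delaunay_triangles(poly)
    verts: list[tuple[float, float]] = []
    index: dict[tuple[float, float], int] = {}
    faces = []
    for t in tris.geoms:
        # constrained DT covers the polygon; drop slivers outside (holes)
        if not poly.buffer(1e-9).contains(t.representative_point()):
            continue
        ids = []
        for x, y in np.asarray(t.exterior.coords)[:3]:
            key = (round(x, 9), round(y, 9))
            if key not in index:
                index[key] = len(verts)
                verts.append((x, y))
            ids.append(index[key])
        faces.append(ids)
    return np.array(verts, dtype=float), np.array(faces, dtype=int)


def extrude_polygon_mesh(poly: Polygon, thickness: float, z0: float = 0.0) -> trimesh.Trimesh:
    """Watertight prism: ``poly`` extruded from z0 to z0+thickness."""
    if not poly.is_valid or poly.is_empty:
        raise ValueError("polygon is invalid or empty")
    v2, faces2 = _triangulate_polygon(poly)
    n = len(v2)
    bottom = np.column_stack([v2, np.full(n, z0)])
    top = np.column_stack([v2, np.full(n, z0 + thickness)])
    verts = np.vstack([bottom, top])
    faces = [f[::-1] for f in faces2]  # bottom faces point down
    faces += [[f[0] + n, f[1] + n, f[2] + n] for f in faces2]
    # side walls from rings
    rings = [np.asarray(poly.exterior.coords)] + [np.asarray(i.coords) for i in poly.interiors]
    vlist = list(verts)
    key_of = {(round(x, 9), round(y, 9)): i for i, (x, y) in enumerate(v2)}

    def vid(x: float, y: float, top_layer: bool) -> int:
        key = (round(x, 9), round(y, 9))
        if key in key_of:
            return key_of[key] + (n if top_layer else 0)
        # ring point not used by triangulation (collinear) — append
        vlist.append([x, y, z0 + thickness if top_layer else z0])
        key_of_new = len(vlist) - 1
        return key_of_new

    for ring_i, ring in enumerate(rings):
        ccw = _ring_is_ccw(ring)
        # exterior CCW / holes CW give outward walls with the winding below
        flip = (ring_i == 0) != ccw
        for (x1, y1), (x2, y2) in zip(ring[:-1], ring[1:]):
            b1, b2 = vid(x1, y1, False), vid(x2, y2, False)
            t1, t2 = vid(x1, y1, True), vid(x2, y2, True)
            quad = [[b1, b2, t2], [b1, t2, t1]]
            if flip:
                quad = [[b2, b1, t1], [b2, t1, t2]]
            faces += quad
    mesh = trimesh.Trimesh(np.array(vlist, dtype=float), np.array(faces, dtype=int), process=False)
    mesh.merge_vertices()
    mesh.remove_unreferenced_vertices()
    trimesh.repair.fix_normals(mesh)
    return mesh


def _ring_is_ccw(ring: np.ndarray) -> bool:
    x, y = ring[:, 0], ring[:, 1]
    return float(np.sum((x[1:] - x[:-1]) * (y[1:] + y[:-1]))) < 0


# ---------------------------------------------------------------------------
# misc
# ---------------------------------------------------------------------------
def rotation_about_axis(axis: np.ndarray, angle_rad: float) -> np.ndarray:
    """Rodrigues rotation matrix."""
    axis = np.asarray(axis, dtype=float)
    axis = axis / np.linalg.norm(axis)
    K = np.array(
        [[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]], [-axis[1], axis[0], 0]]
    )
    return np.eye(3) + np.sin(angle_rad) * K + (1 - np.cos(angle_rad)) * (K @ K)


def sample_mesh_surface(mesh: trimesh.Trimesh, n: int, seed: int) -> np.ndarray:
    """Uniform area-weighted surface samples (deterministic given seed)."""
    rng = np.random.default_rng(seed)
    areas = mesh.area_faces
    probs = areas / areas.sum()
    fids = rng.choice(len(mesh.faces), size=n, p=probs)
    r1, r2 = rng.random(n), rng.random(n)
    s = np.sqrt(r1)
    u, v = 1 - s, s * (1 - r2)
    w = s * r2
    tri = mesh.triangles[fids]
    return u[:, None] * tri[:, 0] + v[:, None] * tri[:, 1] + w[:, None] * tri[:, 2]
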