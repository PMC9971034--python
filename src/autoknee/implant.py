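"""Generic TKR component geometry from predicted bone surfaces.

Femur component: the condylar surface of the prediction is clipped by a
five-plane box-cut family (anterior, anterior chamfer, distal/transverse,
posterior chamfer, posterior, plus medial/lateral trims), whose offsets
scale with the subject's condylar AP/ML measurements; the clipped patch is
the articular (outer) surface, its inward offset by the shell thickness is
the bone-facing surface, and side walls plus two fixation pins complete
the solid. Tibia plate: a cross-section taken parallel to the tibial
plateau, 2 mm distal to the widest medial-condyle point, is extruded to a
5 mm plate with a posterior cut, a proximal bearing recess and a distal
fixation pin. All operations are deterministic mesh geometry (no learned
components); fillets/chamfers are omitted as they do not enter the fit
metrics.

Canonical frame: x medial–lateral, y anterior–posterior (posterior = -y),
z slice axis increasing tibia -> femur; left knee (medial = -x).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import trimesh
from shapely.geometry import Polygon, box as shapely_box

from .config import FemurCutTemplate
from .geometry import boundary_loops, extrude_polygon_mesh, rotation_about_axis


class ImplantError(RuntimeError):
    pass


# ---------------------------------------------------------------------------
# measurements & cut planning
# ---------------------------------------------------------------------------
@dataclass
class CondylarMeasures:
    ap_mm: float
    ml_mm: float
    condylar_bounds: np.ndarray  # (2, 3) min/max of the condylar region

    def __iter__(self):
        return iter((self.ap_mm, self.ml_mm))


def measure_ap_ml(mesh: trimesh.Trimesh, condylar_fraction: float = 0.60) -> CondylarMeasures:
    """Maximum condylar AP (y) and ML (x) extents of a femur prediction.

    The condylar region is the distal ``condylar_fraction`` of the z
    extent (distal = low z in the canonical frame).
    """
    if len(mesh.vertices) == 0:
        raise ImplantError("empty mesh")
    z0, z1 = mesh.bounds[0][2], mesh.bounds[1][2]
    sel = mesh.vertices[:, 2] <= z0 + condylar_fraction * (z1 - z0)
    pts = mesh.vertices[sel]
    lo, hi = pts.min(axis=0), pts.max(axis=0)
    return CondylarMeasures(float(hi[1] - lo[1]), float(hi[0] - lo[0]), np.stack([lo, hi]))


@dataclass
class CutPlan:
    """Ordered oriented cutting planes; normals point toward retained material."""

    planes: list  # of (name, point (3,), unit normal (3,))

    def __post_init__(self) -> None:
        fixed = []
        for name, p, n in self.planes:
            n = np.asarray(n, dtype=float)
            fixed.append((name, np.asarray(p, dtype=float), n / np.linalg.norm(n)))
        self.planes = fixed

    def transformed(self, T) -> "CutPlan":
        """The same plan carried through a rigid transform."""
        return CutPlan(
            [(name, T.apply(p), T.rotation @ n) for name, p, n in self.planes]
        )


def plan_femur_cuts(
    measures: CondylarMeasures, template: FemurCutTemplate | None = None
) -> CutPlan:
    """Scale the relative cut template to absolute mm planes.

    AP-referenced offsets are fractions of the condylar AP extent anchored
    at the posterior/distal corner of the condylar bounding box, so
    doubling AP doubles every AP-referenced offset.
    """
    if measures.ap_mm <= 0 or measures.ml_mm <= 0:
        raise ImplantError("measures must be positive")
    t = template or FemurCutTemplate()
    ap, ml = measures.ap_mm, measures.ml_mm
    (x0, y0, z0), (x1, y1, _) = measures.condylar_bounds
    xc = 0.5 * (x0 + x1)
    s2 = 1.0 / np.sqrt(2.0)
    planes = [
        ("anterior", (xc, y0 + t.anterior_frac * ap, z0), (0, -1, 0)),
        (
            "anterior_chamfer",
            (xc, y0 + t.anterior_chamfer_frac[0] * ap, z0 + t.anterior_chamfer_frac[1] * ap),
            (0, -s2, -s2),
        ),
        ("distal", (xc, y0, z0 + t.distal_frac * ap), (0, 0, -1)),
        (
            "posterior_chamfer",
            (xc, y0 + t.posterior_chamfer_frac[0] * ap, z0 + t.posterior_chamfer_frac[1] * ap),
            (0, s2, -s2),
        ),
        ("posterior", (xc, y0 + t.posterior_frac * ap, z0), (0, 1, 0)),
        ("medial", (xc - t.ml_trim_frac * ml, y0, z0), (1, 0, 0)),
        ("lateral", (xc + t.ml_trim_frac * ml, y0, z0), (-1, 0, 0)),
    ]
    return CutPlan(planes)


# ---------------------------------------------------------------------------
# implant components
# ---------------------------------------------------------------------------
@dataclass
class ImplantComponent:
    kind: str  # femur_component | tibia_plate
    mesh: trimesh.Trimesh  # full solid including pins
    provenance: dict
    outer_patch: trimesh.Trimesh | None = None  # articular surface (on prediction)
    inner_patch: trimesh.Trimesh | None = None  # bone-facing surface
    edge_loops: list = field(default_factory=list)  # (n, 3) mm loops on the bone margin
    profile: "TibiaProfile | None" = None
    pins: list = field(default_factory=list)


def clip_by_plan(mesh: trimesh.Trimesh, plan: CutPlan) -> trimesh.Trimesh:
    """Open surface patch retained after all plan half-space clips."""
    patch = mesh.copy()
    for name, p, n in plan.planes:
        patch = trimesh.intersections.slice_mesh_plane(patch, plane_normal=n, plane_origin=p)
        if len(patch.faces) == 0:
            raise ImplantError(f"degenerate cut plan: '{name}' plane empties the mesh")
    patch.merge_vertices(merge_tex=True, merge_norm=True)
    patch.update_faces(patch.nondegenerate_faces())
    patch.remove_unreferenced_vertices()
    return patch


def _loops_as_points(mesh: trimesh.Trimesh, resample_mm: float = 0.5) -> list[np.ndarray]:
    loops = []
    for loop in boundary_loops(mesh):
        pts = mesh.vertices[loop]
        loops.append(_resample_closed(pts, resample_mm))
    return loops


def _resample_closed(pts: np.ndarray, step: float) -> np.ndarray:
    closed = np.vstack([pts, pts[:1]])
    seg = np.linalg.norm(np.diff(closed, axis=0), axis=1)
    s = np.concatenate([[0], np.cumsum(seg)])
    total = s[-1]
    if total <= step:
        return pts
    t = np.arange(0, total, step)
    out = np.empty((len(t), pts.shape[1]))
    for d in range(pts.shape[1]):
        out[:, d] = np.interp(t, s, closed[:, d])
    return out


def design_femur_component(
    pred_mesh: trimesh.Trimesh,
    plan: CutPlan,
    shell_mm: float = 1.5,
    pin_radius_mm: float = 3.0,
    pin_length_mm: float = 10.0,
    source_id: str | None = None,
) -> ImplantComponent:
    """Solid femoral component: clipped articular shell + walls + two pins."""
    outer = clip_by_plan(pred_mesh, plan)
    normals = outer.vertex_normals  # outward (prediction is watertight/oriented)
    inner_verts = outer.vertices - shell_mm * normals
    inner = trimesh.Trimesh(inner_verts, outer.faces.copy(), process=False)

    nv = len(outer.vertices)
    verts = np.vstack([outer.vertices, inner_verts])
    faces = [outer.faces, inner.faces[:, ::-1] + nv]
    walls = []
    for loop in boundary_loops(outer):
        m = len(loop)
        for i in range(m):
            a, b = int(loop[i]), int(loop[(i + 1) % m])
            walls.append([a, b, b + nv])
            walls.append([a, b + nv, a + nv])
    faces.append(np.array(walls, dtype=int))
    body = trimesh.Trimesh(verts, np.vstack(faces), process=False)
    body.merge_vertices()
    trimesh.repair.fix_normals(body)

    # fixation pins on the bone-facing side, pointing proximally (+z)
    lo, hi = outer.bounds
    xc, yc = 0.5 * (lo[0] + hi[0]), 0.5 * (lo[1] + hi[1])
    pins = []
    for sx in (-1.0, 1.0):
        px = xc + sx * 0.25 * (hi[0] - lo[0])
        near = np.argmin((outer.vertices[:, 0] - px) ** 2 + (outer.vertices[:, 1] - yc) ** 2)
        anchor = inner_verts[near]
        pin = trimesh.creation.cylinder(radius=pin_radius_mm, height=pin_length_mm, sections=24)
        pin.apply_translation([anchor[0], anchor[1], anchor[2] + pin_length_mm / 2 - 1.0])
        pins.append(pin)
    full = trimesh.util.concatenate([body] + pins)
    return ImplantComponent(
        kind="femur_component",
        mesh=full,
        provenance={"plan": plan, "shell_mm": shell_mm, "source": source_id},
        outer_patch=outer,
        inner_patch=inner,
        edge_loops=_loops_as_points(outer),
        pins=pins,
    )


# ---------------------------------------------------------------------------
# tibia plate
# ---------------------------------------------------------------------------
@dataclass
class PlateSpec:
    section_offset_mm: float = 2.0  # below widest medial-condyle point
    thickness_mm: float = 5.0
    pin_radius_mm: float = 3.0
    pin_length_mm: float = 10.0
    bearing_recess_depth_mm: float = 2.0
    bearing_frac: float = 0.5  # recess size, fraction of profile extents
    notch_width_frac: float = 0.25  # posterior cut, fraction of ML extent
    notch_depth_frac: float = 0.10  # fraction of AP extent

    def __post_init__(self) -> None:
        if self.thickness_mm <= 0 or self.section_offset_mm < 0:
            raise ValueError("thickness must be > 0 and offset >= 0")


@dataclass
class OrientedPlane:
    point: np.ndarray
    normal: np.ndarray  # unit, pointing distally (away from the femur)


@dataclass
class TibiaProfile:
    """Closed section polygon in levelled (plateau-parallel) coordinates."""

    polygon: Polygon
    rotation: np.ndarray  # world -> levelled
    z_section: float  # levelled z of the section plane
    widest_point: np.ndarray  # levelled coords
    source_mesh: trimesh.Trimesh | None = None  # prediction the profile came from

    def carried_through(self, T) -> "TibiaProfile":
        """Section plane re-expressed in the frame reached by rigid ``T``."""
        R2 = self.rotation @ T.rotation.T
        z2 = self.z_section + float((self.rotation @ T.rotation.T @ T.translation)[2])
        return TibiaProfile(self.polygon, R2, z2, self.widest_point)


def tibia_plateau_plane(pred_mesh: trimesh.Trimesh, top_fraction: float = 0.12) -> OrientedPlane:
    """Least-squares plane through the proximal plateau region."""
    V = pred_mesh.vertices
    if len(V) == 0:
        raise ImplantError("empty mesh")
    z0, z1 = V[:, 2].min(), V[:, 2].max()
    sel = V[:, 2] >= z1 - top_fraction * (z1 - z0)
    pts = V[sel]
    if len(pts) < 10:
        raise ImplantError("too few plateau points for plane fit")
    A = np.column_stack([pts[:, 0], pts[:, 1], np.ones(len(pts))])
    coef, *_ = np.linalg.lstsq(A, pts[:, 2], rcond=None)
    a, b, _ = coef
    n = np.array([a, b, -1.0])  # distal orientation (negative z component)
    n /= np.linalg.norm(n)
    return OrientedPlane(pts.mean(axis=0), n)


def extract_tibia_profile(
    pred_mesh: trimesh.Trimesh,
    plane: OrientedPlane,
    offset_mm: float = 2.0,
    medial_sign: float = -1.0,
) -> TibiaProfile:
    """Section polygon ``offset_mm`` distal to the widest medial-condyle point.

    The mesh is levelled so the plateau plane is horizontal; the widest
    point on the medial half sets the section height; the largest closed
    intersection loop is returned in levelled plane coordinates.
    """
    up = -plane.normal  # proximal direction
    axis = np.cross(up, [0, 0, 1.0])
    na = np.linalg.norm(axis)
    if na < 1e-12:
        R = np.eye(3)
    else:
        ang = float(np.arccos(np.clip(up[2], -1, 1)))
        R = rotation_about_axis(axis / na, ang)
    V = pred_mesh.vertices @ R.T
    levelled = trimesh.Trimesh(V, pred_mesh.faces.copy(), process=False)
    # widest point of the medial condyle: extreme ML vertex on the medial
    # half of the proximal third
    z0, z1 = V[:, 2].min(), V[:, 2].max()
    prox = V[V[:, 2] >= z1 - (z1 - z0) / 3.0]
    cx = prox[:, 0].mean()
    medial = prox[np.sign(prox[:, 0] - cx) == np.sign(medial_sign)]
    if len(medial) == 0:
        raise ImplantError("no medial points found")
    widest = medial[np.argmax(np.abs(medial[:, 0] - cx))]
    z_sec = float(widest[2] - offset_mm)
    section = levelled.section(plane_origin=[0, 0, z_sec], plane_normal=[0, 0, 1])
    if section is None:
        raise ImplantError("no intersection at the section plane")
    # largest closed loop, kept in levelled xy coordinates
    loops = [np.asarray(e.discrete(section.vertices)) for e in section.entities]
    loops = [L for L in loops if len(L) >= 4]
    if not loops:
        raise ImplantError("no closed loop at the section plane")
    big = max(loops, key=lambda L: abs(Polygon(L[:, :2]).area))
    poly = Polygon(big[:, :2])
    if not poly.is_valid:
        poly = poly.buffer(0)
    return TibiaProfile(poly, R, z_sec, widest, source_mesh=pred_mesh)


def design_tibia_plate(
    profile: TibiaProfile, spec: PlateSpec | None = None, source_id: str | None = None
) -> ImplantComponent:
    """Extruded plate with posterior cut, bearing recess and fixation pin.

    Built in the levelled frame with the plate's distal face at z = 0 and
    proximal (bone/bearing) face at z = thickness.
    """
    spec = spec or PlateSpec()
    poly = profile.polygon
    if not poly.is_valid or poly.is_empty:
        raise ImplantError("self-intersecting or empty profile polygon")
    x0, y0, x1, y1 = poly.bounds
    ml, ap = x1 - x0, y1 - y0
    # posterior notch (posterior = -y side)
    notch = shapely_box(
        (x0 + x1) / 2 - spec.notch_width_frac * ml / 2,
        y0 - 1.0,
        (x0 + x1) / 2 + spec.notch_width_frac * ml / 2,
        y0 + spec.notch_depth_frac * ap,
    )
    cut = poly.difference(notch)
    if cut.geom_type != "Polygon":
        cut = max(cut.geoms, key=lambda g: g.area)
    # central bearing recess on the proximal face
    cx, cy = cut.centroid.x, cut.centroid.y
    recess = shapely_box(
        cx - spec.bearing_frac * ml / 2,
        cy - spec.bearing_frac * ap / 2,
        cx + spec.bearing_frac * ml / 2,
        cy + spec.bearing_frac * ap / 2,
    ).intersection(cut.buffer(-2.0))
    if recess.geom_type != "Polygon" or recess.is_empty:
        recess = None
    bodies = []
    ring = cut.difference(recess) if recess is not None else cut
    if ring.geom_type != "Polygon":
        ring = max(ring.geoms, key=lambda g: g.area)
    bodies.append(extrude_polygon_mesh(ring, spec.thickness_mm))
    if recess is not None:
        bodies.append(
            extrude_polygon_mesh(recess, spec.thickness_mm - spec.bearing_recess_depth_mm)
        )
    pin = trimesh.creation.cylinder(radius=spec.pin_radius_mm, height=spec.pin_length_mm, sections=24)
    pin.apply_translation([cx, cy, -spec.pin_length_mm / 2 + 0.5])
    mesh = trimesh.util.concatenate(bodies + [pin])
    return ImplantComponent(
        kind="tibia_plate",
        mesh=mesh,
        provenance={"spec": spec, "source": source_id},
        profile=profile,
        pins=[pin],
    )


# ---------------------------------------------------------------------------
# resection (ground-truth side of the fit comparison)
# ---------------------------------------------------------------------------
def resect_bone(gt_mesh: trimesh.Trimesh, plan_or_profile) -> dict:
    """Resected ground-truth geometry matching a component's construction.

    Femur (``CutPlan``): the ground-truth mesh clipped by the same plan;
    returns the patch and its boundary edge loops. Tibia
    (``TibiaProfile``): the equivalent section of the ground truth taken at
    the same levelled plane; returns the profile polygon.
    """
    if isinstance(plan_or_profile, CutPlan):
        patch = clip_by_plan(gt_mesh, plan_or_profile)
        return {"kind": "femur", "patch": patch, "edge_loops": _loops_as_points(patch)}
    if isinstance(plan_or_profile, TibiaProfile):
        p = plan_or_profile
        V = gt_mesh.vertices @ p.rotation.T
        levelled = trimesh.Trimesh(V, gt_mesh.faces.copy(), process=False)
        section = levelled.section(plane_origin=[0, 0, p.z_section], plane_normal=[0, 0, 1])
        if section is None:
            raise ImplantError("ground-truth mesh has no intersection at the section plane")
        loops = [np.asarray(e.discrete(section.vertices)) for e in section.entities]
        big = max(loops, key=lambda L: Polygon(L[:, :2]).area if len(L) >= 4 else 0.0)
        poly = Polygon(big[:, :2])
        if not poly.is_valid:
            poly = poly.buffer(0)
        return {"kind": "tibia", "profile": poly}
    raise ImplantError(f"unsupported resection input: {type(plan_or_profile)}")
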