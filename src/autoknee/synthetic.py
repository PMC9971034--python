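"""Parametric synthetic knee phantoms with full ground truth.

A single analytic template (two-lobed distal femur with shaft, flat-topped
proximal tibia with shaft, thin fibula distractor) is meshed once by
marching cubes and then deformed per subject by linear displacement-field
variation modes:

  mode 0 — global scale about the knee centre (dimensionless weight),
  mode 1 — medial/lateral spread of the condyles and plateau (mm),
  mode 2 — plateau/condyle slope, a z-displacement proportional to the
           medial–lateral coordinate (mm at the bone edge).

Because every subject is the template plus a linear combination of fixed
displacement fields (plus optional vertex jitter), all subjects share vertex
topology (correspondence by construction) and the population has a known,
exactly three-dimensional shape space — which makes statistical-shape-model
recovery testable against ground truth.

Canonical frame: x = medial–lateral, y = anterior–posterior, z = slice axis
increasing tibia -> femur; a left knee. Right-side subjects are emulated by
mirroring the voxelised volume only; ground-truth meshes are always stored
in the canonical left frame.
"""

from __future__ import annotations

import functools
from dataclasses import dataclass, field

import numpy as np
import trimesh
from skimage.draw import polygon as draw_polygon
from skimage.measure import marching_cubes

from .ct_io import CtVolume

LABELS = ("FIBULA_TIBIA", "KNEE", "FEMUR", "OTHER")

# stored-value intensities (HU + 1024)
AIR_I = 24.0
TISSUE_I = 1064.0
BONE_I = 2224.0

# template layout constants (mm, knee-local x/y; absolute z)
_KNEE_CENTER_Z = 46.0
_FIBULA_TOP_Z = 30.1
_CONDYLE_TOP_Z = 68.3
_TIBIA_TOP_Z = 45.6
_FEMUR_TIP_Z = 46.3
_JOINT_Z = 0.5 * (_TIBIA_TOP_Z + _FEMUR_TIP_Z)


class SyntheticError(RuntimeError):
    pass


@dataclass
class PopulationParams:
    """Cohort generation parameters.

    ``mode_sds`` are the standard deviations of the three variation modes
    (scale: dimensionless; spread: mm; slope: mm at the bone edge);
    ``noise_sd_mm`` is iid per-vertex jitter.
    """

    n_subjects: int = 10
    mode_sds: tuple[float, float, float] = (0.05, 2.0, 1.2)
    noise_sd_mm: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 2:
            raise ValueError("n_subjects must be >= 2")
        if any(s < 0 for s in self.mode_sds) or self.noise_sd_mm < 0:
            raise ValueError("standard deviations must be >= 0")


@dataclass
class SubjectPhantom:
    subject_id: int
    femur_mesh: trimesh.Trimesh
    tibia_mesh: trimesh.Trimesh
    fibula_mesh: trimesh.Trimesh
    mode_weights: np.ndarray
    side: str  # left | right
    metadata: dict = field(default_factory=dict)

    @property
    def z_joint(self) -> float:
        return self.metadata["z_joint"]


@dataclass
class GroundTruth:
    """Everything the pipeline could be asked to predict, per volume."""

    masks: dict  # bone -> (n_slices, H, W) bool, canonical left frame
    labels: list  # per-slice class label
    boxes: dict  # slice idx -> (centre_row, centre_col, height, width), left frame
    meshes: dict  # bone -> trimesh (canonical left frame)
    mode_weights: np.ndarray
    side: str
    z_joint: float
    knee_band: tuple  # (first, last) slice indices of the true knee region, half-open
    pixel_mm: float
    slice_mm: float
    metadata: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# template construction
# ---------------------------------------------------------------------------
def _femur_field(x, y, z):
    lobe_p = 1 - ((x - 17) / 17) ** 2 - ((y - 4) / 20) ** 2 - ((z - 57.3) / 11) ** 2
    lobe_m = 1 - ((x + 17) / 17) ** 2 - ((y - 4) / 20) ** 2 - ((z - 57.3) / 11) ** 2
    shaft = 1 - (x / 13) ** 2 - ((y - 4) / 13) ** 2 - ((z - 73.3) / 11) ** 8
    return np.maximum(np.maximum(lobe_p, lobe_m), shaft)


def _tibia_field(x, y, z):
    plateau = 1 - (x / 33) ** 2 - (y / 23) ** 2 - ((z - 38.6) / 7.0) ** 4
    shaft = 1 - (x / 12.5) ** 2 - ((y - 2) / 12.5) ** 2 - ((z - 22.1) / 16) ** 8
    # anterior tuberosity: breaks the plateau's front/back near-symmetry
    tuber = 1 - ((x - 2) / 7.0) ** 2 - ((y - 18) / 7.0) ** 2 - ((z - 28.0) / 9.0) ** 4
    return np.maximum(np.maximum(plateau, shaft), tuber)


def _fibula_field(x, y, z):
    return 1 - ((x - 30) / 5.5) ** 2 - ((y - 8) / 5.5) ** 2 - ((z - 18.1) / 12) ** 8


_BONE_FIELDS = {
    "femur": (_femur_field, (-37, 37), (-18, 26), (44, 87)),
    "tibia": (_tibia_field, (-36, 36), (-26, 28), (4, 49)),
    "fibula": (_fibula_field, (22, 38), (0, 16), (4, 33)),
}


def _mesh_from_field(fieldfn, xb, yb, zb, pitch: float) -> trimesh.Trimesh:
    xs = np.arange(xb[0] - 2 * pitch, xb[1] + 2 * pitch, pitch)
    ys = np.arange(yb[0] - 2 * pitch, yb[1] + 2 * pitch, pitch)
    zs = np.arange(zb[0] - 2 * pitch, zb[1] + 2 * pitch, pitch)
    X, Y, Z = np.meshgrid(xs, ys, zs, indexing="ij")
    F = fieldfn(X, Y, Z)
    verts, faces, _, _ = marching_cubes(F, level=1e-6, spacing=(pitch, pitch, pitch))
    verts += np.array([xs[0], ys[0], zs[0]])
    mesh = trimesh.Trimesh(verts, faces, process=False)
    mesh.merge_vertices()
    mesh.update_faces(mesh.nondegenerate_faces())
    mesh.remove_unreferenced_vertices()
    trimesh.repair.fix_normals(mesh)
    if not mesh.is_watertight:
        raise SyntheticError("degenerate phantom: template mesh not watertight")
    return mesh


@functools.lru_cache(maxsize=2)
def template_meshes(pitch: float = 1.25) -> dict:
    """The shared bone templates (knee-local x/y, absolute z), meshed once."""
    out = {}
    for bone, (fn, xb, yb, zb) in _BONE_FIELDS.items():
        mesh = _mesh_from_field(fn, xb, yb, zb, pitch)
        trimesh.smoothing.filter_laplacian(mesh, iterations=3, volume_constraint=True)
        out[bone] = mesh
    return out


def _mode_fields(bone: str, verts: np.ndarray) -> np.ndarray:
    """Per-mode displacement fields evaluated at template vertices.

    Returns (3, n_vertices, 3). Linear in the mode weights by construction.
    """
    x, y, z = verts[:, 0], verts[:, 1], verts[:, 2]
    D = np.zeros((3, len(verts), 3))
    # mode 0: global scale about the knee centre
    D[0] = verts - np.array([0.0, 0.0, _KNEE_CENTER_Z])
    # mode 1: medial/lateral spread, localised near the joint
    if bone == "femur":
        g = np.exp(-(((z - 57.0) / 14.0) ** 2))
    elif bone == "tibia":
        g = np.exp(-(((z - 40.0) / 8.0) ** 2))
    else:  # fibula shifts rigidly half a unit
        g = np.full_like(z, 0.5)
    D[1, :, 0] = np.tanh(x / 12.0) * g
    # mode 2: plateau / condyle slope (z displacement ~ ML coordinate)
    if bone == "tibia":
        s = np.exp(-(((z - 43.0) / 5.0) ** 2))
        D[2, :, 2] = (x / 33.0) * s
    elif bone == "femur":
        s = np.exp(-(((z - 52.0) / 8.0) ** 2))
        D[2, :, 2] = 0.5 * (x / 34.0) * s
    return D


@functools.lru_cache(maxsize=2)
def _cached_mode_fields(pitch: float = 1.25) -> dict:
    t = template_meshes(pitch)
    return {bone: _mode_fields(bone, t[bone].vertices) for bone in t}


# ---------------------------------------------------------------------------
# population generation
# ---------------------------------------------------------------------------
def generate_bone_population(params: PopulationParams, pitch: float = 1.25) -> list[SubjectPhantom]:
    """Draw a reproducible phantom cohort from the 3-mode shape space."""
    rng = np.random.default_rng(params.seed)
    templates = template_meshes(pitch)
    fields = _cached_mode_fields(pitch)
    subjects = []
    for i in range(params.n_subjects):
        w = rng.normal(0.0, params.mode_sds, size=3)
        # sex follows overall size (keeps the marginal mode distribution
        # exactly N(0, sd) while making sex a size-correlated covariate)
        sex = "M" if w[0] >= 0 else "F"
        if 1.0 + w[0] <= 0.05:
            raise SyntheticError("degenerate phantom: non-positive global scale")
        side = "left" if rng.random() < 0.5 else "right"
        meshes = {}
        for bone, tmesh in templates.items():
            V = tmesh.vertices + np.tensordot(w, fields[bone], axes=1)
            if params.noise_sd_mm > 0:
                V = V + rng.normal(0.0, params.noise_sd_mm, size=V.shape)
            meshes[bone] = trimesh.Trimesh(V, tmesh.faces.copy(), process=False)
        sz = 1.0 + w[0]
        meta = {
            "sex": sex,
            "age": float(rng.uniform(45, 85)),
            "height_cm": float(170 + 80 * w[0] + rng.normal(0, 4)),
            "z_joint": _KNEE_CENTER_Z + (_JOINT_Z - _KNEE_CENTER_Z) * sz,
            "z_fibula_top": _KNEE_CENTER_Z + (_FIBULA_TOP_Z - _KNEE_CENTER_Z) * sz,
            "z_condyle_top": _KNEE_CENTER_Z + (_CONDYLE_TOP_Z - _KNEE_CENTER_Z) * sz,
            "pitch": pitch,
        }
        subjects.append(
            SubjectPhantom(i, meshes["femur"], meshes["tibia"], meshes["fibula"], w, side, meta)
        )
    return subjects


# ---------------------------------------------------------------------------
# voxelisation
# ---------------------------------------------------------------------------
def _rasterize_sections(
    mesh: trimesh.Trimesh, n_slices: int, slice_mm: float, pixel_mm: float, shape: tuple[int, int],
    offset_xy: np.ndarray,
) -> np.ndarray:
    """Per-slice binary masks of a mesh via planar cross-sections."""
    masks = np.zeros((n_slices,) + shape, dtype=bool)
    heights = np.arange(n_slices) * slice_mm
    sections = mesh.section_multiplane(
        plane_origin=[0, 0, 0], plane_normal=[0, 0, 1], heights=heights
    )
    from shapely.geometry import Polygon as ShPolygon

    for k, sec in enumerate(sections):
        if sec is None:
            continue
        polys = [p for p in sec.polygons_closed if p is not None and not p.is_empty]
        # even-odd nesting: loops inside an odd number of others are holes
        order = sorted(range(len(polys)), key=lambda i: -abs(polys[i].area))
        shp = [ShPolygon(p.exterior) for p in polys]
        for i in order:
            depth = sum(
                1 for j in range(len(polys))
                if j != i and shp[j].contains(shp[i].representative_point())
            )
            ext = np.asarray(polys[i].exterior.coords)
            rr, cc = draw_polygon(
                (ext[:, 1] + offset_xy[1]) / pixel_mm,
                (ext[:, 0] + offset_xy[0]) / pixel_mm,
                shape=shape,
            )
            masks[k, rr, cc] = depth % 2 == 0
    return masks


def voxelize_subject(
    s: SubjectPhantom,
    pixel_mm: float = 0.8,
    slice_mm: float = 1.0,
    noise_sd: float = 20.0,
    seed: int = 0,
    img_px: int = 200,
    n_slices: int = 92,
    knee_center_xy: tuple[float, float] = (64.0, 80.0),
    center_jitter_mm: float = 0.0,
) -> tuple[CtVolume, GroundTruth]:
    """Voxelise one phantom into a CT-like volume plus full ground truth.

    Bone voxels are painted at high intensity, a soft-tissue ellipse at
    medium, air low; Gaussian noise is added on top. Right-side subjects get
    a horizontally mirrored volume (masks and boxes stay in the canonical
    left frame, matching the flip-then-detect pipeline convention).
    """
    if pixel_mm <= 0 or slice_mm <= 0:
        raise ValueError("spacings must be positive")
    rng = np.random.default_rng(seed)
    shape = (img_px, img_px)
    jitter = rng.uniform(-center_jitter_mm, center_jitter_mm, size=2) if center_jitter_mm else np.zeros(2)
    offset = np.array(knee_center_xy) + jitter  # (x, y) of the knee centre

    meshes = {"femur": s.femur_mesh, "tibia": s.tibia_mesh, "fibula": s.fibula_mesh}
    fov = img_px * pixel_mm
    for bone, m in meshes.items():
        lo = m.bounds[0][:2] + offset
        hi = m.bounds[1][:2] + offset
        if (lo < 0).any() or (hi > fov).any():
            raise SyntheticError(f"FOV overflow: {bone} extends outside the field of view")

    masks = {
        bone: _rasterize_sections(m, n_slices, slice_mm, pixel_mm, shape, offset)
        for bone, m in meshes.items()
    }

    # soft tissue on slices within the overall bone z-range
    z_lo = min(m.bounds[0][2] for m in meshes.values())
    z_hi = max(m.bounds[1][2] for m in meshes.values())
    rr0, cc0 = np.mgrid[0:img_px, 0:img_px]
    exy = ((cc0 * pixel_mm - offset[0]) / 55.0) ** 2 + ((rr0 * pixel_mm - offset[1]) / 45.0) ** 2
    tissue2d = exy <= 1.0

    vol = np.full((n_slices,) + shape, AIR_I)
    labels = []
    for k in range(n_slices):
        z = k * slice_mm
        has_tissue = z_lo <= z <= z_hi
        if has_tissue:
            vol[k][tissue2d] = TISSUE_I
        for bone in meshes:
            vol[k][masks[bone][k]] = BONE_I
        if not has_tissue:
            labels.append("OTHER")
        elif masks["fibula"][k].any() or z < s.metadata["z_fibula_top"]:
            labels.append("FIBULA_TIBIA")
        elif z <= s.metadata["z_condyle_top"]:
            labels.append("KNEE")
        else:
            labels.append("FEMUR")

    if noise_sd > 0:
        vol = vol + rng.normal(0.0, noise_sd, size=vol.shape)
    vol = np.clip(vol, 0, 65535)

    # knee bounding boxes (canonical left frame)
    knee_idx = [k for k, lab in enumerate(labels) if lab == "KNEE"]
    boxes = {}
    fallback = None
    if knee_idx:
        union_all = np.zeros(shape, dtype=bool)
        for k in knee_idx:
            union_all |= masks["femur"][k] | masks["tibia"][k]
        if union_all.any():
            fallback = _bbox_of(union_all)
    for k in knee_idx:
        u = masks["femur"][k] | masks["tibia"][k]
        boxes[k] = _bbox_of(u) if u.any() else fallback

    ct = CtVolume(
        vol[:, :, ::-1].copy() if s.side == "right" else vol,
        (pixel_mm, pixel_mm),
        slice_mm,
    )
    band = (min(knee_idx), max(knee_idx) + 1) if knee_idx else (0, 0)
    gt = GroundTruth(
        masks=masks,
        labels=labels,
        boxes=boxes,
        meshes={
            bone: trimesh.Trimesh(
                m.vertices + np.array([offset[0], offset[1], 0.0]), m.faces.copy(), process=False
            )
            for bone, m in meshes.items()
        },
        mode_weights=s.mode_weights.copy(),
        side=s.side,
        z_joint=s.metadata["z_joint"],
        knee_band=band,
        pixel_mm=pixel_mm,
        slice_mm=slice_mm,
        metadata=dict(s.metadata, subject_id=s.subject_id, offset_xy=offset.tolist()),
    )
    return ct, gt


def _bbox_of(mask: np.ndarray) -> tuple[float, float, int, int]:
    rows = np.flatnonzero(mask.any(axis=1))
    cols = np.flatnonzero(mask.any(axis=0))
    h = int(rows[-1] - rows[0] + 1)
    w = int(cols[-1] - cols[0] + 1)
    return (float(rows[0] + rows[-1]) / 2.0, float(cols[0] + cols[-1]) / 2.0, h, w)


# ---------------------------------------------------------------------------
# training fixtures
# ---------------------------------------------------------------------------
def make_training_fixtures(
    pop: list[SubjectPhantom],
    split: tuple[float, float] = (0.7, 0.3),
    seed: int = 0,
    pixel_mm: float = 0.8,
    slice_mm: float = 1.0,
    noise_sd: float = 20.0,
    roi_size: int = 160,
) -> dict:
    """Labelled datasets for the classifier, ROI detector and segmenters.

    Subjects (never individual slices) are split disjointly into train and
    validation. All crops are in the left-knee frame: right-side subjects'
    mirrored volumes are flipped back before cropping, so left and
    (mirrored) right knees both contribute.
    """
    if not pop:
        raise ValueError("population is empty")
    if abs(sum(split) - 1.0) > 1e-9:
        raise ValueError("split fractions must sum to 1")
    rng = np.random.default_rng(seed)
    ids = [s.subject_id for s in pop]
    perm = rng.permutation(len(ids))
    n_train = max(1, int(round(split[0] * len(ids))))
    if n_train >= len(ids):
        n_train = len(ids) - 1
    train_ids = {ids[i] for i in perm[:n_train]}
    val_ids = {ids[i] for i in perm[n_train:]}

    data = {
        "classifier": [],  # (image, label, subject_id)
        "detector": [],  # (image, (centre_row, centre_col), (h, w), subject_id)
        "segmentation": {"femur": [], "tibia": []},  # (crop, mask, subject_id)
        "train_subjects": sorted(train_ids),
        "val_subjects": sorted(val_ids),
        "ground_truth": {},
        "volumes": {},
    }
    from .ct_io import flip_slice_horizontal
    from .roi import crop_window, median_roi_box

    for s in pop:
        ct, gt = voxelize_subject(
            s, pixel_mm=pixel_mm, slice_mm=slice_mm, noise_sd=noise_sd,
            seed=seed + 1000 + s.subject_id, center_jitter_mm=4.0,
        )
        data["ground_truth"][s.subject_id] = gt
        data["volumes"][s.subject_id] = ct
        # canonical (left-frame) slices: flip mirrored right-side volumes back
        if s.side == "right":
            canon = np.stack([flip_slice_horizontal(sl) for sl in ct.slices])
        else:
            canon = ct.slices
        for k, lab in enumerate(gt.labels):
            data["classifier"].append((canon[k], lab, s.subject_id))
        centres = []
        for k, box in gt.boxes.items():
            cr, cc, h, w = box
            data["detector"].append((canon[k], (cr, cc), (h, w), s.subject_id))
            centres.append((cr, cc))
        if not centres:
            continue
        roi = median_roi_box(centres, roi_size, image_shape=ct.shape)
        r0, r1, c0, c1 = crop_window(roi)
        for k in gt.boxes:
            crop = canon[k, r0:r1, c0:c1]
            for bone in ("femur", "tibia"):
                m = gt.masks[bone][k, r0:r1, c0:c1]
                data["segmentation"][bone].append((crop, m, s.subject_id))
    return data
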