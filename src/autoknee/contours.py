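"""Area profiles, tibia–femur transition detection, and 3-D contour stacks.

The transition slice — where the femoral condyles end and the tibial
plateau begins — is found from the per-slice segmented-area curves of the
two bones: between the positions of each curve's maximum, it is the first
slice (tibia -> femur order) at which the femur curve meets or exceeds the
tibia curve. Contours up to the transition form the tibia stack, contours
after it the femur stack; both stacks are trimmed at their far ends where
end-of-region segmentation noise concentrates, and positioned in
millimetre space using pixel/slice spacing.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .roi import RoiSpec, crop_window
from .segment import mask_area_mm2


class ContourError(RuntimeError):
    pass


@dataclass
class AreaProfile:
    """Per-slice segmented areas (mm^2) over the knee range, both bones."""

    femur: np.ndarray
    tibia: np.ndarray
    first_slice: int = 0  # global index of element 0

    def __post_init__(self) -> None:
        self.femur = np.asarray(self.femur, dtype=float)
        self.tibia = np.asarray(self.tibia, dtype=float)
        if len(self.femur) != len(self.tibia):
            raise ValueError("femur/tibia profiles must be the same length")
        if (self.femur < 0).any() or (self.tibia < 0).any():
            raise ValueError("areas must be non-negative")


@dataclass
class ContourStack:
    """Per-slice bone outlines positioned in 3-D millimetre space."""

    bone: str
    zs: np.ndarray  # (n,) strictly increasing, mm
    polylines: list  # list of (m_i, 2) arrays, columns (x, y) mm
    slice_spacing_mm: float = 1.0

    def __post_init__(self) -> None:
        self.zs = np.asarray(self.zs, dtype=float)
        if len(self.zs) != len(self.polylines):
            raise ValueError("zs/polylines length mismatch")
        if len(self.zs) > 1 and not (np.diff(self.zs) > 0).all():
            raise ValueError("z must be strictly increasing")
        if any(len(p) == 0 for p in self.polylines):
            raise ValueError("empty polyline in stack")

    def points(self) -> np.ndarray:
        """All contour points as one (N, 3) array."""
        out = []
        for z, poly in zip(self.zs, self.polylines):
            out.append(np.column_stack([poly, np.full(len(poly), z)]))
        return np.vstack(out)


def area_profiles(femur_masks, tibia_masks, pixel_spacing, first_slice: int = 0) -> AreaProfile:
    """Segmented area per slice for each bone (aligned mask lists)."""
    if len(femur_masks) != len(tibia_masks):
        raise ContourError("mask lists must be aligned by slice")
    f = [mask_area_mm2(m, pixel_spacing) for m in femur_masks]
    t = [mask_area_mm2(m, pixel_spacing) for m in tibia_masks]
    return AreaProfile(np.array(f), np.array(t), first_slice)


def find_transition_slice(p: AreaProfile) -> int:
    """Transition slice index (global) from the area-curve intersection.

    With indices normalised tibia -> femur, scans [argmax_tibia,
    argmax_femur] for the first k with femur_area(k) >= tibia_area(k); a tie
    at equality resolves to that k.
    """
    if p.tibia.max() <= 0 or p.femur.max() <= 0:
        raise ContourError("inconsistent profile: both curves need a positive maximum")
    at = int(np.argmax(p.tibia))
    af = int(np.argmax(p.femur))
    if not at < af:
        raise ContourError("inconsistent profile: tibia argmax must precede femur argmax")
    for k in range(at, af + 1):
        if p.femur[k] >= p.tibia[k]:
            return k + p.first_slice
    raise ContourError("no transition found: curves never intersect between their maxima")


def split_and_build_stacks(
    femur_contours: dict,
    tibia_contours: dict,
    transition: int,
    knee_range: tuple[int, int],
    slice_spacing_mm: float,
    pixel_spacing: tuple[float, float],
    roi: RoiSpec,
    trim: int = 5,
) -> tuple[ContourStack, ContourStack]:
    """Assemble trimmed tibia and femur contour stacks in mm.

    ``*_contours`` map global slice index -> list of :class:`Contour` in ROI
    pixel coordinates. Tibia keeps slices [knee_start + trim, transition),
    femur keeps [transition, knee_end - trim): the trim is applied at the
    ends away from the joint line, where segmentation noise concentrates.
    Slices without a surviving contour are skipped; the largest contour per
    slice is used.
    """
    if trim < 0:
        raise ValueError("trim must be >= 0")
    first, last = knee_range
    if not first <= transition < last:
        raise ContourError("transition outside knee range")
    r0, _, c0, _ = crop_window(roi)
    sr, sc = pixel_spacing

    def build(contours: dict, lo: int, hi: int, bone: str) -> ContourStack:
        if hi - lo <= 0:
            raise ContourError(f"stack too short: trim consumes the {bone} stack")
        zs, polys = [], []
        for k in range(lo, hi):
            cands = contours.get(k, [])
            if not cands:
                continue
            best = max(cands, key=lambda c: c.length_px)
            pts = np.asarray(best.points, dtype=float)
            xy = np.column_stack([(c0 + pts[:, 1]) * sc, (r0 + pts[:, 0]) * sr])
            zs.append(k * slice_spacing_mm)
            polys.append(xy)
        if not polys:
            raise ContourError(f"stack too short: no {bone} contours survive")
        return ContourStack(bone, np.array(zs), polys, slice_spacing_mm)

    tibia = build(tibia_contours, first + trim, transition, "tibia")
    femur = build(femur_contours, transition, last - trim, "femur")
    return femur, tibia
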