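"""Bone segmentation, oracle masks, contour tracing and area measures."""

import numpy as np
import pytest

from autoknee.roi import RoiSpec
from autoknee.segment import (
    SegmentationError,
    extract_bone_contours,
    mask_area_mm2,
    oracle_segmenter,
    segment_knee_slices,
    train_bone_segmenter,
)


# -- area -------------------------------------------------------------------
def test_mask_area_arithmetic():
    m = np.zeros((20, 20), dtype=bool)
    m[:10, :10] = True
    assert mask_area_mm2(m, (0.8, 0.8)) == pytest.approx(64.0)
    assert mask_area_mm2(np.zeros((5, 5)), (0.8, 0.8)) == 0.0
    assert mask_area_mm2(m[:, ::-1], (0.8, 0.8)) == mask_area_mm2(m, (0.8, 0.8))


# -- contours ---------------------------------------------------------------
def test_square_contour_perimeter():
    m = np.zeros((30, 30), dtype=bool)
    m[10:20, 10:20] = True
    cs = extract_bone_contours(m, min_length_px=10)
    assert len(cs) == 1 and cs[0].closed
    assert cs[0].length_px == pytest.approx(36.0, abs=4.0)


def test_short_contours_filtered():
    m = np.zeros((40, 40), dtype=bool)
    m[5:25, 5:25] = True
    m[32:34, 32:34] = True  # tiny blob, perimeter < threshold
    cs = extract_bone_contours(m, min_length_px=20)
    assert len(cs) == 1


def test_empty_mask_gives_empty_list():
    assert extract_bone_contours(np.zeros((10, 10), dtype=bool), 5) == []


def test_hole_contours_discarded():
    m = np.zeros((40, 40), dtype=bool)
    m[5:35, 5:35] = True
    m[15:25, 15:25] = False  # hole
    cs = extract_bone_contours(m, min_length_px=5)
    assert len(cs) == 1  # outer boundary only


def test_contours_lie_on_mask_boundary(rng):
    m = rng.random((60, 60)) > 0.8
    from scipy import ndimage

    m = ndimage.binary_closing(ndimage.binary_opening(m))
    boundary = m & ~ndimage.binary_erosion(m)
    by, bx = np.nonzero(boundary)
    if len(by) == 0:
        pytest.skip("degenerate random mask")
    bpts = np.column_stack([by, bx])
    for c in extract_bone_contours(m, min_length_px=4):
        d = np.sqrt(((c.points[:, None, :] - bpts[None]) ** 2).sum(-1)).min(axis=1)
        assert (d <= 1.5).all()


def test_raising_min_length_never_increases_count(rng):
    m = rng.random((50, 50)) > 0.75
    counts = [len(extract_bone_contours(m, L)) for L in (0, 5, 10, 20, 40)]
    assert all(a >= b for a, b in zip(counts, counts[1:]))


# -- oracle -----------------------------------------------------------------
def test_oracle_mask_is_exact(phantom):
    _, _, gt = phantom
    k = (gt.knee_band[0] + gt.knee_band[1]) // 2
    m = oracle_segmenter(gt, k, "tibia")
    np.testing.assert_array_equal(m.grid, gt.masks["tibia"][k])
    roi = RoiSpec((100, 100), 160, (200, 200))
    cropped = oracle_segmenter(gt, k, "tibia", roi)
    assert cropped.grid.shape == (160, 160)
    # femur is absent below the joint
    low = gt.knee_band[0] + 1
    assert not oracle_segmenter(gt, low, "femur").grid.any()


def test_oracle_requires_ground_truth():
    with pytest.raises(SegmentationError):
        oracle_segmenter(None, 0, "femur")


# -- learned segmenters -----------------------------------------------------
def test_shape_mismatch_rejected(trained):
    _, fixtures = trained
    bad = dict(fixtures)
    img, m, sid = fixtures["segmentation"]["femur"][0]
    bad["segmentation"] = {"femur": [(img, m[:-1], sid)], "tibia": fixtures["segmentation"]["tibia"]}
    with pytest.raises(SegmentationError, match="mismatch"):
        train_bone_segmenter("femur", bad)


def test_all_empty_masks_rejected(trained):
    _, fixtures = trained
    img, m, sid = fixtures["segmentation"]["femur"][0]
    bad = dict(fixtures)
    bad["segmentation"] = {"femur": [(img, np.zeros_like(m), sid)] * 4,
                           "tibia": fixtures["segmentation"]["tibia"]}
    with pytest.raises(SegmentationError, match="no positive pixels"):
        train_bone_segmenter("femur", bad)


def test_heldout_dice_and_binary_output(trained, phantom):
    models, _ = trained
    assert models.seg_femur.val_dice >= 0.90
    assert models.seg_tibia.val_dice >= 0.90
    _, ct, gt = phantom
    canon = ct.slices[:, :, ::-1] if gt.side == "right" else ct.slices
    ks = sorted(gt.boxes)[:6]
    from autoknee.roi import crop_window, median_roi_box

    roi = median_roi_box([gt.boxes[k][:2] for k in sorted(gt.boxes)], 160, ct.shape)
    r0, r1, c0, c1 = crop_window(roi)
    crops = [canon[k, r0:r1, c0:c1] for k in ks]
    masks = segment_knee_slices(models.seg_tibia, crops, ks)
    inter = union = 0
    for m, k in zip(masks, ks):
        assert set(np.unique(m.grid)) <= {False, True}
        ref = gt.masks["tibia"][k, r0:r1, c0:c1]
        inter += 2 * (m.grid & ref).sum()
        union += m.grid.sum() + ref.sum()
    assert inter / union >= 0.90


def test_soft_tissue_only_crop_is_near_empty(trained):
    models, _ = trained
    from autoknee.synthetic import AIR_I, TISSUE_I

    img = np.full((160, 160), AIR_I)
    yy, xx = np.mgrid[0:160, 0:160]
    img[((yy - 80) / 70.0) ** 2 + ((xx - 80) / 60.0) ** 2 <= 1] = TISSUE_I
    img += np.random.default_rng(1).normal(0, 20, img.shape)
    mask = segment_knee_slices(models.seg_femur, [img], [0])[0]
    assert mask.grid.mean() <= 0.01
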