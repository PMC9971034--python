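"""Per-bone binary segmentation of knee crops and contour extraction.

Separate models are trained for femur and tibia (a single model for both
loses geometric accuracy near the joint). Each model couples a slice gate
(does this crop contain the bone at all? — decided from the pooled crop,
which sees the condyle-vs-plateau shape context) with a per-pixel
classifier on multi-scale local intensity features; the per-pixel score is
thresholded at 0.5. An oracle segmenter returning ground-truth masks lets
the downstream contour/shape-model/implant stages be tested independently
of learned-model quality.
"""

from __future__ import annotations

import pickle
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import ndimage
from shapely.geometry import LinearRing, Point
from skimage.measure import find_contours
from sklearn.neural_network import MLPClassifier

from .classify import pool_features

_SCALE = 2500.0


class SegmentationError(RuntimeError):
    pass


@dataclass
class BinaryMask:
    grid: np.ndarray  # {0,1}, crop-sized
    bone: str  # femur | tibia
    slice_index: int

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid).astype(bool)


@dataclass
class Contour:
    """Ordered polyline of sub-pixel (row, col) points."""

    points: np.ndarray  # (n, 2)
    closed: bool

    @property
    def length_px(self) -> float:
        return float(np.sum(np.linalg.norm(np.diff(self.points, axis=0), axis=1)))


def _pixel_features(img: np.ndarray) -> np.ndarray:
    """(H*W, 5) per-pixel feature rows: intensity + 3 Gaussian scales + |grad|."""
    img = np.asarray(img, dtype=float)
    g2 = ndimage.gaussian_filter(img, 2)
    g4 = ndimage.gaussian_filter(img, 4)
    g8 = ndimage.gaussian_filter(img, 8)
    gm = ndimage.gaussian_gradient_magnitude(img, 2)
    stack = np.stack([img, g2, g4, g8, gm], axis=-1) / _SCALE
    return stack.reshape(-1, 5)


class BoneSegmenter:
    """Gate x per-pixel model for one bone; scores thresholded at 0.5."""

    def __init__(self, bone: str, seed: int = 0, hidden_px=(16,), hidden_gate=(32,),
                 max_iter: int = 250):
        self.bone = bone
        self.crop_shape: tuple[int, int] | None = None
        self.gate = MLPClassifier(hidden_layer_sizes=hidden_gate, max_iter=max_iter,
                                  random_state=seed, learning_rate_init=3e-3)
        self.pixel = MLPClassifier(hidden_layer_sizes=hidden_px, max_iter=max_iter,
                                   random_state=seed + 1, learning_rate_init=3e-3)
        self.val_dice: float | None = None

    def fit(self, pairs, seed: int = 0, max_px_per_slice: int = 600) -> "BoneSegmenter":
        rng = np.random.default_rng(seed)
        self.crop_shape = np.asarray(pairs[0][0]).shape
        gate_X, gate_y = [], []
        px_X, px_y = [], []
        for img, mask in pairs:
            mask = np.asarray(mask).astype(bool)
            gate_X.append(pool_features(img))
            gate_y.append(int(mask.any()))
            if not mask.any():
                continue
            feats = _pixel_features(img)
            flat = mask.ravel()
            pos = np.flatnonzero(flat)
            neg = np.flatnonzero(~flat)
            n = min(max_px_per_slice // 2, len(pos))
            take_pos = rng.choice(pos, size=n, replace=False)
            take_neg = rng.choice(neg, size=min(n, len(neg)), replace=False)
            idx = np.concatenate([take_pos, take_neg])
            px_X.append(feats[idx])
            px_y.append(flat[idx])
        if not px_X:
            raise SegmentationError("no positive pixels in training masks")
        self.gate.fit(np.stack(gate_X), np.array(gate_y))
        self.pixel.fit(np.vstack(px_X), np.concatenate(px_y).astype(int))
        return self

    def score_map(self, img: np.ndarray) -> np.ndarray:
        """Per-pixel probability of bone (gate probability x pixel probability)."""
        if self.crop_shape is not None and np.asarray(img).shape != tuple(self.crop_shape):
            raise SegmentationError(
                f"crop size {np.asarray(img).shape} does not match training size {self.crop_shape}"
            )
        g = float(self.gate.predict_proba([pool_features(img)])[0, 1]) if len(
            self.gate.classes_) > 1 else float(self.gate.classes_[0])
        feats = _pixel_features(img)
        if len(self.pixel.classes_) > 1:
            p = self.pixel.predict_proba(feats)[:, list(self.pixel.classes_).index(1)]
        else:
            p = np.full(len(feats), float(self.pixel.classes_[0]))
        return (g * p).reshape(np.asarray(img).shape)

    def save(self, path: str | Path) -> None:
        Path(path).write_bytes(pickle.dumps(self))

    @classmethod
    def load(cls, path: str | Path) -> "BoneSegmenter":
        return pickle.loads(Path(path).read_bytes())


def train_bone_segmenter(
    bone: str, dataset: dict, seed: int = 0, hidden_px=(16,), hidden_gate=(32,),
    max_iter: int = 250,
) -> BoneSegmenter:
    """Train one bone's segmenter on `(crop, mask, subject_id)` fixtures.

    Validation Dice (pooled over held-out subjects' positive slices) is
    stored on the returned model.
    """
    rows = dataset["segmentation"][bone]
    for img, mask, _sid in rows:
        if np.asarray(img).shape != np.asarray(mask).shape:
            raise SegmentationError("image/mask shape mismatch")
    train_ids = set(dataset["train_subjects"])
    val_ids = set(dataset["val_subjects"])
    train = [(im, m) for im, m, sid in rows if sid in train_ids]
    seg = BoneSegmenter(bone, seed=seed, hidden_px=hidden_px, hidden_gate=hidden_gate,
                        max_iter=max_iter).fit(train, seed=seed)
    val = [(im, np.asarray(m).astype(bool)) for im, m, sid in rows if sid in val_ids]
    if val:
        inter = union = 0.0
        for im, m in val:
            pred = seg.score_map(im) >= 0.5
            inter += 2.0 * np.logical_and(pred, m).sum()
            union += pred.sum() + m.sum()
        seg.val_dice = float(inter / union) if union else 1.0
    return seg


def segment_knee_slices(
    model: BoneSegmenter, crops, slice_indices=None, threshold: float = 0.5
) -> list[BinaryMask]:
    """Apply one bone's model to every knee crop."""
    if slice_indices is None:
        slice_indices = range(len(crops))
    return [
        BinaryMask(model.score_map(c) >= threshold, model.bone, int(k))
        for c, k in zip(crops, slice_indices)
    ]


def oracle_segmenter(ground_truth, slice_index: int, bone: str, roi=None) -> BinaryMask:
    """Exact ground-truth mask (optionally cropped to an ROI window).

    Synthetic runs only; isolates downstream stages from learned-model
    quality.
    """
    if ground_truth is None or bone not in ground_truth.masks:
        raise SegmentationError("ground truth not available")
    grid = ground_truth.masks[bone][slice_index]
    if roi is not None:
        from .roi import crop_window

        r0, r1, c0, c1 = crop_window(roi)
        grid = grid[r0:r1, c0:c1]
    return BinaryMask(grid.copy(), bone, slice_index)


def extract_bone_contours(mask: BinaryMask | np.ndarray, min_length_px: float = 30.0) -> list[Contour]:
    """Trace mask boundaries into ordered sub-pixel polylines.

    Inner (hole) contours are discarded — only the outer boundary of each
    connected component survives — and polylines shorter than
    ``min_length_px`` are filtered out as segmentation noise.
    """
    grid = mask.grid if isinstance(mask, BinaryMask) else np.asarray(mask).astype(bool)
    if not grid.any():
        return []
    raw = find_contours(grid.astype(float), 0.5)
    contours = []
    for pts in raw:
        closed = bool(np.allclose(pts[0], pts[-1]))
        c = Contour(np.asarray(pts, dtype=float), closed)
        if c.length_px >= min_length_px:
            contours.append(c)
    # outer-boundary retention: drop any contour nested inside another
    keep = []
    rings = [
        LinearRing(c.points) if c.closed and len(c.points) >= 4 else None for c in contours
    ]
    from shapely.geometry import Polygon

    polys = [Polygon(r) if r is not None else None for r in rings]
    for i, c in enumerate(contours):
        inside = False
        for j, p in enumerate(polys):
            if i == j or p is None:
                continue
            if p.contains(Point(c.points[0])) and p.contains(Point(c.points[len(c.points) // 2])):
                inside = True
                break
        if not inside:
            keep.append(c)
    return keep


def mask_area_mm2(mask: BinaryMask | np.ndarray, pixel_spacing: tuple[float, float]) -> float:
    """Positive-pixel count times pixel area."""
    grid = mask.grid if isinstance(mask, BinaryMask) else np.asarray(mask).astype(bool)
    return float(grid.sum()) * pixel_spacing[0] * pixel_spacing[1]
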