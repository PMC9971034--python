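"""Knee region-of-interest location and cropping.

One detector is trained for the left knee only; right-knee volumes are
horizontally flipped before detection (flip-then-detect). Per-slice box
centres are aggregated into a single fixed-size square ROI at the per-axis
median centre, shared by every knee slice of the volume.
"""

from __future__ import annotations

import pickle
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from sklearn.neural_network import MLPRegressor

from .classify import pool_features
from .ct_io import flip_slice_horizontal


@dataclass
class BoundingBox:
    centre: tuple[float, float]  # (row, col) pixels
    height: int
    width: int

    def __post_init__(self) -> None:
        if self.height <= 0 or self.width <= 0:
            raise ValueError("box height/width must be positive")


@dataclass
class RoiSpec:
    """Square crop window: per-axis median centre, clamped to the image."""

    centre: tuple[float, float]  # (row, col)
    size: int = 160
    image_shape: tuple[int, int] | None = None


class RoiDetector:
    """Bounding-box regressor: pooled slice image -> (centre, size)."""

    def __init__(self, hidden=(64,), max_iter=400, seed: int = 0, block: int = 8):
        self.block = block
        self.model = MLPRegressor(
            hidden_layer_sizes=hidden, max_iter=max_iter, random_state=seed,
            learning_rate_init=3e-3,
        )
        self.val_centre_error_px: float | None = None

    def _feats(self, images) -> np.ndarray:
        return np.stack([pool_features(im, self.block) for im in images])

    def fit(self, images, targets) -> "RoiDetector":
        self.model.fit(self._feats(images), np.asarray(targets, dtype=float))
        return self

    def predict(self, images) -> np.ndarray:
        return self.model.predict(self._feats(images))

    def save(self, path: str | Path) -> None:
        Path(path).write_bytes(pickle.dumps(self))

    @classmethod
    def load(cls, path: str | Path) -> "RoiDetector":
        return pickle.loads(Path(path).read_bytes())


def train_roi_detector(dataset: dict, hidden=(64,), max_iter=400, seed: int = 0) -> RoiDetector:
    """Train the left-knee box regressor on `(image, centre, size)` fixtures.

    Validation mean centre error (pixels) is measured on the held-out
    subject split and stored on the returned detector.
    """
    rows = dataset["detector"]
    if not rows:
        raise ValueError("empty detector dataset")
    train_ids = set(dataset["train_subjects"])
    val_ids = set(dataset["val_subjects"])
    for img, (cr, cc), (h, w), _sid in rows:
        H, W = img.shape
        if not (0 <= cr < H and 0 <= cc < W):
            raise ValueError("bounding box centre outside image bounds")
    Xtr = [r[0] for r in rows if r[3] in train_ids]
    ytr = [(r[1][0], r[1][1], r[2][0], r[2][1]) for r in rows if r[3] in train_ids]
    det = RoiDetector(hidden=hidden, max_iter=max_iter, seed=seed).fit(Xtr, ytr)
    Xv = [r[0] for r in rows if r[3] in val_ids]
    yv = np.array([r[1] for r in rows if r[3] in val_ids], dtype=float)
    if len(Xv):
        pred = det.predict(Xv)[:, :2]
        det.val_centre_error_px = float(np.mean(np.linalg.norm(pred - yv, axis=1)))
    return det


def detect_centres(det: RoiDetector, slices) -> list[tuple[float, float]]:
    """Predicted box centre per knee slice."""
    pred = det.predict(list(slices))
    return [(float(r), float(c)) for r, c in pred[:, :2]]


def median_roi_box(
    centres, size: int = 160, image_shape: tuple[int, int] | None = None
) -> RoiSpec:
    """Fixed-size square ROI at the per-axis (lower) median slice centre."""
    centres = list(centres)
    if not centres:
        raise ValueError("no centres provided")
    rows = sorted(c[0] for c in centres)
    cols = sorted(c[1] for c in centres)
    i = (len(centres) - 1) // 2  # lower median for even counts
    return RoiSpec((rows[i], cols[i]), size, image_shape)


def crop_window(roi: RoiSpec) -> tuple[int, int, int, int]:
    """Half-open (row0, row1, col0, col1) window, clamped to the image."""
    half = roi.size / 2.0
    r0 = int(round(roi.centre[0] - half))
    c0 = int(round(roi.centre[1] - half))
    if roi.image_shape is not None:
        H, W = roi.image_shape
        if roi.size > H or roi.size > W:
            raise ValueError("ROI larger than image")
        r0 = min(max(r0, 0), H - roi.size)
        c0 = min(max(c0, 0), W - roi.size)
    return r0, r0 + roi.size, c0, c0 + roi.size


def crop_to_roi(slices, roi: RoiSpec, side: str = "left") -> list[np.ndarray]:
    """Crop every slice to the ROI; right-knee slices are flipped first."""
    r0, r1, c0, c1 = crop_window(roi)
    out = []
    for sl in slices:
        if side == "right":
            sl = flip_slice_horizontal(sl)
        if r1 > sl.shape[0] or c1 > sl.shape[1]:
            raise ValueError("ROI larger than image")
        out.append(np.asarray(sl)[r0:r1, c0:c1])
    return out
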