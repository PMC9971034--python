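"""Per-slice four-class classification and knee-region delimitation.

Classes: FIBULA_TIBIA (below-knee slices showing the tibial shaft and
fibula), KNEE (condylar region of the distal femur and proximal tibia),
FEMUR (femoral shaft above the condyles), OTHER (no anatomy). The label
sequence is majority-vote smoothed, the anatomical bone order is read off
the relative positions of the FIBULA_TIBIA and FEMUR runs, and the knee
region is taken as the longest contiguous KNEE run.
"""

from __future__ import annotations

import pickle
from collections import Counter
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from skimage.measure import block_reduce
from sklearn.neural_network import MLPClassifier

from .ct_io import CtVolume

LABELS = ("FIBULA_TIBIA", "KNEE", "FEMUR", "OTHER")

_INTENSITY_SCALE = 2500.0


class ClassifierError(RuntimeError):
    pass


@dataclass
class SliceLabelSequence:
    labels: list[str]
    probabilities: np.ndarray  # (n_slices, 4) rows sum to 1, column order LABELS

    def __post_init__(self) -> None:
        self.probabilities = np.asarray(self.probabilities, dtype=float)
        if len(self.labels) != len(self.probabilities):
            raise ValueError("labels and probabilities length mismatch")


def pool_features(img: np.ndarray, block: int = 8) -> np.ndarray:
    """Block-mean pooled, intensity-normalised image feature vector."""
    img = np.asarray(img, dtype=float)
    H, W = img.shape
    ph = (-H) % block
    pw = (-W) % block
    if ph or pw:
        img = np.pad(img, ((0, ph), (0, pw)), mode="edge")
    pooled = block_reduce(img, (block, block), np.mean)
    return (pooled / _INTENSITY_SCALE).ravel()


class SliceClassifier:
    """Small MLP over block-pooled slice images (4-class softmax output)."""

    def __init__(self, hidden=(64,), max_iter=300, seed: int = 0, block: int = 8):
        self.block = block
        self.image_shape: tuple[int, int] | None = None
        self.model = MLPClassifier(
            hidden_layer_sizes=hidden, max_iter=max_iter, random_state=seed,
            learning_rate_init=3e-3,
        )
        self.val_accuracy: float | None = None

    def _feats(self, images) -> np.ndarray:
        return np.stack([pool_features(im, self.block) for im in images])

    def fit(self, images, labels) -> "SliceClassifier":
        self.image_shape = np.asarray(images[0]).shape
        self.model.fit(self._feats(images), labels)
        return self

    def predict_proba(self, images) -> tuple[list[str], np.ndarray]:
        P = self.model.predict_proba(self._feats(images))
        classes = list(self.model.classes_)
        # reorder columns to the canonical LABELS order (absent classes -> 0)
        out = np.zeros((len(P), len(LABELS)))
        for j, lab in enumerate(LABELS):
            if lab in classes:
                out[:, j] = P[:, classes.index(lab)]
        labels = [LABELS[i] for i in np.argmax(out, axis=1)]
        return labels, out

    def save(self, path: str | Path) -> None:
        Path(path).write_bytes(pickle.dumps(self))

    @classmethod
    def load(cls, path: str | Path) -> "SliceClassifier":
        return pickle.loads(Path(path).read_bytes())


def train_slice_classifier(
    dataset: dict, hidden=(64,), max_iter=300, seed: int = 0
) -> SliceClassifier:
    """Train on `(image, label, subject_id)` fixtures, subject-disjoint split.

    Held-out accuracy over the validation subjects is stored on the model.
    """
    rows = dataset["classifier"]
    train_ids = set(dataset["train_subjects"])
    val_ids = set(dataset["val_subjects"])
    train = [(im, lab) for im, lab, sid in rows if sid in train_ids]
    present = {lab for _, lab in train}
    missing = set(LABELS) - present
    if missing:
        raise ClassifierError(f"class coverage: no training examples for {sorted(missing)}")
    clf = SliceClassifier(hidden=hidden, max_iter=max_iter, seed=seed)
    clf.fit([im for im, _ in train], [lab for _, lab in train])
    val = [(im, lab) for im, lab, sid in rows if sid in val_ids]
    if val:
        pred, _ = clf.predict_proba([im for im, _ in val])
        clf.val_accuracy = float(np.mean([p == t for p, (_, t) in zip(pred, val)]))
    return clf


def classify_volume(
    model: SliceClassifier, vol: CtVolume, strict: bool = False
) -> SliceLabelSequence:
    """One label + probability vector per slice of the volume."""
    slices = list(vol.slices)
    if model.image_shape is not None and vol.shape != tuple(model.image_shape):
        if strict:
            raise ClassifierError(
                f"slice size {vol.shape} does not match training size {model.image_shape}"
            )
        from skimage.transform import resize

        slices = [resize(sl, model.image_shape, preserve_range=True) for sl in slices]
    labels, probs = model.predict_proba(slices)
    return SliceLabelSequence(labels, probs)


def smooth_labels(seq: SliceLabelSequence, window: int = 5) -> SliceLabelSequence:
    """Sliding-window majority vote; ties keep the original label."""
    if window < 1 or window % 2 == 0:
        raise ValueError("window must be an odd integer >= 1")
    labels = seq.labels
    n = len(labels)
    half = window // 2
    out = []
    for i in range(n):
        win = labels[max(0, i - half): min(n, i + half + 1)]
        counts = Counter(win)
        top = counts.most_common()
        if len(top) > 1 and top[0][1] == top[1][1]:
            winners = {lab for lab, c in top if c == top[0][1]}
            out.append(labels[i] if labels[i] in winners else top[0][0])
        else:
            out.append(top[0][0])
    return SliceLabelSequence(out, seq.probabilities.copy())


def determine_bone_order(seq: SliceLabelSequence) -> str:
    """'tibia_to_femur' or 'femur_to_tibia' from median run positions."""
    pos_t = [i for i, l in enumerate(seq.labels) if l == "FIBULA_TIBIA"]
    pos_f = [i for i, l in enumerate(seq.labels) if l == "FEMUR"]
    if not pos_t or not pos_f:
        raise ClassifierError("indeterminate order: need both FIBULA_TIBIA and FEMUR slices")
    return "tibia_to_femur" if np.median(pos_t) < np.median(pos_f) else "femur_to_tibia"


def knee_slice_range(seq: SliceLabelSequence) -> tuple[int, int]:
    """Longest contiguous KNEE run as a half-open [first, last) range."""
    best = None
    start = None
    for i, lab in enumerate(seq.labels + ["_"]):
        if lab == "KNEE" and start is None:
            start = i
        elif lab != "KNEE" and start is not None:
            if best is None or i - start > best[1] - best[0]:
                best = (start, i)
            start = None
    if best is None:
        raise ClassifierError("no knee region: no KNEE slices in sequence")
    return best
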