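"""DICOM series ingest and per-slice image export.

Coordinate convention (fixed repo-wide): pixel (row r, col c) in slice k
maps to the millimetre point (x = c * col_spacing, y = r * row_spacing,
z = k * slice_spacing), 0-based indices. Slices are normalised at load so
the slice index increases monotonically along the scan axis; anatomical
direction (tibia-first vs femur-first) is decided downstream by the slice
classifier.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pydicom
from PIL import Image
from pydicom.dataset import FileDataset, FileMetaDataset
from pydicom.uid import CTImageStorage, ExplicitVRLittleEndian, generate_uid


class CtIoError(RuntimeError):
    pass


@dataclass
class CtVolume:
    """Ordered axial slice stack with spacing metadata (raw stored values)."""

    slices: np.ndarray  # (n_slices, rows, cols)
    pixel_spacing_mm: tuple[float, float]  # (row, col)
    slice_spacing_mm: float
    slice_ids: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.slices = np.asarray(self.slices)
        if self.slices.ndim != 3:
            raise ValueError("slices must be a (n, rows, cols) array")
        if min(self.pixel_spacing_mm) <= 0 or self.slice_spacing_mm <= 0:
            raise ValueError("spacings must be positive")
        if not self.slice_ids:
            self.slice_ids = list(range(len(self.slices)))

    @property
    def n_slices(self) -> int:
        return len(self.slices)

    @property
    def shape(self) -> tuple[int, int]:
        return self.slices.shape[1:]

    def reversed(self) -> "CtVolume":
        """Stack with slice order reversed (used to normalise bone order)."""
        return CtVolume(
            self.slices[::-1].copy(),
            self.pixel_spacing_mm,
            self.slice_spacing_mm,
            list(reversed(self.slice_ids)),
        )


def load_dicom_series(directory: str | Path) -> CtVolume:
    """Read one single-frame CT series into an ordered, spacing-aware volume.

    Slices are sorted by ImagePositionPatient z (falling back to
    InstanceNumber), never by filename. Slice spacing is derived from
    inter-slice position deltas when per-file spacing tags are absent or
    disagree.
    """
    directory = Path(directory)
    datasets = []
    for f in sorted(directory.iterdir()):
        if not f.is_file():
            continue
        try:
            ds = pydicom.dcmread(f)
            _ = ds.pixel_array
        except Exception:
            continue
        datasets.append(ds)
    if len(datasets) < 2:
        raise CtIoError("no usable series: need at least 2 readable DICOM files")
    series_uids = {getattr(ds, "SeriesInstanceUID", None) for ds in datasets}
    if len(series_uids) != 1:
        raise CtIoError("no usable series: directory mixes multiple series")

    def sort_key(ds):
        ipp = getattr(ds, "ImagePositionPatient", None)
        if ipp is not None:
            return float(ipp[2])
        return float(getattr(ds, "InstanceNumber", 0))

    datasets.sort(key=sort_key)
    shapes = {ds.pixel_array.shape for ds in datasets}
    if len(shapes) != 1:
        raise CtIoError("inhomogeneous series: slice dimensions differ")

    slices = np.stack([ds.pixel_array for ds in datasets]).astype(np.float64)
    ps = getattr(datasets[0], "PixelSpacing", [1.0, 1.0])
    pixel_spacing = (float(ps[0]), float(ps[1]))

    zs = []
    for ds in datasets:
        ipp = getattr(ds, "ImagePositionPatient", None)
        if ipp is not None:
            zs.append(float(ipp[2]))
    if len(zs) == len(datasets):
        deltas = np.diff(zs)
        slice_spacing = float(np.median(np.abs(deltas)))
    else:
        slice_spacing = float(getattr(datasets[0], "SliceThickness", 1.0))
    if slice_spacing <= 0:
        slice_spacing = float(getattr(datasets[0], "SliceThickness", 1.0))

    ids = [int(getattr(ds, "InstanceNumber", i)) for i, ds in enumerate(datasets)]
    return CtVolume(slices, pixel_spacing, slice_spacing, ids)


def write_dicom_series(vol: CtVolume, out_dir: str | Path, reverse_positions: bool = False) -> list[Path]:
    """Write a volume as a single-frame CT series (used by the phantom
    generator; round-trips exactly through :func:`load_dicom_series`).

    ``reverse_positions`` writes descending z positions so loaders must sort
    by position rather than by filename/instance order.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    series_uid = generate_uid(entropy_srcs=["autoknee-series"])
    study_uid = generate_uid(entropy_srcs=["autoknee-study"])
    paths = []
    n = vol.n_slices
    for i in range(n):
        k = n - 1 - i if reverse_positions else i
        meta = FileMetaDataset()
        meta.MediaStorageSOPClassUID = CTImageStorage
        meta.MediaStorageSOPInstanceUID = generate_uid(entropy_srcs=[f"autoknee-{i}"])
        meta.TransferSyntaxUID = ExplicitVRLittleEndian
        ds = FileDataset(None, {}, file_meta=meta, preamble=b"\0" * 128)
        ds.SOPClassUID = CTImageStorage
        ds.SOPInstanceUID = meta.MediaStorageSOPInstanceUID
        ds.SeriesInstanceUID = series_uid
        ds.StudyInstanceUID = study_uid
        ds.Modality = "CT"
        ds.InstanceNumber = i + 1
        ds.ImagePositionPatient = [0.0, 0.0, float(k * vol.slice_spacing_mm)]
        ds.ImageOrientationPatient = [1, 0, 0, 0, 1, 0]
        ds.PixelSpacing = [vol.pixel_spacing_mm[0], vol.pixel_spacing_mm[1]]
        ds.SliceThickness = vol.slice_spacing_mm
        ds.Rows, ds.Columns = vol.shape
        ds.BitsAllocated = 16
        ds.BitsStored = 16
        ds.HighBit = 15
        ds.PixelRepresentation = 0
        ds.SamplesPerPixel = 1
        ds.PhotometricInterpretation = "MONOCHROME2"
        ds.RescaleIntercept = -1024.0
        ds.RescaleSlope = 1.0
        arr = np.clip(vol.slices[k], 0, 65535).astype(np.uint16)
        ds.PixelData = arr.tobytes()
        path = out_dir / f"slice_{i:04d}.dcm"
        ds.save_as(path, enforce_file_format=True)
        paths.append(path)
    return paths


def export_slice_images(
    vol: CtVolume, out_dir: str | Path, window: tuple[float, float]
) -> list[Path]:
    """Write one 8-bit grayscale PNG per slice, linearly windowed/clipped."""
    lo, hi = window
    if not lo < hi:
        raise ValueError("window must satisfy lo < hi")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for k, sl in enumerate(vol.slices):
        img = window_slice(sl, (lo, hi))
        path = out_dir / f"slice_{k:04d}.png"
        Image.fromarray(img, mode="L").save(path)
        paths.append(path)
    return paths


def window_slice(sl: np.ndarray, window: tuple[float, float]) -> np.ndarray:
    """Linear window of one slice to uint8 (monotone in input intensity)."""
    lo, hi = window
    scaled = (np.asarray(sl, dtype=float) - lo) / (hi - lo)
    return np.clip(np.round(scaled * 255.0), 0, 255).astype(np.uint8)


def flip_slice_horizontal(img: np.ndarray) -> np.ndarray:
    """Reverse columns (left/right mirror); an involution."""
    img = np.asarray(img)
    if img.size == 0:
        raise ValueError("empty image")
    return img[:, ::-1].copy()
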