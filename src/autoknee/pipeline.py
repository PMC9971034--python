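"""End-to-end orchestration: ingest -> classify -> ROI -> segment ->
contours -> transition -> stacks -> align -> morph -> implant design.

A stage failure aborts the run with a stage-tagged diagnostic rather than
a bare traceback; every intermediate is kept on the returned result object
so runs can be inspected and re-evaluated.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import trimesh

from . import classify as clf
from . import contours as cb
from . import implant as imp
from . import metrics as fm
from . import roi as roi_mod
from . import segment as seg
from .config import PipelineConfig
from .ct_io import CtVolume, flip_slice_horizontal, load_dicom_series
from .ssm import ShapeModel, align_stack_to_base, morph_to_stack, train_ssm
from .synthetic import make_training_fixtures


class PipelineStageError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class TrainedModels:
    classifier: clf.SliceClassifier
    detector: roi_mod.RoiDetector
    seg_femur: seg.BoneSegmenter
    seg_tibia: seg.BoneSegmenter
    ssm_femur: ShapeModel
    ssm_tibia: ShapeModel

    def save(self, directory: str | Path) -> None:
        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        self.classifier.save(d / "classifier.pkl")
        self.detector.save(d / "detector.pkl")
        self.seg_femur.save(d / "seg_femur.pkl")
        self.seg_tibia.save(d / "seg_tibia.pkl")
        self.ssm_femur.save(d / "ssm_femur.npz")
        self.ssm_tibia.save(d / "ssm_tibia.npz")

    @classmethod
    def load(cls, directory: str | Path) -> "TrainedModels":
        d = Path(directory)
        return cls(
            clf.SliceClassifier.load(d / "classifier.pkl"),
            roi_mod.RoiDetector.load(d / "detector.pkl"),
            seg.BoneSegmenter.load(d / "seg_femur.pkl"),
            seg.BoneSegmenter.load(d / "seg_tibia.pkl"),
            ShapeModel.load(d / "ssm_femur.npz"),
            ShapeModel.load(d / "ssm_tibia.npz"),
        )


def train_models(population, config: PipelineConfig | None = None, seed: int = 0,
                 fixtures: dict | None = None) -> tuple[TrainedModels, dict]:
    """Train every learned stage plus both shape models from a phantom cohort.

    Returns the models and the fixture dict (whose held-out subject split
    the caller can reuse for evaluation).
    """
    config = config or PipelineConfig()
    if fixtures is None:
        fixtures = make_training_fixtures(population, seed=seed, roi_size=config.roi_size_px)
    classifier = clf.train_slice_classifier(fixtures, seed=seed)
    detector = roi_mod.train_roi_detector(fixtures, seed=seed)
    seg_f = seg.train_bone_segmenter("femur", fixtures, seed=seed)
    seg_t = seg.train_bone_segmenter("tibia", fixtures, seed=seed)
    train_ids = set(fixtures["train_subjects"])
    gts = fixtures["ground_truth"]
    femur_meshes = [gts[i].meshes["femur"] for i in sorted(train_ids)]
    tibia_meshes = [gts[i].meshes["tibia"] for i in sorted(train_ids)]
    ssm_f = train_ssm(femur_meshes, smooth_iters=config.ssm_smooth_iters)
    ssm_t = train_ssm(tibia_meshes, smooth_iters=config.ssm_smooth_iters)
    return TrainedModels(classifier, detector, seg_f, seg_t, ssm_f, ssm_t), fixtures


@dataclass
class PipelineResult:
    femur_prediction: trimesh.Trimesh
    tibia_prediction: trimesh.Trimesh
    femur_component: imp.ImplantComponent
    tibia_plate: imp.ImplantComponent
    labels: list
    knee_range: tuple
    transition: int
    roi: roi_mod.RoiSpec
    stacks: dict  # bone -> ContourStack (volume frame)
    regions: dict  # bone -> (z_lo, z_hi) fitted band, volume frame mm
    morph_weights: dict
    logs: list = field(default_factory=list)


def run_pipeline(
    source: str | Path | CtVolume,
    models: TrainedModels,
    config: PipelineConfig | None = None,
) -> PipelineResult:
    """Run the full CT-to-implant pipeline on one volume or DICOM directory."""
    config = config or PipelineConfig()
    logs: list[str] = []
    t_start = time.time()

    def log(stage: str) -> None:
        logs.append(f"{stage}: t={time.time() - t_start:.1f}s")

    def stage(name, fn, *args, **kw):
        try:
            out = fn(*args, **kw)
        except Exception as e:  # noqa: BLE001 - surface with stage name
            raise PipelineStageError(name, str(e)) from e
        log(name)
        return out

    # ingest (right knees are mirrored to the left frame up front; the
    # single detector/segmenters are left-knee models)
    if isinstance(source, CtVolume):
        vol = source
    else:
        vol = stage("ingest", load_dicom_series, source)
    if config.side == "right":
        vol = CtVolume(
            np.stack([flip_slice_horizontal(s) for s in vol.slices]),
            vol.pixel_spacing_mm, vol.slice_spacing_mm, vol.slice_ids,
        )

    # classification, smoothing, bone order, knee region
    seq = stage("classify", clf.classify_volume, models.classifier, vol)
    seq = clf.smooth_labels(seq, config.label_smooth_window)
    order = stage("bone_order", clf.determine_bone_order, seq)
    if order == "femur_to_tibia":
        vol = vol.reversed()
        seq = clf.SliceLabelSequence(list(reversed(seq.labels)), seq.probabilities[::-1])
    knee = stage("knee_range", clf.knee_slice_range, seq)
    first, last = knee

    # ROI (volume already in the left frame)
    knee_slices = [vol.slices[k] for k in range(first, last)]
    centres = stage("roi_detect", roi_mod.detect_centres, models.detector, knee_slices)
    roi = roi_mod.median_roi_box(centres, config.roi_size_px, image_shape=vol.shape)
    crops = roi_mod.crop_to_roi(knee_slices, roi, side="left")
    log("roi_crop")

    # segmentation + contours
    idx = list(range(first, last))
    masks_f = stage("segment_femur", seg.segment_knee_slices, models.seg_femur, crops, idx,
                    config.seg_threshold)
    masks_t = stage("segment_tibia", seg.segment_knee_slices, models.seg_tibia, crops, idx,
                    config.seg_threshold)
    cont_f = {m.slice_index: seg.extract_bone_contours(m, config.min_contour_length_px)
              for m in masks_f}
    cont_t = {m.slice_index: seg.extract_bone_contours(m, config.min_contour_length_px)
              for m in masks_t}
    log("contours")

    # transition + stacks
    profile = cb.area_profiles(masks_f, masks_t, vol.pixel_spacing_mm, first_slice=first)
    transition = stage("transition", cb.find_transition_slice, profile)
    femur_stack, tibia_stack = stage(
        "stacks", cb.split_and_build_stacks, cont_f, cont_t, transition, knee,
        vol.slice_spacing_mm, vol.pixel_spacing_mm, roi, config.stack_trim_slices,
    )

    # shape model fitting (prediction mapped back to the volume frame)
    preds, weights, regions, stacks = {}, {}, {}, {}
    for bone, stack, model in (
        ("femur", femur_stack, models.ssm_femur),
        ("tibia", tibia_stack, models.ssm_tibia),
    ):
        pts = stack.points()
        aligned, T = stage(f"align_{bone}", align_stack_to_base, stack, model,
                           config.icp_max_iters, config.icp_tol_mm)
        mesh, w, info = stage(
            f"morph_{bone}", morph_to_stack, model, aligned, config.n_pc,
            config.morph_max_outer, 1e-8, config.morph_weight_bound_sd,
        )
        Tinv = T.inverse()
        pred = trimesh.Trimesh(Tinv.apply(mesh.vertices), mesh.faces.copy(), process=False)
        preds[bone] = pred
        weights[bone] = w
        regions[bone] = (float(pts[:, 2].min()), float(pts[:, 2].max()))
        stacks[bone] = stack

    # implant design
    measures = stage("measure", imp.measure_ap_ml, preds["femur"], config.condylar_fraction)
    plan = imp.plan_femur_cuts(measures, config.femur_cuts)
    femur_comp = stage(
        "design_femur", imp.design_femur_component, preds["femur"], plan,
        config.shell_mm, config.pin_radius_mm, config.pin_length_mm,
    )
    plane = stage("plateau_plane", imp.tibia_plateau_plane, preds["tibia"],
                  config.plateau_fit_fraction)
    tprofile = stage("tibia_profile", imp.extract_tibia_profile, preds["tibia"], plane,
                     config.section_offset_mm)
    plate_spec = imp.PlateSpec(
        section_offset_mm=config.section_offset_mm,
        thickness_mm=config.plate_thickness_mm,
        pin_radius_mm=config.pin_radius_mm,
        pin_length_mm=config.pin_length_mm,
    )
    plate = stage("design_tibia", imp.design_tibia_plate, tprofile, plate_spec)

    return PipelineResult(
        preds["femur"], preds["tibia"], femur_comp, plate, list(seq.labels), knee,
        transition, roi, stacks, regions, weights, logs,
    )


def evaluate_subject(result: PipelineResult, gt, config: PipelineConfig | None = None,
                     seed: int = 0) -> dict:
    """Fit metrics of one subject's predictions/components vs ground truth."""
    config = config or PipelineConfig()
    out = {}
    for bone, pred in (("femur", result.femur_prediction), ("tibia", result.tibia_prediction)):
        rep = fm.prediction_fit(pred, gt.meshes[bone], result.regions[bone],
                                n_samples=config.rmse_n_samples, seed=seed)
        out[f"{bone}_prediction_rmse_mm"] = rep.rmse_mm
    comp_rep = fm.component_fit(result.femur_component, gt.meshes["femur"],
                                config.ouh_threshold_mm, seed=seed)
    out["femur_component_rmse_mm"] = comp_rep.rmse_mm
    out["femur_max_ouh_mm"] = comp_rep.max_ouh_mm
    out["femur_ouh_flag"] = comp_rep.ouh_flag
    plate_rep = fm.component_fit(result.tibia_plate, gt.meshes["tibia"],
                                 config.ouh_threshold_mm, seed=seed)
    out["tibia_component_rmse_mm"] = plate_rep.rmse_mm
    out["tibia_max_ouh_mm"] = plate_rep.max_ouh_mm
    out["tibia_ouh_flag"] = plate_rep.ouh_flag
    return out


COHORT_COLUMNS = [
    "subject_id", "sex", "side", "age", "height_cm",
    "femur_prediction_rmse_mm", "tibia_prediction_rmse_mm",
    "femur_component_rmse_mm", "tibia_component_rmse_mm",
    "femur_max_ouh_mm", "tibia_max_ouh_mm", "femur_ouh_flag", "tibia_ouh_flag",
]


def evaluate_cohort(results: dict, ground_truths: dict,
                    config: PipelineConfig | None = None, seed: int = 0
                    ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-subject FitReports and cohort summary statistics.

    ``results``/``ground_truths`` map subject id -> PipelineResult /
    GroundTruth. Returns (per-subject table with COHORT_COLUMNS, stats
    table from :func:`autoknee.metrics.cohort_stats`).
    """
    if not results:
        raise ValueError("empty cohort")
    config = config or PipelineConfig()
    rows = []
    for sid, res in results.items():
        gt = ground_truths[sid]
        row = {"subject_id": sid, "sex": gt.metadata.get("sex"), "side": gt.side,
               "age": gt.metadata.get("age"), "height_cm": gt.metadata.get("height_cm")}
        row.update(evaluate_subject(res, gt, config, seed=seed))
        rows.append(row)
    df = pd.DataFrame(rows)[COHORT_COLUMNS]
    stats = fm.cohort_stats(
        df,
        metrics=["femur_prediction_rmse_mm", "tibia_prediction_rmse_mm",
                 "femur_component_rmse_mm", "tibia_component_rmse_mm"],
        group_cols=["sex", "side"],
        continuous_cols=["age", "height_cm"],
    )
    return df, stats
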