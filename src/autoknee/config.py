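"""Pipeline configuration: the single source of the pipeline's constants.

Clinically meaningful defaults (ROI size, stack trim, number of morphing
principal components, plate thickness, tibia section offset, OUH threshold)
follow the published custom-TKR workflow this package implements; purely
numerical knobs (windowing, Canny-style contour length filter, ICP
tolerances, cut-template fractions) are this package's own choices and are
documented in docs/methods.md.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml


@dataclass
class FemurCutTemplate:
    """Relative plane offsets of the five-plane femoral box cut.

    Offsets are fractions of the condylar AP extent (for planes whose
    position scales anterior–posteriorly / distally) or of the ML extent
    (for the medial/lateral trim planes), so the plan scales with subject
    size.
    """

    anterior_frac: float = 0.98
    anterior_chamfer_frac: tuple[float, float] = (0.85, 0.38)
    distal_frac: float = 0.45
    posterior_chamfer_frac: tuple[float, float] = (0.15, 0.38)
    posterior_frac: float = 0.02
    ml_trim_frac: float = 0.50  # half-width kept, fraction of ML


@dataclass
class PipelineConfig:
    # --- geometry / imaging constants from the reference workflow ---
    roi_size_px: int = 160              # square knee crop, pixels
    stack_trim_slices: int = 5          # slices trimmed at the far ends of each stack
    n_pc: int = 2                       # principal components used for morphing
    plate_thickness_mm: float = 5.0     # tibial plate extrusion thickness
    section_offset_mm: float = 2.0      # profile plane below widest medial condyle
    ouh_threshold_mm: float = 3.0       # clinical over/underhang flag (inclusive)

    # --- CT ingest ---
    window_lo: float = 150.0            # bone-ish display window on stored values
    window_hi: float = 2500.0
    side: str = "left"                  # left | right; right is mirrored before detection

    # --- classification / smoothing ---
    label_smooth_window: int = 5

    # --- segmentation / contours ---
    seg_threshold: float = 0.5          # per-pixel probability threshold
    min_contour_length_px: float = 30.0

    # --- shape model fitting ---
    icp_max_iters: int = 100
    icp_tol_mm: float = 1e-6
    morph_max_outer: int = 25
    morph_weight_bound_sd: float = 3.0  # weights bounded to +/- this many mode sds
    ssm_smooth_iters: int = 0

    # --- implant design ---
    shell_mm: float = 1.5               # femoral component thickness
    shell_tolerance_mm: float = 1.5     # accepted bone-facing surface offset
    pin_radius_mm: float = 3.0
    pin_length_mm: float = 10.0
    plateau_fit_fraction: float = 0.12  # top z-fraction of tibia used for plane fit
    condylar_fraction: float = 0.60     # distal z-fraction treated as condylar region
    femur_cuts: FemurCutTemplate = field(default_factory=FemurCutTemplate)

    # --- metrics ---
    rmse_n_samples: int = 2000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.side not in ("left", "right"):
            raise ValueError(f"side must be 'left' or 'right', got {self.side!r}")
        if self.label_smooth_window % 2 != 1:
            raise ValueError("label_smooth_window must be odd")

    # -- serialisation -------------------------------------------------
    def to_yaml(self, path: str | Path) -> None:
        d = asdict(self)
        Path(path).write_text(yaml.safe_dump(d, sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        d = yaml.safe_load(Path(path).read_text())
        cuts = d.pop("femur_cuts", None)
        cfg = cls(**d)
        if cuts is not None:
            for k, v in cuts.items():
                setattr(cfg.femur_cuts, k, tuple(v) if isinstance(v, list) else v)
        return cfg
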