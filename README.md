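# autoknee

Automated design of custom total knee replacement (TKR) implants from CT
scans. Starting from an axial DICOM series, the pipeline

1. classifies every slice into four classes — `Fibula/Tibia`, `Knee`,
   `Femur`, `Other` — and delimits the contiguous knee region;
2. locates the (left) knee with a bounding-box regressor and crops all
   knee slices to a shared 160 × 160 px region of interest at the median
   box centre (right knees are mirrored first, so only a left-knee model
   is ever trained);
3. segments femur and tibia with separate per-bone models, traces the
   mask boundaries into sub-pixel contours and drops short noise
   contours;
4. finds the tibia–femur transition slice where the two per-slice
   segmented-area curves intersect between their maxima, splits the
   contours there, trims 5 noisy end slices per stack, and positions the
   contours in millimetre space using the DICOM spacing;
5. rigidly registers each contour stack to a per-bone statistical shape
   model (SSM) by ICP and morphs the model's first **2 principal
   components** to fit the stack, yielding a full 3-D surface prediction;
6. derives a generic femoral component (scaled five-plane box cut of the
   condylar surface, shell offset, fixation pins) and a tibial plate (a
   section taken parallel to the tibial plateau 2 mm below the widest
   medial-condyle point, extruded to 5 mm with bearing/posterior cuts and
   a pin).

Fit is scored by the surface RMSE

    RMSE = sqrt( Σ_i (x_i − x̂_i)² / N )

over closest-point distances after rigid ICP alignment, and by the
maximum over/underhang (OUH), the directed Hausdorff distance between the
component edges C and the resected-bone edges B,

    h(C, B) = max_{c∈C} min_{b∈B} d(c, b),

with OUH ≥ 3 mm (inclusive) flagged as clinically significant.

Because real clinical CT datasets of this kind are access-restricted, the
package ships a first-class synthetic knee-phantom generator
(`autoknee.synthetic`): a parametric femur/tibia/fibula template deformed
by three analytic variation modes (global scale, condyle/plateau spread,
plateau slope) and voxelised into CT-like volumes with per-slice masks,
class labels, bounding boxes and ground-truth meshes. Every learned stage
trains on these phantoms at desk scale, and every geometric claim can be
checked against known ground truth.

## Worked example

```python
from autoknee import synthetic as syn
from autoknee.config import PipelineConfig
from autoknee.pipeline import train_models, run_pipeline, evaluate_subject

pop = syn.generate_bone_population(syn.PopulationParams(n_subjects=14, seed=7))
models, _ = train_models(pop[:10], seed=7)          # ~20 s on one CPU

subject = pop[13]                                    # held out
ct, gt = syn.voxelize_subject(subject, seed=113, center_jitter_mm=4.0)
cfg = PipelineConfig(side=subject.side)
res = run_pipeline(ct, models, cfg)
print(res.transition, res.knee_range)
print(evaluate_subject(res, gt, cfg))
```

prints (one run on this machine):

```
45 (29, 70)
{'femur_prediction_rmse_mm': 0.175, 'tibia_prediction_rmse_mm': 0.287,
 'femur_component_rmse_mm': 1.433, 'femur_max_ouh_mm': 0.975, 'femur_ouh_flag': False,
 'tibia_component_rmse_mm': 0.193, 'tibia_max_ouh_mm': 0.585, 'tibia_ouh_flag': False}
```

i.e. the knee region spans slices 29–70, the tibia–femur transition was
detected at slice 45 (the phantom's true joint line is at ~45.9 mm with
1 mm slices), both 3-D bone predictions land within 0.3 mm RMSE of the
ground-truth surfaces, the component's bone-facing surface sits within
the 1.5 mm shell of the bone, and neither implant exceeds the 3 mm
over/underhang threshold.

The same workflow is available from the shell:

```bash
autoknee simulate --n 10 --seed 0 --out phantoms/
autoknee train --n 20 --seed 0 --out models/
autoknee predict phantoms/subject_003/dicom models/ --side left --out pred/
autoknee evaluate pred/ phantoms/subject_003/
```

## Layout

- `src/autoknee/ct_io.py` — DICOM ingest/writing, windowed PNG export, flips
- `src/autoknee/synthetic.py` — phantom population generator + voxeliser
- `src/autoknee/classify.py` — slice classifier, smoothing, bone order, knee range
- `src/autoknee/roi.py` — box regressor, median ROI, flip-then-crop
- `src/autoknee/segment.py` — per-bone segmenters, oracle masks, contours
- `src/autoknee/contours.py` — area profiles, transition, contour stacks
- `src/autoknee/ssm.py` — SSM training (GPA + PCA), ICP, 2-PC morphing
- `src/autoknee/implant.py` — cut planning, femoral component, tibial plate, resection
- `src/autoknee/metrics.py` — surface RMSE, max OUH, heatmaps, cohort stats
- `src/autoknee/pipeline.py`, `cli.py` — orchestration and the `autoknee` CLI

See `docs/methods.md` for the underlying models, parameter choices and
known limitations.
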