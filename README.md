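# tearfilm

Non-invasive, objective detection of tear-film breakup in interference-color
images of the ocular surface — for researchers working on dry eye disease,
tear-film interferometry, and medical image analysis pipelines.

The tear film's outer lipid layer produces thin-film interference colors
under white light: reflections from the layer's front and back surfaces
differ in optical path by 2·n·d, so the recorded color encodes local lipid
thickness d. Breakup — local rupture of the film — appears as characteristic
dark regions. This package implements the full detection method:

* **optics / scene simulation** — renders interference colors from a latent
  thickness field via the two-beam reflectance
  R(λ) = r₁² + r₂² + 2 r₁ r₂ cos(4π n d / λ) and the CIE 1931 observer, and
  generates labeled synthetic videos with three breakup morphologies
  (area / spot / line), fringed and uniform backgrounds, and the real-world
  confounders (bright reflections, particles, eyelashes, eyelid/camera
  mask), with definitional per-pixel ground truth;
* **patch classifier** — a nine-class 96×96 patch classifier built as
  transfer learning: a frozen convolutional feature extractor plus a
  trainable softmax head (Adam, categorical cross-entropy, batch size 20,
  checkpoint at maximal validation accuracy), with scale/shift/h-flip
  augmentation (never vertical flips);
* **frame-level detector** — the central 384×384 region is tiled into 49
  overlapping 96×96 windows (stride 48); a frame is declared breakup when
  the number of tiles classified area/spot/line reaches a threshold, and the
  integer tile count is the sweepable ROC score;
* **evaluation** — video-grouped six-fold cross-validation (no patch of one
  video ever spans folds), confusion matrices, per-class recall / precision /
  F1, breakup-vs-non-breakup aggregation, and ROC/AUC with a DeLong 95% CI.

See `docs/methods.md` for the model, assumptions, and design choices.

## Worked example

```python
import numpy as np
from tearfilm import scene, detect
from tearfilm.optics import OpticalModel, ThicknessMap, render_interference

# render a uniform 120 nm lipid film with a spot rupture
spec = scene.SceneSpec(
    video_id="demo", duration=2.0, fps=2.0, frame_size=(640, 480),
    events=[scene.BreakupEvent("spot", onset=1.0, center=(264, 344),
                               initial_size=18, growth_rate=2.0)],
    seed=7,
)
video = scene.render_video(spec)
print([f.truth.breakup_present for f in video.frames])
# [False, False, True, True]   <- label flips when the rupture enters the ROI

grid = detect.tile_frame(384, 96, 48)
print(len(grid.tiles), grid.per_axis)
# 49 7                         <- 7x7 half-overlapping tiles cover the ROI

from tearfilm.metrics import f1_from_precision_recall
print(round(float(f1_from_precision_recall(0.917, 0.897)), 3))
# 0.907                        <- area-pattern F1 from its recall/precision
```

The command-line pipeline mirrors this end to end:

```sh
tearfilm simulate --seed 1 --out cohort/          # synthetic videos + manifests
tearfilm split --manifest cohort/manifest.csv --out groups.json
tearfilm train-eval --manifest cohort/manifest.csv --out cv/
tearfilm detect-eval --model cv/fold0_model.npz --frames cohort/frames.csv --out det/
```

Every command is deterministic for a fixed config and seed: re-running
produces byte-identical reports, and `provenance.json` records content
hashes of everything written.

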