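# Methods

## Problem

Tear-film breakup — local rupture of the precorneal tear film — is the event
timed by breakup-time tests for dry eye disease. In lipid-layer
interferometry, white light reflected from the front and back surfaces of the
lipid layer interferes, so the recorded color encodes local lipid thickness,
and breakup appears as characteristic dark regions. This package implements a
non-invasive, objective frame-level breakup detector for such
interference-color images: a nine-class 96×96 patch classifier, an
overlapping-tile decision rule over a central 384×384 region, video-grouped
six-fold cross-validation, and ROC evaluation. Because the clinical videos
behind the original method are not public, the package ships a physics-based
synthetic scene generator that provides labeled images with definitional
ground truth, and the whole pipeline is validated end to end on that
synthetic study.

## Optical model

The simulator renders thin-film interference at normal incidence with the
two-beam (first-order) approximation:

R(λ) = r₁² + r₂² + 2 r₁ r₂ cos(4π n d / λ),

with Fresnel amplitudes r₁ = (n_air − n_lipid)/(n_air + n_lipid) and
r₂ = (n_lipid − n_aq)/(n_lipid + n_aq), lipid index n = 1.48, aqueous 1.334,
film thickness d in nm. The coefficients are small (|r₁| ≈ 0.19, |r₂| ≈ 0.05),
so multiple internal reflections contribute little: against a truncated Airy
multiple-beam summation (kept as a test-only oracle) the worst-case relative
deviation over d ∈ [0, 500] nm is 2.0%, at interference extrema where the
neglected terms (∝ r₁²) peak. Spectra are sampled at 380–780 nm in 5 nm
steps, integrated against the CIE 1931 2° observer (evaluated from the
standard multi-lobe piecewise-Gaussian fits), white-balanced per channel so
the illuminant renders neutral, converted through the linear-sRGB matrix, and
gamma-encoded. The illuminant defaults to equal energy because the device
lamp spectrum is not published; colors are therefore plausible, not
radiometrically calibrated. Ruptured pixels are drawn as a dark desaturated
gray (0.22 with 6% multiplicative noise), matching the dark appearance of
real breakup.

## Scene generator

A scene is a smooth random lipid-thickness field (Gaussian noise low-passed
at a correlation length of 60–120 px, mean 90–160 nm) plus structure:

* **Breakup events** appear after a simulated blink (t = 0 at full opening)
  and grow: `spot` is a disk/ellipse (radius ~12–20 px) that may elongate
  vertically (tear fluid moves upward); `line` is a vertical capsule whose
  length exceeds 3× its width by construction; `area` is an irregular blob
  (radius ~35–55 px) with angular boundary modulation. Around each rupture
  the film thins toward zero over a soft margin so the edge shows physically
  rendered color banding. Footprint geometry enforces class separability:
  spots are near-isotropic at onset (aspect within [1/1.5, 1.5]), lines
  exceed aspect 3.
* **Backgrounds**: low-amplitude fields read as the `uniform` class; strong
  sinusoidal thickness modulation (45–80 nm, 33–80 px period) produces
  visible colored `interference_fringe` stripes.
* **Confounders** in image space: `bright_reflection` saturates a soft disk
  toward white (intraocular-lens reflections), `particle` darkens small
  blobs (oil/debris), `eyelash` draws thin dark Bézier curves entering from
  the frame border, `eyelid` blacks out eyelid arcs and the circular camera
  mask. Secondary particles/lashes/reflections are sprinkled across ~20–35%
  of scenes so every class is observed in many videos.

Ground truth is definitional: the generator records each element's footprint
mask, and a frame is labeled breakup-present iff any rupture pixel lies
inside the central 384×384 detection region. Patch labels follow a
dominant-element rule (ties favor breakup; a window containing rupture pixels
can never receive a non-breakup label; `uniform`/`interference_fringe`
windows must be free of all footprints). Cohort defaults mirror the emulated
clinical study: 640×480 frames, 30 s at 30 fps, up to 40 evaluation frames
per video, one video per eye and two eyes per subject; desk-scale runs
shorten duration/fps (the labels do not depend on them). Breakup sizes and
growth rates are not quantified in the source clinical work; the defaults
above are plausible ranges exposed as configuration, not claims. The
generator does not model eye motion, photoreal lid texture, or camera noise
beyond the optics, so passing tests demonstrate pipeline correctness and
recoverability under the stated image formation model — not clinical
performance.

## Classifier

Transfer-learning layout: a frozen feature extractor plus a trainable softmax
head. The shipped extractor is a small deterministic random-filter
convolutional network (four 3×3 conv + ReLU + average-pool stages over a 4×
down-sampled 224×224 input, global mean/max pooling, concatenated with
global and 2×2-block color statistics and luminance gradient-energy
statistics; all filters fixed by a seed). Random convolutional features with
a trained linear readout are a standard strong baseline for color/texture
discrimination, which is what separates these nine classes; the backbone is
an interface, so a large pretrained network can be dropped in where
available. Training follows the patch protocol: 96×96 patches are augmented
on the fly (scale ±10%, shifts ±10% with reflection padding, horizontal flip
p = 0.5; vertical flips are never applied because breakup morphology is
vertically signed), rescaled to 224×224 bilinearly, and the head is trained
with Adam (lr 10⁻², weight decay 10⁻³ on the weights), categorical
cross-entropy, batch size 20, with the checkpoint taken at the epoch of
maximal validation accuracy (earliest epoch on ties). The learning rate is a
package choice — the source protocol names only the optimizer — selected for
reliable convergence of a linear head on standardized features. Features are
standardized by the training split's mean/scale, stored with the model.
Epoch budgets are runtime knobs (the validation-selection rule makes them
non-semantic); desk default 30, and the reference experiment uses 14.

## Detection rule

A frame's central 384×384 region (origin (48, 128) on a 640×480 frame,
centered with floor rounding) is tiled into 96×96 windows at stride 48 —
7×7 = 49 tiles, adjacent tiles overlapping by half so small ruptures cannot
fall between windows; every interior pixel is covered by 4 tiles. Each tile
is classified; the frame is declared breakup iff the number of tiles labeled
`area`/`spot`/`line` is at least `min_breakup_tiles` (inclusive; default 1,
the most sensitive reading). The integer breakup-tile count is the ROC sweep
statistic: `decide(labels, n)` ⇔ `count ≥ n`, so sweeping n traces the
curve; a summed breakup-probability score is available as an alternative.
Overlays tint breakup tiles (purple area, blue spot, green line) with a
single-pass per-class mask so overlapping tiles blend once; where classes
overlap, area > spot > line takes precedence.

## Cross-validation

Patches from one video (and, by default, from both eyes of one subject — a
stricter anti-leakage choice than the video-level grouping of the source
protocol, configurable off) stay in one of six groups. Assignment is greedy
largest-first: units ordered by descending patch count (ties broken by a
seed-keyed hash, making the result deterministic and invariant to record
order) are placed in the group minimizing the summed squared per-class
counts. The advisory balance tolerance is 30% relative deviation per class,
matching the spread visible in the emulated cohort's published breakdown.
Folds rotate cyclically: fold 1 trains on {A,B,C,D}, validates on E, tests
on F; each subsequent fold rotates the sequence by one, so every group is
tested exactly once and validates exactly once.

## Evaluation

Confusion matrices use rows = actual, columns = predicted. Per-class recall,
precision and F1 come from the matrix margins; 0/0 ratios are reported as
NaN, never silently as 0, so averages cannot be corrupted. Binary
aggregation takes {area, spot, line} as positive. AUC is the midrank
Mann–Whitney statistic P(s⁺ > s⁻) + ½P(s⁺ = s⁻) computed from ranks (exact);
curve points come from sweeping all distinct thresholds. The 95% CI uses the
DeLong placement-based variance with a normal interval clipped to [0, 1]
(the dominant method in standard statistical environments), with a seeded
stratified bootstrap as a selectable cross-check. Fold summaries report mean
± sample (n−1) standard deviation. Percentages print to one decimal and F1
to three, following the conventions of the emulated study.

## Reference experiment (desk scale)

`tearfilm.experiments.synthetic_recovery` runs the whole study in a few
minutes on one CPU: 36 training videos (100 patches/class), classifier
trained on five of six video groups with the sixth as validation checkpoint
(14 epochs); nine-class accuracy measured on 270 patches from 18 entirely
new videos (a stricter hold-out than a held-out group); frame-level ROC on
54 frames from 18 easy-regime videos (large high-contrast breakups),
scored by breakup-tile count. Problem sizes were chosen so the experiment
completes at desk scale while keeping every class represented in multiple
videos of both cohorts. The headline clinical numbers of the emulated study
(nine-class accuracy 81.3%, binary 92.3%/83.4%/95.2%, frame AUC 0.898)
depend on its proprietary 350-eye video set and a large pretrained backbone
and are therefore not desk-reproducible; the synthetic study validates the
pipeline's correctness and recoverability instead.

## Numerical choices and edge cases

* All color math in float; quantization to 8 bits only at PNG write.
* Wavelength grid 380–780 nm step 5 nm: halving the step changes the XYZ
  integral by well under 0.5%.
* Class-label tie-breaks: argmax ties resolve to the earliest class in the
  canonical order (area, spot, line, uniform, interference_fringe,
  bright_reflection, particle, eyelash, eyelid).
* Degenerate ROC inputs (single-class labels) raise, with guidance, rather
  than returning an undefined AUC.
* Every stochastic stage draws from a named substream of one top-level seed
  (SHA-256-keyed), so stages re-run independently and reproducibly;
  re-running any pipeline command yields byte-identical outputs.

## Known limitations

* Synthetic colors are plausible, not calibrated to any device; the
  illuminant and acceptance angle of real interferometers are unpublished.
* The shipped backbone is far smaller than a pretrained deep network;
  synthetic accuracies do not transfer to clinical imagery.
* Breakup-time (NIBUT) measurement across a video timeline is out of scope;
  the detector stops at per-frame presence.
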