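"""Reference experiments: end-to-end synthetic recovery of the detection pipeline.

The clinical cohort behind the original method is not public, so the pipeline
is exercised end to end on synthetic scenes: train the patch classifier on one
rendered cohort, measure nine-class accuracy on patches from entirely new
videos, and measure frame-level breakup detection (ROC/AUC of the
breakup-tile-count score) on an easy-regime evaluation cohort with large,
high-contrast breakups.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import detect, metrics, scene
from ._util import substream
from .crossval import assign_groups, rotation_plan
from .data import CLASSES, Manifest
from .model import RandomConvBackbone, TrainConfig, classify_patches, train_head

__all__ = ["RecoveryResult", "synthetic_recovery"]


@dataclass
class RecoveryResult:
    patch_accuracy: float  # nine-class accuracy on patches from unseen videos
    n_eval_patches: int
    auc: float
    n_frames: int
    n_positive_frames: int
    sensitivity_at_1: float
    specificity_at_1: float
    scores: list[float]
    labels: list[bool]
    confusion: metrics.ConfusionMatrix
    val_accuracy: float


def synthetic_recovery(
    seed: int = 1,
    n_train_videos: int = 36,
    patches_per_class: int = 100,
    n_eval_videos: int = 18,
    eval_patches_per_class: int = 30,
    n_detect_videos: int = 18,
    max_epochs: int = 14,
    duration: float = 1.5,
    fps: float = 2.0,
) -> RecoveryResult:
    """Run the full synthetic study at desk scale.

    Training cohort: ``n_train_videos`` scenes cycling through the nine class
    archetypes, ``patches_per_class`` labeled patches. The classifier trains
    on five of six video groups with the sixth as the validation checkpoint
    set. Patch evaluation uses patches sampled from a disjoint cohort of new
    videos (a stricter hold-out than a held-out group). Detection evaluation
    scores frames of an easy-regime cohort by breakup-tile count.
    """
    # --- training cohort ---
    specs = scene.default_cohort(
        n_train_videos, seed=substream(seed, "train-cohort").integers(2**31),
        duration=duration, fps=fps,
    )
    videos = [scene.render_video(s) for s in specs]
    records, shortfall = scene.emit_labeled_patches(
        videos, patches_per_class, substream(seed, "train-patches")
    )
    if shortfall:
        raise RuntimeError(f"training cohort could not supply all classes: {shortfall}")
    manifest = Manifest(records)
    assignment = assign_groups(manifest, k=6, seed=seed)
    # validation group = the rotation's fold-0 validation; train on the rest
    val_group = rotation_plan(6).folds[0][1]
    train = [r for r in records if assignment.group_of_video[r.video_id] != val_group]
    val = [r for r in records if assignment.group_of_video[r.video_id] == val_group]

    backbone = RandomConvBackbone(seed=0)
    config = TrainConfig(max_epochs=max_epochs, seed=seed)
    model, history = train_head(train, val, backbone, config)

    # --- patch-level recovery on unseen videos ---
    eval_specs = scene.default_cohort(
        n_eval_videos, seed=substream(seed, "eval-cohort").integers(2**31),
        duration=duration, fps=fps,
    )
    eval_videos = [scene.render_video(s) for s in eval_specs]
    eval_records, _ = scene.emit_labeled_patches(
        eval_videos, eval_patches_per_class, substream(seed, "eval-patches")
    )
    probs = classify_patches(model, backbone, np.stack([r.image for r in eval_records]))
    predicted = [CLASSES[i] for i in probs.argmax(axis=1)]
    actual = [r.label for r in eval_records]
    cm = metrics.confusion(actual, predicted)
    patch_acc = metrics.per_class_metrics(cm).attrs["accuracy"]

    # --- frame-level detection on an easy-regime cohort ---
    detect_specs = scene.default_cohort(
        n_detect_videos, seed=substream(seed, "detect-cohort").integers(2**31),
        duration=duration, fps=fps, easy=True,
    )
    detect_videos = [scene.render_video(s) for s in detect_specs]
    samples = scene.emit_labeled_frames(detect_videos, 3, substream(seed, "detect-frames"))
    scores: list[float] = []
    labels: list[bool] = []
    for s in samples:
        tile_labels, _, _ = detect.classify_frame(s.frame.image, model, backbone)
        scores.append(detect.frame_score(tile_labels))
        labels.append(s.label)
    roc = metrics.roc_auc(scores, labels)
    sens, spec = metrics.operating_point(scores, labels, 1)
    return RecoveryResult(
        patch_accuracy=float(patch_acc),
        n_eval_patches=len(eval_records),
        auc=float(roc.auc),
        n_frames=len(samples),
        n_positive_frames=int(sum(labels)),
        sensitivity_at_1=sens,
        specificity_at_1=spec,
        scores=scores,
        labels=labels,
        confusion=cm,
        val_accuracy=float(history.val_accuracy.max()),
    )
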