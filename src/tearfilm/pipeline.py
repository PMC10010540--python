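"""End-to-end pipeline commands: simulate, split, train/evaluate, detect/evaluate.

Every command is a pure function of (config, seed): stochastic stages draw
from named substreams of the single top-level seed, reports embed the exact
configuration used, and re-running a command reproduces its outputs
byte-for-byte.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
import yaml

from ._util import substream
from . import crossval, detect, metrics, scene
from .data import CLASSES, Manifest, PatchRecord, load_manifest, save_manifest
from .model import RandomConvBackbone, TrainConfig, load_model, save_model, train_head
from .optics import OpticalModel

__all__ = ["RunConfig", "cmd_simulate", "cmd_split", "cmd_train_eval", "cmd_detect_eval"]


@dataclass
class SimulateConfig:
    n_videos: int = 12
    duration: float = 2.0
    fps: float = 2.0
    frame_size: tuple[int, int] = (640, 480)
    patches_per_class: int = 30
    max_frames_per_video: int = 40
    easy: bool = False


@dataclass
class RunConfig:
    seed: int = 0
    simulate: SimulateConfig = field(default_factory=SimulateConfig)
    n_groups: int = 6
    max_epochs: int = 30
    batch_size: int = 20
    learning_rate: float = 1e-3
    backbone_seed: int = 0
    min_breakup_tiles: int = 1
    score_mode: str = "count"  # or "proba"
    ci_method: str = "delong"

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        path = Path(path)
        raw = (
            json.loads(path.read_text())
            if path.suffix == ".json"
            else yaml.safe_load(path.read_text())
        )
        return cls.from_dict(raw or {})

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        sim_raw = dict(raw.pop("simulate", {}))
        known_sim = set(SimulateConfig.__dataclass_fields__)
        bad = set(sim_raw) - known_sim
        if bad:
            raise ValueError(f"unknown simulate config keys: {sorted(bad)}")
        known = set(cls.__dataclass_fields__) - {"simulate"}
        bad = set(raw) - known
        if bad:
            raise ValueError(f"unknown config keys: {sorted(bad)}")
        if "frame_size" in sim_raw:
            sim_raw["frame_size"] = tuple(sim_raw["frame_size"])
        return cls(simulate=SimulateConfig(**sim_raw), **raw)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["simulate"]["frame_size"] = list(d["simulate"]["frame_size"])
        return d


def _write_png(path: Path, image: np.ndarray) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    iio.imwrite(path, (np.clip(image, 0.0, 1.0) * 255).round().astype(np.uint8))


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _dump_json(obj, path: Path) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def cmd_simulate(config: RunConfig, out_dir: str | Path) -> dict:
    """Render a synthetic cohort: frames, ground truth, patch and frame manifests.

    Writes ``<video_id>/frame_<i>.png`` plus a JSON ground-truth sidecar per
    video, patch PNGs with ``manifest.csv``, a frame-label ``frames.csv``, and
    a provenance file with content hashes of everything produced.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    sim = config.simulate
    specs = scene.default_cohort(
        sim.n_videos,
        seed=config.seed,
        frame_size=sim.frame_size,
        duration=sim.duration,
        fps=sim.fps,
        easy=sim.easy,
    )
    model = OpticalModel()
    videos = []
    written: list[Path] = []
    for spec in specs:
        video = scene.render_video(spec, model)
        videos.append(video)
        gt = {
            "video_id": spec.video_id,
            "eye_id": spec.eye_id,
            "subject_id": spec.subject_id,
            "background": video.frames[0].truth.background if video.frames else "uniform",
            "frames": [
                {"index": f.index, "t": f.t, "breakup_present": f.truth.breakup_present}
                for f in video.frames
            ],
        }
        for f in video.frames:
            p = out / spec.video_id / f"frame_{f.index:04d}.png"
            _write_png(p, f.image)
            written.append(p)
        gt_path = out / spec.video_id / "truth.json"
        _dump_json(gt, gt_path)
        written.append(gt_path)

    patch_rng = substream(config.seed, "emit-patches")
    records, shortfall = scene.emit_labeled_patches(videos, sim.patches_per_class, patch_rng)
    patch_dir = out / "patches"
    per_label_idx: dict[str, int] = {}
    for rec in records:
        i = per_label_idx.get(rec.label, 0)
        per_label_idx[rec.label] = i + 1
        rel = f"patches/{rec.video_id}_{rec.label}_{i:04d}.png"
        _write_png(out / rel, rec.image)
        rec.path = rel
        written.append(out / rel)
    manifest = Manifest(records)
    save_manifest(manifest, out / "manifest.csv")
    written.append(out / "manifest.csv")

    frame_rng = substream(config.seed, "emit-frames")
    samples = scene.emit_labeled_frames(videos, sim.max_frames_per_video, frame_rng)
    frames_df = pd.DataFrame(
        [
            {
                "path": f"{s.video_id}/frame_{s.frame.index:04d}.png",
                "video_id": s.video_id,
                "eye_id": s.eye_id,
                "label": int(s.label),
            }
            for s in samples
        ]
    )
    frames_df.to_csv(out / "frames.csv", index=False)
    written.append(out / "frames.csv")

    provenance = {
        "config": config.to_dict(),
        "patch_shortfall": shortfall,
        "hashes": {str(p.relative_to(out)): _sha256(p) for p in sorted(written)},
    }
    _dump_json(provenance, out / "provenance.json")
    return provenance


def cmd_split(config: RunConfig, manifest_path: str | Path, out_path: str | Path) -> dict:
    """Assign videos to balanced groups and write the assignment + rotation plan."""
    manifest = load_manifest(manifest_path)
    assignment = crossval.assign_groups(manifest, k=config.n_groups, seed=config.seed)
    plan = crossval.rotation_plan(config.n_groups)
    payload = {
        "config": config.to_dict(),
        "group_of_video": assignment.group_of_video,
        "group_class_counts": assignment.group_class_counts,
        "group_eye_counts": assignment.group_eye_counts,
        "rotation": [
            {"training": list(tr), "validation": va, "test": te}
            for tr, va, te in plan.folds
        ],
    }
    _dump_json(payload, Path(out_path))
    return payload


def _evaluate_records(records, mdl, backbone, root) -> metrics.ConfusionMatrix:
    from .model import classify_patches

    actual, predicted = [], []
    batch: list[np.ndarray] = []
    batch_labels: list[str] = []
    for rec in records:
        batch.append(rec.load_image(root))
        batch_labels.append(rec.label)
        if len(batch) == 64:
            probs = classify_patches(mdl, backbone, np.stack(batch))
            predicted += [mdl.class_order[i] for i in probs.argmax(axis=1)]
            actual += batch_labels
            batch, batch_labels = [], []
    if batch:
        probs = classify_patches(mdl, backbone, np.stack(batch))
        predicted += [mdl.class_order[i] for i in probs.argmax(axis=1)]
        actual += batch_labels
    return metrics.confusion(actual, predicted)


def cmd_train_eval(
    config: RunConfig,
    manifest_path: str | Path,
    out_dir: str | Path,
    folds: list[int] | None = None,
) -> dict:
    """Grouped cross-validation: train a head per fold and evaluate on its test group.

    Writes one model per fold plus a single JSON report with per-fold and
    pooled metrics. ``folds`` restricts which rotation folds run (default all).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest_path = Path(manifest_path)
    manifest = load_manifest(manifest_path)
    if not manifest.records:
        raise ValueError(f"manifest {manifest_path} is empty")
    root = manifest_path.parent
    assignment = crossval.assign_groups(manifest, k=config.n_groups, seed=config.seed)
    plan = crossval.rotation_plan(config.n_groups)
    backbone = RandomConvBackbone(seed=config.backbone_seed)
    fold_ids = list(range(len(plan.folds))) if folds is None else list(folds)

    per_fold = []
    pooled: metrics.ConfusionMatrix | None = None
    for fi in fold_ids:
        train, val, test = crossval.materialize_fold(manifest, assignment, plan, fi)
        tc = TrainConfig(
            batch_size=config.batch_size,
            max_epochs=config.max_epochs,
            learning_rate=config.learning_rate,
            seed=config.seed + fi,
        )
        mdl, history = train_head(train, val, backbone, tc, root=root)
        save_model(mdl, out / f"fold{fi}_model.npz", tc)
        history.to_csv(out / f"fold{fi}_history.csv", index=False)
        cm = _evaluate_records(test, mdl, backbone, root)
        pooled = cm if pooled is None else pooled + cm
        table = metrics.per_class_metrics(cm)
        binary = metrics.aggregate_binary(cm)
        per_fold.append(
            {
                "fold": fi,
                "test_group": plan.folds[fi][2],
                "n_train": len(train),
                "n_val": len(val),
                "n_test": len(test),
                "accuracy": table.attrs["accuracy"],
                "binary_accuracy": binary.accuracy,
                "sensitivity": binary.sensitivity,
                "specificity": binary.specificity,
                "confusion": cm.counts.tolist(),
            }
        )

    pooled_table = metrics.per_class_metrics(pooled)
    pooled_binary = metrics.aggregate_binary(pooled)
    report = {
        "config": config.to_dict(),
        "class_order": list(CLASSES),
        "group_class_counts": assignment.group_class_counts,
        "group_eye_counts": assignment.group_eye_counts,
        "folds": per_fold,
        "pooled": {
            "confusion": pooled.counts.tolist(),
            "accuracy": pooled_table.attrs["accuracy"],
            "per_class": {
                c: {
                    k: (None if pd.isna(v) else float(v))
                    for k, v in pooled_table.loc[c].items()
                }
                for c in CLASSES
            },
            "binary": {
                "accuracy": pooled_binary.accuracy,
                "sensitivity": pooled_binary.sensitivity,
                "specificity": pooled_binary.specificity,
            },
        },
    }
    if len(per_fold) >= 2:
        summary = metrics.crossval_summary(
            {
                k: [f[k] for f in per_fold]
                for k in ("accuracy", "binary_accuracy", "sensitivity", "specificity")
            }
        )
        report["crossval_summary"] = {
            k: {"mean": float(summary.loc[k, "mean"]), "sd": float(summary.loc[k, "sd"])}
            for k in summary.index
        }
    _dump_json(report, out / "train_eval_report.json")
    return report


def cmd_detect_eval(
    config: RunConfig,
    model_path: str | Path,
    frames_csv: str | Path,
    out_dir: str | Path,
    overlay_dir: str | Path | None = None,
) -> dict:
    """Score labeled frames, write the per-frame CSV and the ROC/AUC report."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    frames_csv = Path(frames_csv)
    df = pd.read_csv(frames_csv)
    if df.empty:
        raise ValueError(f"no labeled frames in {frames_csv}")
    mdl = load_model(model_path)
    backbone = RandomConvBackbone(seed=config.backbone_seed)
    root = frames_csv.parent
    rows = []
    scores = []
    labels = []
    for row in df.itertuples(index=False):
        img = iio.imread(root / row.path).astype(float) / 255.0
        tile_labels, tile_probs, grid = detect.classify_frame(img, mdl, backbone)
        decision = detect.decide_frame(tile_labels, config.min_breakup_tiles)
        score = (
            detect.frame_score_proba(tile_probs, mdl.class_order)
            if config.score_mode == "proba"
            else decision.score
        )
        scores.append(score)
        labels.append(bool(row.label))
        rows.append(
            {
                "frame_path": row.path,
                "video_id": row.video_id,
                "label": int(row.label),
                "score": score,
                "decision": int(decision.breakup),
                **{f"tiles_{c}": decision.per_class_tile_counts[c] for c in CLASSES},
            }
        )
        if overlay_dir is not None:
            overlay = detect.render_overlay(img, tile_labels, grid)
            _write_png(Path(overlay_dir) / Path(row.path).name, overlay)
    pd.DataFrame(rows).to_csv(out / "frame_scores.csv", index=False)

    labels_arr = np.array(labels)
    if labels_arr.all() or not labels_arr.any():
        raise ValueError(
            "frame labels contain a single class; ROC needs both breakup and "
            "non-breakup frames — regenerate the evaluation set with both"
        )
    roc = metrics.roc_auc(scores, labels_arr)
    ci = metrics.auc_ci95(scores, labels_arr, method=config.ci_method, seed=config.seed)
    sens, spec = metrics.operating_point(scores, labels_arr, config.min_breakup_tiles)
    pd.DataFrame(roc.points, columns=["fpr", "tpr"]).to_csv(out / "roc_points.csv", index=False)
    report = {
        "config": config.to_dict(),
        "n_frames": len(labels),
        "n_positive": int(labels_arr.sum()),
        "auc": roc.auc,
        "ci95": [ci[0], ci[1]],
        "operating_threshold": config.min_breakup_tiles,
        "sensitivity": sens,
        "specificity": spec,
    }
    _dump_json(report, out / "detect_eval_report.json")
    return report
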