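"""Video-grouped six-fold cross-validation.

All patches extracted from one video (and, by default, from both eyes of one
subject) are kept in the same group, so no fold ever trains and tests on
material from the same video. Groups are labeled A..F and rotate through
train/validation/test roles fold by fold.
"""

from __future__ import annotations

import string
from dataclasses import dataclass

import numpy as np

from ._util import stable_hash32
from .data import CLASSES, Manifest, PatchRecord

__all__ = [
    "FoldAssignment",
    "RotationPlan",
    "assign_groups",
    "rotation_plan",
    "materialize_fold",
    "max_class_imbalance",
]


@dataclass
class FoldAssignment:
    group_of_video: dict[str, str]
    group_class_counts: dict[str, dict[str, int]]
    group_eye_counts: dict[str, int]

    @property
    def groups(self) -> list[str]:
        return sorted(self.group_class_counts)


@dataclass
class RotationPlan:
    """Per-fold (training groups, validation group, test group) rotation."""

    folds: list[tuple[tuple[str, ...], str, str]]


def assign_groups(
    manifest: Manifest,
    k: int = 6,
    seed: int = 0,
    tolerance: float = 0.30,
    group_by_subject: bool = True,
) -> FoldAssignment:
    """Greedy balanced assignment of videos to ``k`` groups.

    Assignment units (subjects by default, so both eyes of one subject share a
    group; videos if ``group_by_subject`` is false) are ordered by descending
    patch count and placed, one by one, into the group where they least
    increase the per-class squared class-count imbalance. Deterministic for a
    fixed seed and invariant to the order of manifest records.

    ``tolerance`` is the advisory bound on the relative per-class deviation
    across groups; the achieved imbalance is available via
    :func:`max_class_imbalance`.
    """
    if k < 2:
        raise ValueError("need at least 2 groups")
    if not manifest.records:
        raise ValueError("manifest is empty")
    unit_of = (lambda r: r.subject_id) if group_by_subject else (lambda r: r.video_id)
    units: dict[str, dict[str, int]] = {}
    videos_of_unit: dict[str, set[str]] = {}
    eyes_of_unit: dict[str, set[str]] = {}
    for rec in manifest.records:
        u = unit_of(rec)
        units.setdefault(u, {c: 0 for c in CLASSES})[rec.label] += 1
        videos_of_unit.setdefault(u, set()).add(rec.video_id)
        eyes_of_unit.setdefault(u, set()).add(rec.eye_id)
    if len(units) < k:
        raise ValueError(f"only {len(units)} assignment units for {k} groups")

    labels = list(string.ascii_uppercase[:k])
    # largest-first, seed-hashed tie-break -> deterministic and order-invariant
    order = sorted(units, key=lambda u: (-sum(units[u].values()), stable_hash32(seed, u)))
    counts = {g: np.zeros(len(CLASSES), dtype=float) for g in labels}
    n_units = {g: 0 for g in labels}
    group_of_unit: dict[str, str] = {}
    for u in order:
        v = np.array([units[u][c] for c in CLASSES], dtype=float)
        best, best_cost = None, None
        for g in labels:
            cost = float(np.sum((counts[g] + v) ** 2))
            key = (cost, n_units[g], g)
            if best_cost is None or key < best_cost:
                best, best_cost = g, key
        group_of_unit[u] = best
        counts[best] += v
        n_units[best] += 1

    group_of_video = {
        vid: group_of_unit[u] for u, vids in videos_of_unit.items() for vid in vids
    }
    group_class_counts = {
        g: {c: int(counts[g][i]) for i, c in enumerate(CLASSES)} for g in labels
    }
    group_eye_counts = {g: 0 for g in labels}
    for u, g in group_of_unit.items():
        group_eye_counts[g] += len(eyes_of_unit[u])
    return FoldAssignment(group_of_video, group_class_counts, group_eye_counts)


def max_class_imbalance(assignment: FoldAssignment) -> float:
    """Largest relative deviation of any per-group class count from the class mean."""
    groups = assignment.groups
    worst = 0.0
    for c in CLASSES:
        vals = np.array([assignment.group_class_counts[g][c] for g in groups], float)
        mean = vals.mean()
        if mean > 0:
            worst = max(worst, float(np.max(np.abs(vals - mean)) / mean))
    return worst


def rotation_plan(k: int = 6) -> RotationPlan:
    """Cyclic train/validation/test rotation over groups A..k.

    Fold 1 trains on {A, B, C, D}, validates on E, tests on F; each later fold
    rotates the group sequence right by one, so every group serves as test
    exactly once and as validation exactly once.
    """
    if k < 3:
        raise ValueError("rotation needs at least 3 groups (train/validation/test)")
    labels = list(string.ascii_uppercase[:k])
    folds = []
    for i in range(k):
        order = labels[-i:] + labels[:-i] if i else list(labels)
        folds.append((tuple(order[: k - 2]), order[k - 2], order[k - 1]))
    return RotationPlan(folds)


def materialize_fold(
    manifest: Manifest,
    assignment: FoldAssignment,
    plan: RotationPlan,
    fold_index: int,
) -> tuple[list[PatchRecord], list[PatchRecord], list[PatchRecord]]:
    """Split manifest records into (train, validation, test) for one fold (0-based)."""
    if not (0 <= fold_index < len(plan.folds)):
        raise ValueError(f"fold_index {fold_index} out of range")
    train_groups, val_group, test_group = plan.folds[fold_index]
    train, val, test = [], [], []
    for rec in manifest.records:
        g = assignment.group_of_video[rec.video_id]
        if g == test_group:
            test.append(rec)
        elif g == val_group:
            val.append(rec)
        elif g in train_groups:
            train.append(rec)
        else:
            raise ValueError(f"video {rec.video_id} group {g} not in the fold plan")
    return train, val, test
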