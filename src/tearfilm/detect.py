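"""Frame-level tear-breakup detection by overlapping-tile classification.

A centered 384×384 region of interest (where the cornea fills the frame) is
divided into 96×96 tiles with a 48-px stride, so adjacent tiles overlap by
half a tile and small ruptures cannot slip between tile boundaries. Every
tile is classified by the patch model; if the number of tiles called
``area``/``spot``/``line`` reaches a configurable minimum, the frame is
declared to contain tear breakup. The integer breakup-tile count is the
natural sweepable score for ROC analysis.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data import BREAKUP_CLASSES, CLASSES, PATCH_SIZE
from .model import Backbone, HeadModel, classify_patches

__all__ = [
    "TileGrid",
    "FrameDecision",
    "central_roi",
    "tile_frame",
    "classify_frame",
    "decide_frame",
    "frame_score",
    "frame_score_proba",
    "render_overlay",
]

ROI_SIZE = 384
DEFAULT_STRIDE = 48

OVERLAY_COLORS = {  # breakup classes only
    "area": np.array([0.55, 0.15, 0.75]),  # purple
    "spot": np.array([0.15, 0.35, 0.95]),  # blue
    "line": np.array([0.15, 0.80, 0.30]),  # green
}


@dataclass
class TileGrid:
    roi_origin: tuple[int, int]
    roi_size: int
    patch_size: int
    stride: int
    tiles: list[tuple[int, int]]  # origins (row, col) relative to the ROI, row-major

    @property
    def per_axis(self) -> int:
        return (self.roi_size - self.patch_size) // self.stride + 1


@dataclass
class FrameDecision:
    breakup: bool
    breakup_tile_count: int
    per_class_tile_counts: dict[str, int]
    score: int
    tile_classes: list[str]


def central_roi(frame: np.ndarray, size: int = ROI_SIZE) -> tuple[np.ndarray, tuple[int, int]]:
    """Centered axis-aligned crop (floor rounding); origin for 640×480 is (48, 128)."""
    h, w = frame.shape[:2]
    if h < size or w < size:
        raise ValueError(f"frame {h}x{w} is smaller than the {size}x{size} ROI")
    r0 = (h - size) // 2
    c0 = (w - size) // 2
    return frame[r0 : r0 + size, c0 : c0 + size], (r0, c0)


def tile_frame(
    roi_size: int = ROI_SIZE,
    patch_size: int = PATCH_SIZE,
    stride: int = DEFAULT_STRIDE,
    roi_origin: tuple[int, int] = (0, 0),
) -> TileGrid:
    """Row-major grid of overlapping tile origins; 7×7 = 49 for the default geometry."""
    if patch_size > roi_size:
        raise ValueError("patch_size exceeds roi_size")
    rem = (roi_size - patch_size) % stride
    if rem:
        raise ValueError(
            f"(roi_size - patch_size) must be divisible by stride; remainder {rem}"
        )
    n = (roi_size - patch_size) // stride + 1
    tiles = [(r * stride, c * stride) for r in range(n) for c in range(n)]
    return TileGrid(roi_origin, roi_size, patch_size, stride, tiles)


def classify_frame(
    frame: np.ndarray,
    model: HeadModel,
    backbone: Backbone,
    patch_size: int = PATCH_SIZE,
    stride: int = DEFAULT_STRIDE,
    roi_size: int = ROI_SIZE,
) -> tuple[list[str], np.ndarray, TileGrid]:
    """Classify every tile of the frame's central ROI.

    Returns (per-tile labels in row-major order, per-tile probability matrix,
    the tile grid).
    """
    roi, origin = central_roi(frame, roi_size)
    grid = tile_frame(roi_size, patch_size, stride, origin)
    patches = np.stack(
        [roi[r : r + patch_size, c : c + patch_size] for r, c in grid.tiles]
    )
    probs = classify_patches(model, backbone, patches)
    labels = [model.class_order[i] for i in probs.argmax(axis=1)]
    return labels, probs, grid


def frame_score(tile_labels: list[str]) -> int:
    """Number of tiles labeled with a breakup class (the ROC sweep statistic)."""
    return sum(1 for lab in tile_labels if lab in BREAKUP_CLASSES)


def frame_score_proba(tile_probs: np.ndarray, class_order=CLASSES) -> float:
    """Alternative continuous score: summed breakup-class probability over tiles."""
    idx = [i for i, c in enumerate(class_order) if c in BREAKUP_CLASSES]
    return float(np.asarray(tile_probs)[:, idx].sum())


def decide_frame(tile_labels: list[str], min_breakup_tiles: int = 1) -> FrameDecision:
    """Frame verdict: breakup iff the breakup-tile count reaches the minimum (inclusive)."""
    if min_breakup_tiles < 1:
        raise ValueError("min_breakup_tiles must be >= 1")
    per_class = {c: 0 for c in CLASSES}
    for lab in tile_labels:
        per_class[lab] += 1
    count = frame_score(tile_labels)
    return FrameDecision(
        breakup=count >= min_breakup_tiles,
        breakup_tile_count=count,
        per_class_tile_counts=per_class,
        score=count,
        tile_classes=list(tile_labels),
    )


def render_overlay(
    frame: np.ndarray,
    tile_labels: list[str],
    grid: TileGrid,
    alpha: float = 0.45,
) -> np.ndarray:
    """Tint breakup tiles: purple for area, blue for spot, green for line.

    Tiles of the same class are merged into one mask before blending, so
    overlapping tiles are tinted exactly once. Where classes overlap, the
    morphology listed first in (area, spot, line) takes precedence.
    """
    if len(tile_labels) != len(grid.tiles):
        raise ValueError("tile labels do not align with the grid")
    out = np.asarray(frame, dtype=float).copy()
    h, w = out.shape[:2]
    claimed = np.zeros((h, w), dtype=bool)
    r_off, c_off = grid.roi_origin
    for cls in BREAKUP_CLASSES:
        mask = np.zeros((h, w), dtype=bool)
        for lab, (r, c) in zip(tile_labels, grid.tiles):
            if lab == cls:
                mask[
                    r_off + r : r_off + r + grid.patch_size,
                    c_off + c : c_off + c + grid.patch_size,
                ] = True
        mask &= ~claimed
        if mask.any():
            out[mask] = (1 - alpha) * out[mask] + alpha * OVERLAY_COLORS[cls]
            claimed |= mask
    return np.clip(out, 0.0, 1.0)
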