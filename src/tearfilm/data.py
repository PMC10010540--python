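"""Patch manifests, training-time augmentation, and input-resolution preparation.

The classification unit is a 96×96-pixel RGB patch labeled with one of nine
classes: three breakup morphologies (``area``, ``spot``, ``line``) and six
non-breakup appearances (``uniform``, ``interference_fringe``,
``bright_reflection``, ``particle``, ``eyelash``, ``eyelid``). Each record
carries video/eye/subject provenance so that cross-validation can group by
video and avoid leakage.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from skimage.transform import AffineTransform, resize, warp

__all__ = [
    "CLASSES",
    "BREAKUP_CLASSES",
    "NONBREAKUP_CLASSES",
    "REFERENCE_CLASS_COUNTS",
    "PATCH_SIZE",
    "INPUT_SIZE",
    "PatchRecord",
    "Manifest",
    "AugmentationPolicy",
    "load_manifest",
    "save_manifest",
    "class_counts",
    "augment",
    "resize_to_input",
    "reference_manifest",
]

BREAKUP_CLASSES = ("area", "spot", "line")
NONBREAKUP_CLASSES = (
    "uniform",
    "interference_fringe",
    "bright_reflection",
    "particle",
    "eyelash",
    "eyelid",
)
CLASSES = BREAKUP_CLASSES + NONBREAKUP_CLASSES

#: Per-class patch counts of the clinical training cohort this package emulates
#: (350 eyes, 9,089 patches); used as the default shape for full-scale fixtures.
REFERENCE_CLASS_COUNTS = {
    "area": 643,
    "spot": 684,
    "line": 877,
    "uniform": 1099,
    "interference_fringe": 1201,
    "bright_reflection": 1046,
    "particle": 1230,
    "eyelash": 1119,
    "eyelid": 1190,
}

PATCH_SIZE = 96
INPUT_SIZE = 224

_MANIFEST_COLUMNS = ["path", "class", "video_id", "eye_id", "subject_id"]


@dataclass
class PatchRecord:
    """One labeled 96×96 patch with provenance; image may be in memory or on disk."""

    label: str
    video_id: str
    eye_id: str
    subject_id: str
    path: str = ""
    image: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.label not in CLASSES:
            raise ValueError(f"unknown class label {self.label!r}")
        if self.image is not None:
            self.image = np.asarray(self.image, dtype=float)
            if self.image.shape != (PATCH_SIZE, PATCH_SIZE, 3):
                raise ValueError(
                    f"patch image must be {PATCH_SIZE}x{PATCH_SIZE}x3, got {self.image.shape}"
                )

    def load_image(self, root: str | Path | None = None) -> np.ndarray:
        if self.image is not None:
            return self.image
        import imageio.v3 as iio

        p = Path(root) / self.path if root is not None else Path(self.path)
        arr = iio.imread(p).astype(float) / 255.0
        if arr.shape != (PATCH_SIZE, PATCH_SIZE, 3):
            raise ValueError(f"patch file {p} has shape {arr.shape}")
        return arr


@dataclass
class Manifest:
    records: list[PatchRecord] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.records)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Manifest):
            return NotImplemented
        key = lambda r: (r.path, r.label, r.video_id, r.eye_id, r.subject_id)
        return [key(r) for r in self.records] == [key(r) for r in other.records]

    @property
    def class_counts(self) -> dict[str, int]:
        return class_counts(self)[0]


def class_counts(manifest: Manifest) -> tuple[dict[str, int], int]:
    """Per-class tallies and the total record count."""
    counts = {c: 0 for c in CLASSES}
    for rec in manifest.records:
        counts[rec.label] += 1
    return counts, len(manifest.records)


def save_manifest(manifest: Manifest, path: str | Path) -> None:
    df = pd.DataFrame(
        [
            {
                "path": r.path,
                "class": r.label,
                "video_id": r.video_id,
                "eye_id": r.eye_id,
                "subject_id": r.subject_id,
            }
            for r in manifest.records
        ],
        columns=_MANIFEST_COLUMNS,
    )
    df.to_csv(path, index=False)


def load_manifest(path: str | Path, check_files: bool = False) -> Manifest:
    """Load a patch manifest CSV; validates columns and class labels.

    With ``check_files=True`` every referenced image file must exist (paths are
    resolved relative to the manifest's directory).
    """
    path = Path(path)
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in _MANIFEST_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"manifest {path} is missing columns: {missing}")
    records = []
    for i, row in enumerate(df.itertuples(index=False)):
        label = row[df.columns.get_loc("class")]
        if label not in CLASSES:
            raise ValueError(f"manifest {path} row {i}: unknown class label {label!r}")
        rec = PatchRecord(
            label=label,
            video_id=row.video_id,
            eye_id=row.eye_id,
            subject_id=row.subject_id,
            path=row.path,
        )
        if check_files and not (path.parent / rec.path).exists():
            raise FileNotFoundError(f"manifest {path} row {i}: missing file {rec.path}")
        records.append(rec)
    return Manifest(records)


@dataclass
class AugmentationPolicy:
    """Training-time augmentation: scale, horizontal/vertical shift, horizontal flip.

    Vertical flipping is never applied — some breakup morphologies have a
    vertical shape signature (tear fluid moves upward after a blink) that a
    vertical flip would corrupt.
    """

    scale_range: tuple[float, float] = (0.9, 1.1)
    shift_range: float = 0.1
    hflip_probability: float = 0.5
    vflip_enabled: bool = False

    def __post_init__(self) -> None:
        if self.vflip_enabled:
            raise ValueError("vertical flipping must remain disabled")
        if not (0.0 <= self.hflip_probability <= 1.0):
            raise ValueError("hflip_probability must be in [0, 1]")
        if self.scale_range[0] <= 0 or self.scale_range[1] < self.scale_range[0]:
            raise ValueError("invalid scale_range")

    @classmethod
    def identity(cls) -> "AugmentationPolicy":
        return cls(scale_range=(1.0, 1.0), shift_range=0.0, hflip_probability=0.0)


def augment(
    image: np.ndarray, policy: AugmentationPolicy, rng: np.random.Generator
) -> np.ndarray:
    """Apply one random draw of the policy to a 96×96×3 patch.

    Scaling is about the patch center; shifts are a fraction of the side;
    borders are reflection-padded so no synthetic black edges (which would
    mimic the eyelid class) are introduced. Output shape equals input shape.
    """
    image = np.asarray(image, dtype=float)
    if image.ndim != 3 or image.shape[2] != 3:
        raise ValueError("expected an HxWx3 patch")
    h, w = image.shape[:2]
    s = rng.uniform(*policy.scale_range)
    tx = rng.uniform(-policy.shift_range, policy.shift_range) * w
    ty = rng.uniform(-policy.shift_range, policy.shift_range) * h
    flip = rng.random() < policy.hflip_probability
    if s == 1.0 and tx == 0.0 and ty == 0.0:
        out = image
    else:
        # inverse map for warp: center scale + translation
        cx, cy = (w - 1) / 2.0, (h - 1) / 2.0
        fwd = (
            AffineTransform(translation=(-cx, -cy))
            + AffineTransform(scale=(s, s))
            + AffineTransform(translation=(cx + tx, cy + ty))
        )
        out = warp(image, fwd.inverse, mode="reflect", order=1, preserve_range=True)
    if flip:
        out = out[:, ::-1, :]
    return np.ascontiguousarray(out)


def resize_to_input(patch: np.ndarray, size: int = INPUT_SIZE) -> np.ndarray:
    """Bilinear rescale of a 96×96×3 patch to the classifier input resolution."""
    patch = np.asarray(patch, dtype=float)
    if patch.shape != (PATCH_SIZE, PATCH_SIZE, 3):
        raise ValueError(f"expected a {PATCH_SIZE}x{PATCH_SIZE}x3 patch, got {patch.shape}")
    return resize(patch, (size, size, 3), order=1, mode="reflect",
                  anti_aliasing=False, preserve_range=True)


def reference_manifest(
    counts: dict[str, int] | None = None,
    n_videos: int = 350,
    seed: int = 0,
    eyes_per_subject: float = 2.0,
) -> Manifest:
    """Build a metadata-only manifest with the given per-class patch counts.

    Patches are spread over ``n_videos`` synthetic videos (one video per eye;
    subjects contribute up to two eyes) so that grouping and cross-validation
    can be exercised at the full cohort scale without rendering any pixels.
    """
    from ._util import substream

    if counts is None:
        counts = REFERENCE_CLASS_COUNTS
    rng = substream(seed, "reference-manifest")
    videos = []
    for v in range(n_videos):
        subject = v // int(round(eyes_per_subject)) if eyes_per_subject else v
        videos.append((f"vid{v:04d}", f"eye{v:04d}", f"sub{subject:04d}"))
    # random owners, then patch up so every video owns at least one record
    owners = {label: rng.integers(0, n_videos, size=n) for label, n in counts.items()}
    covered = np.zeros(n_videos, dtype=bool)
    for arr in owners.values():
        covered[arr] = True
    missing = np.flatnonzero(~covered)
    if missing.size:
        big = max(counts, key=counts.get)
        spare = np.flatnonzero(np.bincount(owners[big], minlength=n_videos) > 1)
        idx = 0
        for v in missing:
            donor = spare[idx % spare.size]
            pos = int(np.flatnonzero(owners[big] == donor)[0])
            owners[big][pos] = v
            idx += 1
    records: list[PatchRecord] = []
    for label, n in counts.items():
        owner = owners[label]
        for i, v in enumerate(owner):
            vid, eye, sub = videos[v]
            records.append(
                PatchRecord(
                    label=label,
                    video_id=vid,
                    eye_id=eye,
                    subject_id=sub,
                    path=f"{vid}/{label}_{i:05d}.png",
                )
            )
    return Manifest(records)
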