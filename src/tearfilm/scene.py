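"""Synthetic tear-film video generator with per-pixel ground truth.

Each scene is a latent lipid-thickness field rendered through the thin-film
optics model, plus three kinds of structure:

* breakup events — film ruptures that appear after a simulated blink
  (t = 0 at full eye opening) and grow over time, in three morphologies:
  ``area`` (broad irregular exposed region), ``spot`` (circular rupture, which
  may elongate vertically as tear fluid moves upward), and ``line`` (vertical
  linear rupture);
* background styles — a smooth low-amplitude field reads as the ``uniform``
  class, while strong thickness gradients/sinusoids produce visible colored
  ``interference_fringe`` stripes;
* image-space confounders — ``bright_reflection`` (saturated highlights, as
  with intraocular lenses), ``particle`` (dark oil/debris specks), ``eyelash``
  (thin dark curves entering from the frame border), and ``eyelid`` (eyelid
  arcs and the circular camera mask).

Every frame carries definitional ground truth: the rupture footprint per
pattern, each confounder's footprint, and a frame-level breakup label that is
true iff any rupture pixel falls inside the central 384×384 detection region.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter

from ._util import stable_hash32, substream
from .data import BREAKUP_CLASSES, PATCH_SIZE, PatchRecord
from .optics import OpticalModel, ThicknessMap, render_interference

__all__ = [
    "BaseFieldSpec",
    "BreakupEvent",
    "ConfounderSpec",
    "SceneSpec",
    "Frame",
    "Video",
    "sample_base_thickness",
    "apply_breakup",
    "event_footprint",
    "composite_confounders",
    "render_video",
    "label_patch",
    "emit_labeled_patches",
    "emit_labeled_frames",
    "default_cohort",
]

ROI_SIZE = 384

OVERLAY_KINDS = ("bright_reflection", "particle", "eyelash", "eyelid")
BACKGROUND_KINDS = ("uniform", "interference_fringe")


@dataclass
class BaseFieldSpec:
    """Smooth random lipid-thickness field: mean and fluctuation, in nm."""

    mean: float = 120.0
    amplitude: float = 15.0
    correlation_length: float = 80.0  # px


@dataclass
class BreakupEvent:
    pattern: str
    onset: float  # seconds after full eye opening
    center: tuple[float, float]  # (row, col) px
    initial_size: float  # px (spot/area radius; line width)
    growth_rate: float = 0.0  # px/s
    elongation_rate: float = 0.0  # px/s, vertical stretching

    def __post_init__(self) -> None:
        if self.pattern not in BREAKUP_CLASSES:
            raise ValueError(f"unknown breakup pattern {self.pattern!r}")
        if self.initial_size < 0 or self.growth_rate < 0 or self.elongation_rate < 0:
            raise ValueError("sizes and rates must be non-negative")


@dataclass
class ConfounderSpec:
    kind: str
    geometry: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.kind not in OVERLAY_KINDS + BACKGROUND_KINDS:
            raise ValueError(f"unknown confounder kind {self.kind!r}")


@dataclass
class SceneSpec:
    """One synthetic video of one eye: 30 s at 30 fps, 640×480, by default."""

    video_id: str
    eye_id: str = ""
    subject_id: str = ""
    duration: float = 30.0
    fps: float = 30.0
    frame_size: tuple[int, int] = (640, 480)  # (width, height)
    base_field: BaseFieldSpec = field(default_factory=BaseFieldSpec)
    events: list[BreakupEvent] = field(default_factory=list)
    confounders: list[ConfounderSpec] = field(default_factory=list)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.duration <= 0 or self.fps <= 0:
            raise ValueError("duration and fps must be positive")
        for ev in self.events:
            if not (0 <= ev.onset <= self.duration):
                raise ValueError("event onset must lie within the video duration")
        if not self.eye_id:
            self.eye_id = f"{self.video_id}-eye"
        if not self.subject_id:
            self.subject_id = f"{self.video_id}-sub"

    @property
    def shape(self) -> tuple[int, int]:
        w, h = self.frame_size
        return (h, w)

    @property
    def n_frames(self) -> int:
        return int(round(self.duration * self.fps))


@dataclass
class FrameTruth:
    breakup_present: bool
    masks: dict[str, np.ndarray]  # class -> boolean footprint
    background: str  # "uniform" or "interference_fringe"


@dataclass
class Frame:
    index: int
    t: float
    image: np.ndarray  # (H, W, 3) float32 in [0, 1]
    truth: FrameTruth


@dataclass
class Video:
    spec: SceneSpec
    frames: list[Frame]


def sample_base_thickness(spec: SceneSpec) -> ThicknessMap:
    """Low-pass-filtered Gaussian noise with the configured mean/amplitude/scale."""
    h, w = spec.shape
    bf = spec.base_field
    if bf.amplitude == 0:
        return ThicknessMap(np.full((h, w), float(bf.mean)))
    rng = substream(spec.seed, "base-field", spec.video_id)
    noise = rng.standard_normal((h, w))
    sigma = max(bf.correlation_length / 2.0, 1e-6)
    smooth = gaussian_filter(noise, sigma, mode="reflect")
    sd = smooth.std()
    if sd > 0:
        smooth /= sd
    return ThicknessMap(np.clip(bf.mean + bf.amplitude * smooth, 0.0, None))


def _apply_fringes(thickness: ThicknessMap, spec: SceneSpec) -> None:
    """Add sinusoidal thickness modulation for interference-fringe confounders."""
    h, w = thickness.values.shape
    rr, cc = np.mgrid[0:h, 0:w]
    for conf in spec.confounders:
        if conf.kind != "interference_fringe":
            continue
        g = conf.geometry
        freq = g.get("frequency", 0.02)  # cycles / px
        theta = g.get("orientation", 0.0)  # radians
        amp = g.get("amplitude", 60.0)  # nm
        phase = g.get("phase", 0.0)
        coord = cc * math.cos(theta) + rr * math.sin(theta)
        thickness.values += amp * np.sin(2 * math.pi * freq * coord + phase)
    np.clip(thickness.values, 0.0, None, out=thickness.values)


def _event_metric(event: BreakupEvent, t: float, shape: tuple[int, int]) -> np.ndarray | None:
    """Normalized distance field: <= 1 inside the rupture footprint."""
    if t < event.onset:
        return None
    dt = t - event.onset
    h, w = shape
    rr, cc = np.mgrid[0:h, 0:w]
    r0, c0 = event.center
    if event.pattern == "spot":
        a = max(event.initial_size + event.growth_rate * dt, 1e-6)  # horizontal semi-axis
        b = a + event.elongation_rate * dt  # vertical stretching
        return np.sqrt(((cc - c0) / a) ** 2 + ((rr - r0) / b) ** 2)
    if event.pattern == "line":
        half_w = max(event.initial_size / 2.0 + event.growth_rate * dt, 1e-6)
        half_len = 1.6 * event.initial_size + event.elongation_rate * dt
        dr = np.clip(np.abs(rr - r0) - half_len, 0.0, None)
        dc = np.abs(cc - c0)
        return np.sqrt(dr ** 2 + dc ** 2) / half_w
    # area: irregular blob via angular radius modulation with event-derived phases
    radius = max(event.initial_size + event.growth_rate * dt, 1e-6)
    dist = np.sqrt((rr - r0) ** 2 + (cc - c0) ** 2)
    ang = np.arctan2(rr - r0, cc - c0)
    h1 = stable_hash32("area", event.onset, event.center)
    p1, p2 = (h1 % 628) / 100.0, ((h1 // 628) % 628) / 100.0
    boundary = radius * (1.0 + 0.22 * np.sin(3 * ang + p1) + 0.13 * np.sin(5 * ang + p2))
    return dist / np.clip(boundary, 1e-6, None)


def event_footprint(event: BreakupEvent, t: float, shape: tuple[int, int]) -> np.ndarray:
    """Boolean rupture footprint of an event at time ``t`` on a frame of ``shape``."""
    m = _event_metric(event, t, shape)
    if m is None:
        return np.zeros(shape, dtype=bool)
    return m <= 1.0


def apply_breakup(thickness: ThicknessMap, event: BreakupEvent, t: float) -> ThicknessMap:
    """Rupture the film under an event's footprint at time ``t``.

    Before onset the map is returned unchanged. After onset the footprint is
    added to the rupture mask and the surrounding thickness is thinned toward
    zero over a soft margin, so the rupture edge shows the thin-film color
    banding characteristic of real breakup borders.
    """
    m = _event_metric(event, t, thickness.values.shape)
    if m is None:
        return thickness
    out = thickness.copy()
    margin = 0.5
    factor = np.clip((m - 1.0) / margin, 0.0, 1.0)
    out.values *= factor
    out.rupture_mask |= m <= 1.0
    return out


def _soft_disk(shape, center, radius) -> np.ndarray:
    rr, cc = np.mgrid[0 : shape[0], 0 : shape[1]]
    d2 = (rr - center[0]) ** 2 + (cc - center[1]) ** 2
    return np.clip(1.0 - d2 / max(radius, 1e-6) ** 2, 0.0, 1.0)


def composite_confounders(
    image: np.ndarray,
    confounders: list[ConfounderSpec],
    rng: np.random.Generator | None = None,
    return_footprints: bool = False,
):
    """Draw image-space confounders over a rendered frame, in list order.

    Bright reflections saturate toward white, particles and eyelashes darken,
    and the eyelid/camera mask blacks out everything outside a circular
    aperture plus an eyelid arc. Background kinds (uniform/fringe) act at the
    thickness stage and are no-ops here. Output stays in [0, 1]; footprint
    masks per kind are returned when requested.
    """
    img = np.asarray(image, dtype=float).copy()
    h, w = img.shape[:2]
    footprints: dict[str, np.ndarray] = {}

    def add_fp(kind: str, mask: np.ndarray) -> None:
        if kind in footprints:
            footprints[kind] |= mask
        else:
            footprints[kind] = mask

    for conf in confounders:
        g = conf.geometry
        if conf.kind == "bright_reflection":
            center = g["center"]
            radius = g["radius"]
            intensity = g.get("intensity", 0.85)
            wgt = intensity * _soft_disk((h, w), center, radius) ** 0.5
            img += (1.0 - img) * wgt[:, :, None]
            add_fp(conf.kind, wgt > 0.05)
        elif conf.kind == "particle":
            mask = np.zeros((h, w), dtype=bool)
            soft = np.zeros((h, w))
            radii = g.get("radii")
            for i, center in enumerate(g["centers"]):
                radius = radii[i] if radii is not None else g.get("radius", 3.0)
                s = _soft_disk((h, w), center, radius)
                soft = np.maximum(soft, s)
                mask |= s > 0.0
            img *= (1.0 - g.get("darkness", 0.8) * soft[:, :, None])
            add_fp(conf.kind, mask)
        elif conf.kind == "eyelash":
            pts = np.asarray(g["control_points"], dtype=float)  # 3x(row, col)
            width = g.get("width", 2.5)
            ts = np.linspace(0.0, 1.0, 160)[:, None]
            curve = ((1 - ts) ** 2 * pts[0] + 2 * ts * (1 - ts) * pts[1] + ts ** 2 * pts[2])
            mask = np.zeros((h, w), dtype=bool)
            rr, cc = np.mgrid[0:h, 0:w]
            # coarse bounding box, then exact distance to the sampled polyline
            r_lo = max(int(curve[:, 0].min() - width - 2), 0)
            r_hi = min(int(curve[:, 0].max() + width + 3), h)
            c_lo = max(int(curve[:, 1].min() - width - 2), 0)
            c_hi = min(int(curve[:, 1].max() + width + 3), w)
            if r_hi > r_lo and c_hi > c_lo:
                sub_r = rr[r_lo:r_hi, c_lo:c_hi]
                sub_c = cc[r_lo:r_hi, c_lo:c_hi]
                d2 = np.full(sub_r.shape, np.inf)
                for p in curve:
                    d2 = np.minimum(d2, (sub_r - p[0]) ** 2 + (sub_c - p[1]) ** 2)
                mask[r_lo:r_hi, c_lo:c_hi] = d2 <= (width / 2.0 + 0.5) ** 2
            img[mask] *= 0.12
            add_fp(conf.kind, mask)
        elif conf.kind == "eyelid":
            mask = np.zeros((h, w), dtype=bool)
            rr, cc = np.mgrid[0:h, 0:w]
            if "aperture_radius" in g:
                center = g.get("aperture_center", (h / 2.0, w / 2.0))
                d2 = (rr - center[0]) ** 2 + (cc - center[1]) ** 2
                mask |= d2 > g["aperture_radius"] ** 2
            if "lid_coverage" in g:
                side = g.get("side", "top")
                big_r = g.get("lid_radius", 900.0)
                cov = g["lid_coverage"]
                if side == "top":
                    lid_center = (cov - big_r, w / 2.0)
                else:
                    lid_center = (h - 1 - cov + big_r, w / 2.0)
                d2 = (rr - lid_center[0]) ** 2 + (cc - lid_center[1]) ** 2
                mask |= d2 < big_r ** 2
            img[mask] = 0.02
            add_fp(conf.kind, mask)
        # background kinds: handled at the thickness stage
    img = np.clip(img, 0.0, 1.0)
    return (img, footprints) if return_footprints else img


def roi_slices(shape: tuple[int, int], size: int = ROI_SIZE) -> tuple[slice, slice]:
    """Central detection-region slices; clipped to the frame for small frames."""
    h, w = shape
    sh, sw = min(size, h), min(size, w)
    r0 = (h - sh) // 2
    c0 = (w - sw) // 2
    return slice(r0, r0 + sh), slice(c0, c0 + sw)


def render_video(spec: SceneSpec, model: OpticalModel | None = None) -> Video:
    """Render all frames of a scene with per-frame ground truth.

    Per frame: base thickness → fringe modulation → breakup events at time t →
    optical rendering → image-space confounders. The frame label is true iff
    any rupture pixel lies inside the central 384×384 detection region.
    """
    if model is None:
        model = OpticalModel()
    base = sample_base_thickness(spec)
    _apply_fringes(base, spec)
    has_fringe = any(c.kind == "interference_fringe" for c in spec.confounders)
    background = "interference_fringe" if has_fringe else "uniform"
    rs, cs = roi_slices(spec.shape)
    frames = []
    for i in range(spec.n_frames):
        t = i / spec.fps
        thick = base.copy()
        pattern_masks: dict[str, np.ndarray] = {}
        for ev in spec.events:
            thick = apply_breakup(thick, ev, t)
            fp = event_footprint(ev, t, spec.shape)
            if fp.any():
                if ev.pattern in pattern_masks:
                    pattern_masks[ev.pattern] |= fp
                else:
                    pattern_masks[ev.pattern] = fp
        frame_rng = substream(spec.seed, "render", spec.video_id, i)
        img = render_interference(thick, model, rng=frame_rng)
        img, overlay_fp = composite_confounders(
            img, spec.confounders, rng=frame_rng, return_footprints=True
        )
        masks = dict(pattern_masks)
        masks.update(overlay_fp)
        present = bool(thick.rupture_mask[rs, cs].any())
        frames.append(
            Frame(
                index=i,
                t=t,
                image=img.astype(np.float32),
                truth=FrameTruth(present, masks, background),
            )
        )
    return Video(spec=spec, frames=frames)


def label_patch(frame: Frame, row0: int, col0: int, size: int = PATCH_SIZE) -> str | None:
    """Class label of a patch window by the dominant-element rule.

    If the window contains rupture pixels, the dominant breakup pattern wins
    provided breakup pixels are not outnumbered by any single confounder
    footprint (ties favor breakup); a window with rupture pixels can never
    receive a non-breakup label, so ``None`` is returned when a confounder
    dominates. Without rupture pixels the dominant overlay confounder wins;
    with no overlay pixels either, the label is the background class.
    """
    win = (slice(row0, row0 + size), slice(col0, col0 + size))
    rupture_counts = {
        p: int(m[win].sum()) for p, m in frame.truth.masks.items() if p in BREAKUP_CLASSES
    }
    overlay_counts = {
        k: int(m[win].sum()) for k, m in frame.truth.masks.items() if k in OVERLAY_KINDS
    }
    total_rupture = sum(rupture_counts.values())
    max_overlay = max(overlay_counts.values(), default=0)
    if total_rupture > 0:
        if total_rupture >= max_overlay:
            return max(BREAKUP_CLASSES, key=lambda p: rupture_counts.get(p, 0))
        return None
    if max_overlay > 0:
        order = {k: i for i, k in enumerate(OVERLAY_KINDS)}
        return max(overlay_counts, key=lambda k: (overlay_counts[k], -order[k]))
    return frame.truth.background


def emit_labeled_patches(
    videos: list[Video],
    patches_per_class: int,
    rng: np.random.Generator,
    classes=None,
    max_attempts_factor: int = 60,
) -> tuple[list[PatchRecord], dict[str, int]]:
    """Sample labeled 96×96 patches from rendered videos.

    For each requested class, patches are centered on (or jittered around) the
    class's footprint pixels and accepted only if the dominant-element rule
    assigns that class; uniform/fringe patches must contain no rupture and no
    confounder pixels at all. Returns the records plus a per-class shortfall
    tally for classes the scenes could not supply in full.
    """
    from .data import CLASSES

    if classes is None:
        classes = CLASSES
    records: list[PatchRecord] = []
    shortfall: dict[str, int] = {}
    if patches_per_class <= 0:
        return records, shortfall

    def frame_has(cls: str, fr: Frame) -> bool:
        if cls in BREAKUP_CLASSES or cls in OVERLAY_KINDS:
            m = fr.truth.masks.get(cls)
            return m is not None and bool(m.any())
        return fr.truth.background == cls

    for cls in classes:
        candidates = [
            (v, fr) for v in videos for fr in v.frames if frame_has(cls, fr)
        ]
        got = 0
        attempts = 0
        budget = max_attempts_factor * patches_per_class
        while got < patches_per_class and attempts < budget and candidates:
            attempts += 1
            v, fr = candidates[rng.integers(len(candidates))]
            h, w = fr.image.shape[:2]
            if cls in BREAKUP_CLASSES or cls in OVERLAY_KINDS:
                ys, xs = np.nonzero(fr.truth.masks[cls])
                j = rng.integers(len(ys))
                r0 = int(ys[j]) - PATCH_SIZE // 2 + int(rng.integers(-12, 13))
                c0 = int(xs[j]) - PATCH_SIZE // 2 + int(rng.integers(-12, 13))
            else:
                r0 = int(rng.integers(0, h - PATCH_SIZE + 1))
                c0 = int(rng.integers(0, w - PATCH_SIZE + 1))
            r0 = min(max(r0, 0), h - PATCH_SIZE)
            c0 = min(max(c0, 0), w - PATCH_SIZE)
            if label_patch(fr, r0, c0) != cls:
                continue
            img = np.asarray(
                fr.image[r0 : r0 + PATCH_SIZE, c0 : c0 + PATCH_SIZE], dtype=float
            )
            records.append(
                PatchRecord(
                    label=cls,
                    video_id=v.spec.video_id,
                    eye_id=v.spec.eye_id,
                    subject_id=v.spec.subject_id,
                    image=img,
                )
            )
            got += 1
        if got < patches_per_class:
            shortfall[cls] = patches_per_class - got
    return records, shortfall


@dataclass
class FrameSample:
    frame: Frame
    label: bool
    video_id: str
    eye_id: str


def emit_labeled_frames(
    videos: list[Video],
    max_per_video: int = 40,
    rng: np.random.Generator | None = None,
) -> list[FrameSample]:
    """Sample up to ``max_per_video`` frames per video with presence labels.

    Sampling is stratified so both labels appear whenever the video contains
    both, mirroring an evaluation set built from breakup and pre-breakup
    moments of each recording.
    """
    if rng is None:
        rng = np.random.default_rng(0)
    out: list[FrameSample] = []
    for v in videos:
        pos = [f for f in v.frames if f.truth.breakup_present]
        neg = [f for f in v.frames if not f.truth.breakup_present]
        quota = min(max_per_video, len(v.frames))
        if pos and neg:
            n_pos = min(len(pos), max(1, quota // 2))
            n_neg = min(len(neg), quota - n_pos)
            n_pos = min(len(pos), quota - n_neg)
            chosen = [
                (f, True) for f in _sample(pos, n_pos, rng)
            ] + [(f, False) for f in _sample(neg, n_neg, rng)]
        else:
            src, lab = (pos, True) if pos else (neg, False)
            chosen = [(f, lab) for f in _sample(src, quota, rng)]
        for f, lab in chosen:
            out.append(FrameSample(f, lab, v.spec.video_id, v.spec.eye_id))
    return out


def _sample(items: list, n: int, rng: np.random.Generator) -> list:
    idx = rng.choice(len(items), size=n, replace=False) if n < len(items) else np.arange(len(items))
    return [items[i] for i in sorted(int(i) for i in np.atleast_1d(idx))]


def default_cohort(
    n_videos: int,
    seed: int,
    frame_size: tuple[int, int] = (640, 480),
    duration: float = 30.0,
    fps: float = 30.0,
    easy: bool = False,
) -> list[SceneSpec]:
    """Build a varied cohort of scene specs covering all nine classes.

    Scenes cycle through archetypes (clean uniform, fringed background, each
    breakup morphology, and each confounder) with randomized geometry; one
    video per eye, two eyes per subject. ``easy=True`` yields large,
    high-contrast breakups on clean backgrounds for detection-evaluation sets.
    """
    w, h = frame_size
    specs = []
    archetypes = [
        "uniform",
        "fringe",
        "spot",
        "line",
        "area",
        "bright_reflection",
        "particle",
        "eyelash",
        "eyelid",
    ]
    for v in range(n_videos):
        rng = substream(seed, "cohort", v)
        kind = archetypes[v % len(archetypes)]
        fringe = kind == "fringe" or (kind in ("line", "area") and rng.random() < 0.3 and not easy)
        base = BaseFieldSpec(
            mean=float(rng.uniform(90, 160)),
            amplitude=float(rng.uniform(5, 18)) if not fringe else float(rng.uniform(20, 40)),
            correlation_length=float(rng.uniform(60, 120)),
        )
        events: list[BreakupEvent] = []
        confs: list[ConfounderSpec] = []
        if fringe:
            confs.append(
                ConfounderSpec(
                    "interference_fringe",
                    {
                        "frequency": float(rng.uniform(0.012, 0.03)),
                        "orientation": float(rng.uniform(0, math.pi)),
                        "amplitude": float(rng.uniform(45, 80)),
                        "phase": float(rng.uniform(0, 2 * math.pi)),
                    },
                )
            )
        margin = 120
        center = (
            float(rng.uniform(margin, h - margin)),
            float(rng.uniform(margin + (w - h) / 2, w - margin - (w - h) / 2)),
        )
        onset = float(rng.uniform(0.15, 0.5) * duration)
        if kind == "spot":
            events.append(
                BreakupEvent(
                    "spot",
                    onset=onset,
                    center=center,
                    initial_size=float(rng.uniform(24, 34) if easy else rng.uniform(12, 20)),
                    growth_rate=float(rng.uniform(0.5, 1.5)),
                    elongation_rate=0.0,
                )
            )
        elif kind == "line":
            events.append(
                BreakupEvent(
                    "line",
                    onset=onset,
                    center=center,
                    initial_size=float(rng.uniform(18, 26) if easy else rng.uniform(10, 16)),
                    growth_rate=float(rng.uniform(0.2, 0.8)),
                    elongation_rate=float(rng.uniform(4, 9)),
                )
            )
        elif kind == "area":
            events.append(
                BreakupEvent(
                    "area",
                    onset=onset,
                    center=center,
                    initial_size=float(rng.uniform(55, 80) if easy else rng.uniform(35, 55)),
                    growth_rate=float(rng.uniform(1, 4)),
                )
            )
        elif kind == "bright_reflection":
            confs.append(
                ConfounderSpec(
                    "bright_reflection",
                    {
                        "center": (
                            float(rng.uniform(150, h - 150)),
                            float(rng.uniform(200, w - 200)),
                        ),
                        "radius": float(rng.uniform(8, 16)),
                        "intensity": float(rng.uniform(0.7, 0.95)),
                    },
                )
            )
        elif kind == "particle":
            n_particles = int(rng.integers(6, 14))
            confs.append(
                ConfounderSpec(
                    "particle",
                    {
                        "centers": [
                            (
                                float(rng.uniform(120, h - 120)),
                                float(rng.uniform(160, w - 160)),
                            )
                            for _ in range(n_particles)
                        ],
                        "radii": [float(rng.uniform(2, 4)) for _ in range(n_particles)],
                    },
                )
            )
        elif kind == "eyelash":
            top = rng.random() < 0.5
            c_base = float(rng.uniform(150, w - 150))
            r_edge = -3.0 if top else h + 2.0
            r_tip = float(rng.uniform(100, 200)) if top else h - float(rng.uniform(100, 200))
            confs.append(
                ConfounderSpec(
                    "eyelash",
                    {
                        "control_points": [
                            (r_edge, c_base),
                            ((r_edge + r_tip) / 2, c_base + float(rng.uniform(-60, 60))),
                            (r_tip, c_base + float(rng.uniform(-90, 90))),
                        ],
                        "width": float(rng.uniform(2.0, 3.5)),
                    },
                )
            )
        elif kind == "eyelid":
            geom = {"lid_coverage": float(rng.uniform(70, 130)),
                    "side": "top" if rng.random() < 0.5 else "bottom"}
            if rng.random() < 0.5:
                geom["aperture_radius"] = float(rng.uniform(290, 330))
            confs.append(ConfounderSpec("eyelid", geom))
        # sprinkle secondary confounders across scenes so each class is seen in
        # many videos, as in real recordings where debris/lashes co-occur
        if not easy:
            if kind != "particle" and rng.random() < 0.35:
                n_extra = int(rng.integers(2, 6))
                confs.append(
                    ConfounderSpec(
                        "particle",
                        {
                            "centers": [
                                (float(rng.uniform(120, h - 120)), float(rng.uniform(160, w - 160)))
                                for _ in range(n_extra)
                            ],
                            "radii": [float(rng.uniform(2, 4)) for _ in range(n_extra)],
                        },
                    )
                )
            if kind != "eyelash" and rng.random() < 0.3:
                top = rng.random() < 0.5
                c_base = float(rng.uniform(150, w - 150))
                r_edge = -3.0 if top else h + 2.0
                r_tip = float(rng.uniform(90, 170)) if top else h - float(rng.uniform(90, 170))
                confs.append(
                    ConfounderSpec(
                        "eyelash",
                        {
                            "control_points": [
                                (r_edge, c_base),
                                ((r_edge + r_tip) / 2, c_base + float(rng.uniform(-60, 60))),
                                (r_tip, c_base + float(rng.uniform(-90, 90))),
                            ],
                            "width": float(rng.uniform(2.0, 3.5)),
                        },
                    )
                )
            if kind != "bright_reflection" and rng.random() < 0.2:
                confs.append(
                    ConfounderSpec(
                        "bright_reflection",
                        {
                            "center": (
                                float(rng.uniform(150, h - 150)),
                                float(rng.uniform(200, w - 200)),
                            ),
                            "radius": float(rng.uniform(7, 13)),
                            "intensity": float(rng.uniform(0.65, 0.9)),
                        },
                    )
                )
        specs.append(
            SceneSpec(
                video_id=f"vid{v:04d}",
                eye_id=f"eye{v:04d}",
                subject_id=f"sub{v // 2:04d}",
                duration=duration,
                fps=fps,
                frame_size=frame_size,
                base_field=base,
                events=events,
                confounders=confs,
                seed=stable_hash32(seed, "scene", v),
            )
        )
    return specs
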