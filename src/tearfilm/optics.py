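"""Thin-film interference rendering for the tear lipid layer.

The tear film's outer lipid layer (tens to hundreds of nm thick) sits on the
aqueous layer. Under white light, reflections from the air/lipid and
lipid/aqueous interfaces interfere; the wavelength-dependent reflectance tints
the image, so color encodes local lipid thickness. This module renders that
color from a 2-D thickness field using a two-beam (first-order) interference
model at normal incidence and the CIE 1931 observer.

Where the film has ruptured, the exposed surface is rendered as a dark,
desaturated gray (optionally with multiplicative texture noise), matching the
dark appearance of breakup regions in interferometry video.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .cie import XYZ_TO_LINEAR_SRGB, cmf_xyz, srgb_gamma

__all__ = [
    "OpticalModel",
    "ThicknessMap",
    "fresnel_amplitude",
    "thin_film_reflectance",
    "spectrum_to_srgb",
    "render_interference",
]


def _default_wavelengths() -> np.ndarray:
    return np.arange(380.0, 780.0 + 1e-9, 5.0)


@dataclass
class OpticalModel:
    """Refractive indices, wavelength grid and illuminant of the interferometer.

    Defaults: air 1.000, lipid 1.48, aqueous 1.334; 380–780 nm in 5 nm steps;
    equal-energy illuminant (the device lamp spectrum is not public).
    """

    n_air: float = 1.000
    n_lipid: float = 1.48
    n_aqueous: float = 1.334
    wavelengths: np.ndarray = field(default_factory=_default_wavelengths)
    illuminant: np.ndarray | None = None
    exposed_gray: float = 0.22
    exposed_noise: float = 0.06

    def __post_init__(self) -> None:
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        if self.illuminant is None:
            self.illuminant = np.ones_like(self.wavelengths)
        self.illuminant = np.asarray(self.illuminant, dtype=float)
        for name in ("n_air", "n_lipid", "n_aqueous"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive, got {getattr(self, name)}")
        wl = self.wavelengths
        if wl.ndim != 1 or wl.size < 2 or np.any(np.diff(wl) <= 0):
            raise ValueError("wavelength grid must be 1-D and strictly increasing")
        if wl[0] < 380.0 - 1e-9 or wl[-1] > 780.0 + 1e-9:
            raise ValueError("wavelength grid must lie within [380, 780] nm")
        if self.illuminant.shape != wl.shape:
            raise ValueError("illuminant must match the wavelength grid")
        if np.any(self.illuminant < 0) or not np.any(self.illuminant > 0):
            raise ValueError("illuminant must be non-negative and not all zero")

    @classmethod
    def from_config(cls, path: str | Path) -> "OpticalModel":
        """Load indices / grid / illuminant / exposed-surface level from JSON or YAML."""
        path = Path(path)
        text = path.read_text()
        raw = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
        if "wavelengths" in raw:
            raw["wavelengths"] = np.asarray(raw["wavelengths"], dtype=float)
        if raw.get("illuminant") is not None:
            raw["illuminant"] = np.asarray(raw["illuminant"], dtype=float)
        return cls(**raw)


@dataclass
class ThicknessMap:
    """Latent simulator state: lipid thickness (nm) per pixel plus a rupture mask."""

    values: np.ndarray
    rupture_mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.rupture_mask is None:
            self.rupture_mask = np.zeros(self.values.shape, dtype=bool)
        self.rupture_mask = np.asarray(self.rupture_mask, dtype=bool)
        if self.values.ndim != 2:
            raise ValueError("thickness values must be a 2-D grid")
        if np.any(self.values < 0):
            raise ValueError("thickness values must be non-negative")
        if self.rupture_mask.shape != self.values.shape:
            raise ValueError("rupture_mask shape must match thickness values")

    def copy(self) -> "ThicknessMap":
        return ThicknessMap(self.values.copy(), self.rupture_mask.copy())


def fresnel_amplitude(n1, n2):
    """Signed normal-incidence amplitude reflection coefficient (n1 − n2)/(n1 + n2).

    The sign carries the half-wave phase flip at a low-to-high index interface.
    """
    n1 = np.asarray(n1, dtype=float)
    n2 = np.asarray(n2, dtype=float)
    if np.any(n1 <= 0) or np.any(n2 <= 0):
        raise ValueError("refractive indices must be positive")
    out = (n1 - n2) / (n1 + n2)
    return float(out) if out.ndim == 0 else out


def thin_film_reflectance(d, wavelength, model: OpticalModel | None = None):
    """Two-beam reflectance of a lipid film of thickness ``d`` nm at ``wavelength`` nm.

    R = r1² + r2² + 2 r1 r2 cos(4π n d / λ) with r1, r2 the Fresnel amplitudes of
    the air/lipid and lipid/aqueous interfaces; clamped to [0, 1]. Broadcasts over
    array inputs.
    """
    if model is None:
        model = OpticalModel()
    d = np.asarray(d, dtype=float)
    wavelength = np.asarray(wavelength, dtype=float)
    if np.any(d < 0):
        raise ValueError("film thickness must be non-negative")
    lo, hi = model.wavelengths[0], model.wavelengths[-1]
    if np.any(wavelength < lo - 1e-9) or np.any(wavelength > hi + 1e-9):
        raise ValueError(f"wavelength outside the model grid [{lo}, {hi}] nm")
    r1 = fresnel_amplitude(model.n_air, model.n_lipid)
    r2 = fresnel_amplitude(model.n_lipid, model.n_aqueous)
    phase = 4.0 * np.pi * model.n_lipid * d / wavelength
    r = r1 * r1 + r2 * r2 + 2.0 * r1 * r2 * np.cos(phase)
    r = np.clip(r, 0.0, 1.0)
    return float(r) if r.ndim == 0 else r


def spectrum_to_srgb(reflectances, model: OpticalModel | None = None):
    """Convert per-wavelength reflectance to display sRGB in [0, 1]³.

    Reflectance × illuminant is integrated against the CIE 1931 2° observer to
    XYZ; channels are white-balanced so the illuminant itself maps to neutral
    (a flat spectrum renders achromatic), converted through the linear-sRGB
    matrix, clipped, and gamma-encoded. Accepts arrays with the wavelength grid
    on the last axis.
    """
    if model is None:
        model = OpticalModel()
    refl = np.asarray(reflectances, dtype=float)
    if refl.shape[-1] != model.wavelengths.size:
        raise ValueError(
            f"expected {model.wavelengths.size} reflectance samples on the last axis, "
            f"got {refl.shape[-1]}"
        )
    cmf = cmf_xyz(model.wavelengths)  # (n, 3)
    weighted = cmf * model.illuminant[:, None]
    xyz = refl @ weighted
    rgb_lin = xyz @ XYZ_TO_LINEAR_SRGB.T
    white = (np.ones_like(model.wavelengths) @ weighted) @ XYZ_TO_LINEAR_SRGB.T
    rgb_lin = rgb_lin / white
    rgb_lin = np.clip(rgb_lin, 0.0, 1.0)
    return np.clip(srgb_gamma(rgb_lin), 0.0, 1.0)


def render_interference(
    thickness: ThicknessMap,
    model: OpticalModel | None = None,
    rng: np.random.Generator | None = None,
    row_chunk: int = 64,
) -> np.ndarray:
    """Render an RGB float image from a thickness map.

    Equal to the per-pixel composition of :func:`thin_film_reflectance` and
    :func:`spectrum_to_srgb`; computed in row chunks to bound memory. Pixels
    under the rupture mask get the exposed-surface gray, with multiplicative
    texture noise when an ``rng`` is supplied.
    """
    if model is None:
        model = OpticalModel()
    h, w = thickness.values.shape
    out = np.empty((h, w, 3), dtype=float)
    wl = model.wavelengths
    for r0 in range(0, h, row_chunk):
        block = thickness.values[r0 : r0 + row_chunk]
        refl = thin_film_reflectance(block[:, :, None], wl[None, None, :], model)
        out[r0 : r0 + block.shape[0]] = spectrum_to_srgb(refl, model)
    mask = thickness.rupture_mask
    if mask.any():
        gray = np.full((int(mask.sum()), 3), model.exposed_gray)
        if rng is not None and model.exposed_noise > 0:
            gray *= 1.0 + model.exposed_noise * rng.standard_normal((gray.shape[0], 1))
        out[mask] = np.clip(gray, 0.0, 1.0)
    return out
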