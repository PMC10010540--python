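"""CIE 1931 2-degree color-matching functions and sRGB conversion constants.

The color-matching functions are evaluated from the multi-lobe piecewise-Gaussian
fits of Wyman, Sloan & Shirley (2013), which reproduce the tabulated 1931 observer
to well under 1% of peak — ample for rendering plausible interference colors.
"""

from __future__ import annotations

import numpy as np

__all__ = ["cmf_xyz", "XYZ_TO_LINEAR_SRGB", "srgb_gamma"]

# linear sRGB <- XYZ (D65), IEC 61966-2-1
XYZ_TO_LINEAR_SRGB = np.array(
    [
        [3.2406, -1.5372, -0.4986],
        [-0.9689, 1.8758, 0.0415],
        [0.0557, -0.2040, 1.0570],
    ]
)


def _lobe(wl: np.ndarray, alpha: float, mu: float, sigma_lo: float, sigma_hi: float) -> np.ndarray:
    sigma = np.where(wl < mu, sigma_lo, sigma_hi)
    return alpha * np.exp(-0.5 * ((wl - mu) / sigma) ** 2)


def cmf_xyz(wavelengths_nm: np.ndarray) -> np.ndarray:
    """Return the (n, 3) matrix of x̄, ȳ, z̄ sampled at the given wavelengths (nm)."""
    wl = np.asarray(wavelengths_nm, dtype=float)
    x = (
        _lobe(wl, 1.056, 599.8, 37.9, 31.0)
        + _lobe(wl, 0.362, 442.0, 16.0, 26.7)
        - _lobe(wl, 0.065, 501.1, 20.4, 26.2)
    )
    y = _lobe(wl, 0.821, 568.8, 46.9, 40.5) + _lobe(wl, 0.286, 530.9, 16.3, 31.1)
    z = _lobe(wl, 1.217, 437.0, 11.8, 36.0) + _lobe(wl, 0.681, 459.0, 26.0, 13.8)
    return np.stack([x, y, z], axis=-1)


def srgb_gamma(linear: np.ndarray) -> np.ndarray:
    """Standard sRGB display transfer function, applied element-wise on [0, 1]."""
    linear = np.asarray(linear, dtype=float)
    return np.where(
        linear <= 0.0031308,
        12.92 * linear,
        1.055 * np.clip(linear, 0.0, None) ** (1 / 2.4) - 0.055,
    )
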