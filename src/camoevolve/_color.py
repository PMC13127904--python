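"""Colour-space helpers: linear-light RGB <-> sRGB <-> CIELAB (D65).

The rendering pipeline works in linear-light RGB (calibrated-reflectance
arithmetic is multiplicative there); measurements work in CIELAB.  These
wrappers pin the conversions to one path (skimage's sRGB/D65 matrices) so
the reflectance-identity calibration holds bit-for-bit across modules.
"""

from __future__ import annotations

import warnings

import numpy as np
from skimage import color


def srgb_to_linear(srgb: np.ndarray) -> np.ndarray:
    s = np.asarray(srgb, dtype=float)
    return np.where(s <= 0.04045, s / 12.92, ((s + 0.055) / 1.055) ** 2.4)


def linear_to_srgb(lin: np.ndarray) -> np.ndarray:
    l = np.clip(np.asarray(lin, dtype=float), 0.0, 1.0)
    return np.where(l <= 0.0031308, l * 12.92, 1.055 * l ** (1 / 2.4) - 0.055)


def linear_to_lab(lin: np.ndarray) -> np.ndarray:
    return color.rgb2lab(linear_to_srgb(lin))


def lab_to_linear(lab: np.ndarray) -> np.ndarray:
    with warnings.catch_warnings():
        # out-of-gamut Lab values are clipped to the sRGB cube by design
        warnings.filterwarnings("ignore", message=".*negative Z values.*")
        rgb = color.lab2rgb(lab)
    return srgb_to_linear(np.clip(rgb, 0.0, 1.0))


def encode_png16(lin: np.ndarray) -> np.ndarray:
    """Quantize a linear-light image to 16-bit sRGB-encoded integers."""
    return (linear_to_srgb(lin) * 65535.0 + 0.5).astype(np.uint16)


def encode_srgb8(lin: np.ndarray) -> np.ndarray:
    """Quantize a linear-light image to 8-bit sRGB-encoded integers."""
    return (linear_to_srgb(lin) * 255.0 + 0.5).astype(np.uint8)
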