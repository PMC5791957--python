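"""Colour-space conversions for mixing-test image analysis.

An 8-bit sRGB scan is expanded into twelve scalar analysis channels:

====== =============================================== ==========
code   meaning                                         range
====== =============================================== ==========
R,G,B  raw 8-bit sRGB components                       [0, 255]
L,u,v  CIE 1976 L*u*v* (D65 white, sRGB primaries)     L in [0,100]
H,S,I  hue / saturation / intensity (arccos variant)   H in [0,2pi)
Rn..Bn chromaticity-normalised RGB                     [0, 1]
====== =============================================== ==========

Hue is kept in radians because downstream mixture indices use circular
statistics.  Hue is undefined for achromatic pixels (R = G = B); those
pixels carry a validity mask and are excluded from hue statistics rather
than imputed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from skimage.color import rgb2luv

from .errors import InputError

#: Public channel naming contract, reused by the feature registry and MEPAT.
CHANNEL_CODES: tuple[str, ...] = (
    "R", "G", "B", "L", "u", "v", "H", "S", "I", "Rn", "Gn", "Bn",
)

#: Fixed histogram ranges per channel.  u*/v* bounds cover the sRGB gamut.
CHANNEL_RANGES: dict[str, tuple[float, float]] = {
    "R": (0.0, 255.0), "G": (0.0, 255.0), "B": (0.0, 255.0),
    "L": (0.0, 100.0), "u": (-134.0, 220.0), "v": (-140.0, 122.0),
    "H": (0.0, 2.0 * np.pi), "S": (0.0, 1.0), "I": (0.0, 1.0),
    "Rn": (0.0, 1.0), "Gn": (0.0, 1.0), "Bn": (0.0, 1.0),
}


def _as_float_rgb(rgb: np.ndarray) -> np.ndarray:
    rgb = np.asarray(rgb)
    if rgb.size == 0:
        raise InputError("empty RGB input")
    if rgb.shape[-1] != 3:
        raise InputError(f"expected trailing RGB axis of size 3, got shape {rgb.shape}")
    return rgb.astype(np.float64)


def to_hsi(rgb: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Convert 8-bit RGB values to (H, S, I) with a hue-validity mask.

    Uses the classical arccos hue formulation:
    ``H = arccos(((R-G)+(R-B))/2 / sqrt((R-G)^2 + (R-B)(G-B)))`` with
    ``H -> 2pi - H`` when ``B > G``.  ``I = (R+G+B)/(3*255)`` and
    ``S = 1 - min(R,G,B)/mean(R,G,B)``.  Hue is masked invalid where
    ``S = 0`` (achromatic pixels).

    Returns ``(H, S, I, hue_defined)`` as float arrays / boolean mask with
    the input's leading shape.
    """
    v = _as_float_rgb(rgb)
    r, g, b = v[..., 0], v[..., 1], v[..., 2]
    total = r + g + b
    i = total / (3.0 * 255.0)
    mn = np.minimum(np.minimum(r, g), b)
    with np.errstate(invalid="ignore", divide="ignore"):
        s = np.where(total > 0, 1.0 - 3.0 * mn / np.where(total > 0, total, 1.0), 0.0)
    achromatic = (r == g) & (g == b)
    num = 0.5 * ((r - g) + (r - b))
    den = np.sqrt((r - g) ** 2 + (r - b) * (g - b))
    with np.errstate(invalid="ignore", divide="ignore"):
        cosang = np.clip(np.where(den > 0, num / np.where(den > 0, den, 1.0), 1.0), -1.0, 1.0)
    h = np.arccos(cosang)
    h = np.where(b > g, 2.0 * np.pi - h, h)
    h = np.where(achromatic, 0.0, h)
    # 2*pi wraps to 0 so the half-open [0, 2pi) contract holds
    h = np.where(h >= 2.0 * np.pi, 0.0, h)
    return h, np.clip(s, 0.0, 1.0), np.clip(i, 0.0, 1.0), ~achromatic


def to_cieluv(rgb: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Convert 8-bit sRGB to CIE L*u*v* (D65), returning (L*, u*, v*)."""
    v = _as_float_rgb(rgb) / 255.0
    shape = v.shape
    luv = rgb2luv(v.reshape(1, -1, 3)).reshape(shape)
    return luv[..., 0], luv[..., 1], luv[..., 2]


def to_normalized_rgb(rgb: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Chromaticity normalisation ``Rn = R/(R+G+B)`` etc.

    Removes most of the brightness dependence of RGB.  A black pixel
    (zero sum) maps to the neutral point (1/3, 1/3, 1/3) so that flat
    shadows do not produce NaNs.
    """
    v = _as_float_rgb(rgb)
    total = v.sum(axis=-1)
    safe = np.where(total > 0, total, 3.0)
    out = v / safe[..., None]
    out[total == 0] = 1.0 / 3.0
    return out[..., 0], out[..., 1], out[..., 2]


@dataclass
class ChannelSet:
    """The twelve analysis channels of one RGB raster.

    ``channels`` maps channel code to a float raster of the source shape;
    ``hue_defined`` marks pixels with a defined hue.
    """

    channels: dict[str, np.ndarray]
    hue_defined: np.ndarray
    shape: tuple[int, int] = field(default=(0, 0))

    def __post_init__(self) -> None:
        if set(self.channels) != set(CHANNEL_CODES):
            missing = set(CHANNEL_CODES) - set(self.channels)
            raise InputError(f"channel set incomplete, missing {sorted(missing)}")
        self.shape = self.channels["R"].shape


def channel_set(image: np.ndarray) -> ChannelSet:
    """Decompose an 8-bit RGB image into the twelve analysis channels."""
    v = _as_float_rgb(image)
    h, s, i, defined = to_hsi(v)
    lum, u, vv = to_cieluv(v)
    rn, gn, bn = to_normalized_rgb(v)
    return ChannelSet(
        channels={
            "R": v[..., 0], "G": v[..., 1], "B": v[..., 2],
            "L": lum, "u": u, "v": vv,
            "H": h, "S": s, "I": i,
            "Rn": rn, "Gn": gn, "Bn": bn,
        },
        hue_defined=defined,
    )
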