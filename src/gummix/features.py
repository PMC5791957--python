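"""Masticatory Performance (MP) feature extraction.

The observed state of a specimen is summarised as the vector
``MP = (f1, ..., fk)`` of scalar features computed over the pooled ROI
pixels of both scan sides.  The default registry pairs ten extraction
models with the twelve colour channels and adds the circular variance
of hue, for 10 x 12 + 1 = 121 features.

Extraction models (model codes):

====  =========================================================
Mp    mean of the ROI pixel values
Vp    absolute (population) variance of the ROI pixel values
Vh    absolute variance of the 256 raw histogram bin counts
Sh    Fisher-Pearson skewness of the histogram (count-weighted
      over bin indices)
Gh    histogram energy  sum(p_i^2)
Eh    histogram entropy -sum(p_i log2 p_i)  (bits)
Nh    number of histogram peaks
V1    height (raw count) of the tallest peak
V2    height of the second-tallest peak (0 if absent)
P2    bin index of the second-tallest peak (-1 if absent)
====  =========================================================

plus ``CVOH``, the circular variance of the hue channel,
``1 - |mean resultant vector|`` — a classical single-number mixture
index.

A feature is addressed by its Mixture Feature Code (MFC): model code +
channel code, e.g. ``VhH`` (histogram variance of hue) or ``EhRn``
(entropy of the normalised-red histogram); the hue circular variance is
the literal code ``CVOH``.  Undefined-hue (achromatic) pixels are
excluded from every H-channel statistic, never imputed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal import find_peaks

from .colorspaces import CHANNEL_CODES, CHANNEL_RANGES, channel_set
from .errors import FeatureError, InputError, RegistryError

MODEL_CODES: tuple[str, ...] = ("Mp", "Vp", "Vh", "Sh", "Gh", "Eh", "Nh", "V1", "V2", "P2")

N_BINS = 256
PEAK_PROMINENCE_FRACTION = 0.01

#: An MP vector is a pandas Series indexed by MFC code.
MPVector = pd.Series


def default_registry() -> list[str]:
    """The default ordered MFC registry: 10 models x 12 channels + CVOH."""
    return [m + c for m in MODEL_CODES for c in CHANNEL_CODES] + ["CVOH"]


@dataclass
class ChannelHistogram:
    """A 256-bin histogram over a channel's fixed full range."""

    counts: np.ndarray
    edges: np.ndarray

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    @property
    def probabilities(self) -> np.ndarray:
        return self.counts / self.total


def pool_roi_pixels(images, masks) -> dict[str, np.ndarray]:
    """Pool ROI pixels of both sides into one value collection per channel.

    Returns a mapping channel code -> 1-D float array.  The ``H`` entry
    holds only defined-hue pixels.
    """
    pooled: dict[str, list[np.ndarray]] = {c: [] for c in CHANNEL_CODES}
    any_roi = False
    for img, mask in zip(images, masks):
        mask = np.asarray(mask, bool)
        if not mask.any():
            continue
        any_roi = True
        cs = channel_set(img)
        for code in CHANNEL_CODES:
            values = cs.channels[code]
            sel = mask & cs.hue_defined if code == "H" else mask
            pooled[code].append(values[sel])
    if not any_roi:
        raise FeatureError("empty ROI on both sides")
    return {c: (np.concatenate(v) if v else np.empty(0)) for c, v in pooled.items()}


def histogram(values: np.ndarray, channel_code: str) -> ChannelHistogram:
    """256 equal-width bins over the channel's fixed full range.

    Values are clipped into the range first (u*/v* can exceed the
    nominal gamut bounds by rounding).
    """
    values = np.asarray(values, dtype=np.float64).ravel()
    if values.size == 0:
        raise InputError("cannot histogram an empty value collection")
    if channel_code not in CHANNEL_RANGES:
        raise RegistryError(channel_code)
    lo, hi = CHANNEL_RANGES[channel_code]
    counts, edges = np.histogram(np.clip(values, lo, hi), bins=N_BINS, range=(lo, hi))
    return ChannelHistogram(counts=counts.astype(np.int64), edges=edges)


def _smoothed_counts(counts: np.ndarray) -> np.ndarray:
    # binomial (1,2,1)/4 smoothing keeps an isolated spike a strict maximum
    padded = np.pad(counts.astype(np.float64), 1, mode="edge")
    return 0.25 * padded[:-2] + 0.5 * padded[1:-1] + 0.25 * padded[2:]


def _peaks(hist: ChannelHistogram) -> tuple[np.ndarray, np.ndarray]:
    """Detected peak bin indices and their raw-count heights.

    A peak is a strict local maximum of the smoothed counts with
    prominence at least 1% of the total count; heights are read from
    the raw histogram.  Returned sorted by descending height.
    """
    smoothed = _smoothed_counts(hist.counts)
    prominence = max(PEAK_PROMINENCE_FRACTION * hist.total, 1e-9)
    idx, _ = find_peaks(smoothed, prominence=prominence)
    heights = hist.counts[idx].astype(np.float64)
    order = np.argsort(-heights, kind="stable")
    return idx[order], heights[order]


def cvoh(hue_values: np.ndarray) -> float:
    """Circular variance of hue: ``1 - |mean resultant vector|`` in [0, 1].

    0 when every hue coincides; 1 when hues cancel (e.g. two equal
    antipodal masses).
    """
    h = np.asarray(hue_values, dtype=np.float64).ravel()
    if h.size == 0:
        raise FeatureError("no defined hue values (achromatic ROI)")
    rbar = np.hypot(np.cos(h).sum(), np.sin(h).sum()) / h.size
    return float(np.clip(1.0 - rbar, 0.0, 1.0))


def extract_feature(model_code: str, pixels: np.ndarray | None = None,
                    hist: ChannelHistogram | None = None) -> float:
    """Evaluate one extraction model on pixel values and/or a histogram."""
    if model_code in ("Mp", "Vp"):
        if pixels is None or np.asarray(pixels).size == 0:
            raise InputError(f"model {model_code} requires pixel values")
        pixels = np.asarray(pixels, dtype=np.float64)
        return float(pixels.mean() if model_code == "Mp" else pixels.var())
    if hist is None:
        raise InputError(f"model {model_code} requires a histogram")
    counts = hist.counts.astype(np.float64)
    p = hist.probabilities
    if model_code == "Vh":
        return float(counts.var())
    if model_code == "Sh":
        # skewness of the bin-index distribution weighted by bin mass
        idx = np.arange(counts.size, dtype=np.float64)
        mu = float((p * idx).sum())
        var = float((p * (idx - mu) ** 2).sum())
        if var == 0:
            return 0.0
        m3 = float((p * (idx - mu) ** 3).sum())
        return m3 / var**1.5
    if model_code == "Gh":
        return float((p**2).sum())
    if model_code == "Eh":
        nz = p[p > 0]
        return float(-(nz * np.log2(nz)).sum())
    if model_code in ("Nh", "V1", "V2", "P2"):
        idx, heights = _peaks(hist)
        if model_code == "Nh":
            return float(idx.size)
        if model_code == "V1":
            return float(heights[0]) if idx.size >= 1 else 0.0
        if model_code == "V2":
            return float(heights[1]) if idx.size >= 2 else 0.0
        return float(idx[1]) if idx.size >= 2 else -1.0
    raise RegistryError(model_code)


def extract_mp(images, masks, registry: list[str] | None = None) -> MPVector:
    """Compute the full MP vector of a specimen image pair.

    ``images`` and ``masks`` are the two sides and their ROI masks
    (arrays or :class:`~gummix.segmentation.RegionMask`).  Returns a
    Series indexed by MFC code in registry order (length 121 under the
    default registry).  Deterministic.
    """
    masks = [m.mask if hasattr(m, "mask") else np.asarray(m, bool) for m in masks]
    if registry is None:
        registry = default_registry()
    pooled = pool_roi_pixels(images, masks)
    hists: dict[str, ChannelHistogram] = {}
    values: dict[str, float] = {}
    for code in registry:
        if code == "CVOH":
            values[code] = cvoh(pooled["H"])
            continue
        model, channel = _parse_mfc(code)
        if model in ("Mp", "Vp"):
            values[code] = extract_feature(model, pixels=pooled[channel])
        else:
            if channel not in hists:
                hists[channel] = histogram(pooled[channel], channel)
            values[code] = extract_feature(model, hist=hists[channel])
    return pd.Series(values, index=registry, dtype=np.float64)


def _parse_mfc(code: str) -> tuple[str, str]:
    for model in MODEL_CODES:
        if code.startswith(model):
            channel = code[len(model):]
            if channel in CHANNEL_CODES:
                return model, channel
    raise RegistryError(code)


def mp_table(mp_vectors: list[MPVector]) -> pd.DataFrame:
    """Stack MP vectors into a specimen-by-feature table."""
    return pd.DataFrame([v for v in mp_vectors])
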