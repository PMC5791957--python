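"""Automatic bolus/background segmentation.

The bolus (the chewed wafer) sits roughly in the centre of a flatbed
scan against a near-uniform lid background, but has irregular shape,
vague boundaries and heterogeneous coloration.  Segmentation therefore
composes three steps:

1. **Mean shift (MS)** edge-preserving smoothing in CIE L*u*v*: each
   pixel is pulled to the mode of its joint spatial-colour
   neighbourhood, flattening intra-region texture while keeping the
   bolus/background boundary sharp.
2. **Distance map (DM)**: the normalised Euclidean distance of every
   pixel to the image centre, an extra clustering feature that biases
   the central blob into one cluster.
3. **K-Means (KM)** with k = 2 on the standardized (L*, u*, v*,
   distance) stack, followed by a connected-component cleanup that
   keeps only the central ROI component.

Ablation variants (KM only, MS+KM, DM+KM) are exposed for comparison.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
from numba import njit
from PIL import Image
from scipy import ndimage
from skimage.color import luv2rgb, rgb2luv
from sklearn.cluster import KMeans

from .errors import InputError, ParameterError, SegmentationError

VARIANTS = ("ms+dm+km", "km", "ms+km", "dm+km")


@dataclass(frozen=True)
class SegmentationParams:
    """Tunable segmentation parameters.

    Bandwidth defaults (8 px spatial, 12 L*u*v* units range) suppress
    scanner noise while preserving blob edges at typical scan scales.
    ``min_colour_separation`` guards against images with no bolus: if
    the two K-Means clusters are closer than this in mean L*u*v* colour,
    segmentation is declared failed.
    """

    spatial_bandwidth: float = 8.0
    range_bandwidth: float = 12.0
    ms_iterations: int = 3
    n_init: int = 10
    distance_weight: float = 1.5
    min_colour_separation: float = 8.0
    closing_radius: int = 8
    convex_hull: bool = True
    seed: int = 0
    variant: str = "ms+dm+km"

    def __post_init__(self) -> None:
        if self.spatial_bandwidth <= 0 or self.range_bandwidth <= 0:
            raise ParameterError("bandwidths must be positive")
        if self.variant not in VARIANTS:
            raise ParameterError(f"variant must be one of {VARIANTS}")


@dataclass
class RegionMask:
    """Binary bolus mask; True marks ROI pixels."""

    mask: np.ndarray

    @property
    def roi_pixel_count(self) -> int:
        return int(self.mask.sum())


@njit(cache=True)
def _ms_filter_kernel(orig, hs, hr, n_iter):  # pragma: no cover - numba
    height, width, _ = orig.shape
    r = int(hs)
    inv2hs2 = 0.5 / (hs * hs)
    inv2hr2 = 0.5 / (hr * hr)
    spatial_w = np.empty((2 * r + 1, 2 * r + 1))
    for dy in range(-r, r + 1):
        for dx in range(-r, r + 1):
            spatial_w[dy + r, dx + r] = np.exp(-(dx * dx + dy * dy) * inv2hs2)
    cur = orig.copy()
    new = np.empty_like(cur)
    for _ in range(n_iter):
        for y in range(height):
            for x in range(width):
                c0 = cur[y, x, 0]
                c1 = cur[y, x, 1]
                c2 = cur[y, x, 2]
                sw = 0.0
                s0 = 0.0
                s1 = 0.0
                s2 = 0.0
                y0 = max(0, y - r)
                y1 = min(height - 1, y + r)
                x0 = max(0, x - r)
                x1 = min(width - 1, x + r)
                for yy in range(y0, y1 + 1):
                    for xx in range(x0, x1 + 1):
                        d0 = orig[yy, xx, 0] - c0
                        d1 = orig[yy, xx, 1] - c1
                        d2 = orig[yy, xx, 2] - c2
                        wr = np.exp(-(d0 * d0 + d1 * d1 + d2 * d2) * inv2hr2)
                        w = spatial_w[yy - y + r, xx - x + r] * wr
                        sw += w
                        s0 += w * orig[yy, xx, 0]
                        s1 += w * orig[yy, xx, 1]
                        s2 += w * orig[yy, xx, 2]
                new[y, x, 0] = s0 / sw
                new[y, x, 1] = s1 / sw
                new[y, x, 2] = s2 / sw
        tmp = cur
        cur = new
        new = tmp
    return cur


def _ms_filter_luv(luv: np.ndarray, params: SegmentationParams) -> np.ndarray:
    return _ms_filter_kernel(
        np.ascontiguousarray(luv, dtype=np.float64),
        float(params.spatial_bandwidth), float(params.range_bandwidth),
        int(params.ms_iterations),
    )


def mean_shift_filter(image: np.ndarray,
                      spatial_bandwidth: float = 8.0,
                      range_bandwidth: float = 12.0,
                      n_iter: int = 3) -> np.ndarray:
    """Edge-preserving mean shift smoothing of an RGB image.

    Each pixel's colour iterates toward the mode of its joint
    spatial-colour neighbourhood (Gaussian kernels; the window is
    truncated at the spatial bandwidth).  Mode seeking runs in CIE
    L*u*v*, where Euclidean distances are perceptual, and the result is
    converted back to RGB.

    Returns a float RGB raster in [0, 255] of the input shape.
    """
    params = SegmentationParams(spatial_bandwidth=spatial_bandwidth,
                                range_bandwidth=range_bandwidth,
                                ms_iterations=n_iter)
    img = np.asarray(image)
    if img.size == 0:
        raise InputError("empty image")
    luv = rgb2luv(img.astype(np.float64) / 255.0)
    out = _ms_filter_luv(luv, params)
    return np.clip(luv2rgb(out), 0.0, 1.0) * 255.0


def distance_map(image_shape: tuple[int, int]) -> np.ndarray:
    """Normalised Euclidean distance of every pixel to the image centre.

    Min-max scaled to [0, 1]: 0 at the centre, 1 at the farthest corner.
    """
    if len(image_shape) < 2 or image_shape[0] < 1 or image_shape[1] < 1:
        raise InputError("non-empty 2D shape required")
    height, width = image_shape[:2]
    cy, cx = (height - 1) / 2.0, (width - 1) / 2.0
    yy, xx = np.mgrid[0:height, 0:width]
    d = np.hypot(yy - cy, xx - cx)
    dmin, dmax = d.min(), d.max()
    if dmax == dmin:
        return np.zeros_like(d)
    return (d - dmin) / (dmax - dmin)


def kmeans_region_classify(feature_stack: np.ndarray,
                           image_shape: tuple[int, int],
                           k: int = 2, seed: int = 0,
                           n_init: int = 10) -> RegionMask:
    """Two-cluster K-Means labelling of pixels into ROI vs background.

    ``feature_stack`` has one standardized feature row per pixel in
    raster order.  The cluster whose mean normalised centre distance is
    smaller becomes the ROI (ties: the smaller cluster, as the bolus is
    smaller than the background); only the ROI connected component
    containing the image centre (falling back to the largest) is kept.
    """
    feats = np.asarray(feature_stack, dtype=np.float64)
    height, width = image_shape[:2]
    if feats.shape[0] != height * width:
        raise InputError("feature stack rows must equal pixel count")
    if np.allclose(feats.std(axis=0), 0.0):
        raise SegmentationError("degenerate input: all pixels identical")
    km = KMeans(n_clusters=k, n_init=n_init, random_state=seed)
    labels = km.fit_predict(feats).reshape(height, width)
    dmap = distance_map(image_shape)
    mean_dist = [dmap[labels == c].mean() if np.any(labels == c) else np.inf
                 for c in range(k)]
    order = np.argsort(mean_dist, kind="stable")
    roi_label = int(order[0])
    if k == 2 and np.isclose(mean_dist[0], mean_dist[1]):
        sizes = [(labels == c).sum() for c in range(k)]
        roi_label = int(np.argmin(sizes))
    roi = labels == roi_label
    if not roi.any():
        raise SegmentationError("no ROI cluster found")
    comps, n_comp = ndimage.label(roi)
    if n_comp > 1:
        centre_label = comps[height // 2, width // 2]
        if centre_label == 0:
            sizes = ndimage.sum_labels(np.ones_like(comps), comps,
                                       index=np.arange(1, n_comp + 1))
            centre_label = int(np.argmax(sizes)) + 1
        roi = comps == centre_label
    return RegionMask(mask=roi)


def segment(image: np.ndarray,
            params: SegmentationParams | None = None) -> RegionMask:
    """Full bolus segmentation of one scan side.

    Composes mean shift smoothing, the centre-distance feature and
    K-Means region classification according to ``params.variant``
    (default ``"ms+dm+km"``; ablations ``"km"``, ``"ms+km"``,
    ``"dm+km"`` drop the MS and/or DM steps).
    """
    if params is None:
        params = SegmentationParams()
    img = np.asarray(image)
    if img.ndim != 3 or img.shape[-1] != 3 or img.size == 0:
        raise InputError("expected a non-empty RGB image")
    luv = rgb2luv(img.astype(np.float64) / 255.0)
    if "ms" in params.variant:
        luv = _ms_filter_luv(luv, params)
    height, width = img.shape[:2]
    channels = [luv[..., 0].ravel(), luv[..., 1].ravel(), luv[..., 2].ravel()]
    if "dm" in params.variant:
        channels.append(distance_map((height, width)).ravel())
    feats = np.stack(channels, axis=1)
    sd = feats.std(axis=0)
    if np.all(sd[:3] == 0.0):
        raise SegmentationError("degenerate input: constant colour image")
    sd[sd == 0] = 1.0
    feats = (feats - feats.mean(axis=0)) / sd
    if "dm" in params.variant:
        feats[:, 3] *= params.distance_weight
    mask = kmeans_region_classify(feats, (height, width), k=2,
                                  seed=params.seed, n_init=params.n_init)
    roi = _regularize(mask.mask, params)
    _check_colour_separation(luv, roi, params)
    return RegionMask(mask=roi)


def _regularize(roi: np.ndarray, params: SegmentationParams) -> np.ndarray:
    """Shape regularization of the raw K-Means ROI label field.

    Colour clustering loses low-chroma bolus wedges near the outline
    (they resemble the background more than the bolus mean).  A morph
    closing at the smoothing scale plus hole filling recovers enclosed
    patches, and — because a press-flattened bolus is nearly convex —
    an optional convex-hull step recovers peripheral wedges.
    """
    from skimage.morphology import closing, convex_hull_image, disk

    if params.closing_radius > 0:
        roi = closing(roi, disk(params.closing_radius))
    roi = ndimage.binary_fill_holes(roi)
    if params.convex_hull:
        roi = convex_hull_image(roi, offset_coordinates=False)
    return roi


def _check_colour_separation(luv: np.ndarray, roi: np.ndarray,
                             params: SegmentationParams) -> None:
    """Reject segmentations where ROI and background colours coincide.

    A background-only scan (no bolus present) still yields two K-Means
    clusters, but their mean colours only differ by noise.
    """
    bg = ~roi
    if not roi.any() or not bg.any():
        raise SegmentationError("segmentation produced an empty region")
    mu_roi = luv[roi].mean(axis=0)
    mu_bg = luv[bg].mean(axis=0)
    sep = float(np.linalg.norm(mu_roi - mu_bg))
    if sep < params.min_colour_separation:
        raise SegmentationError(
            f"no distinct bolus found (cluster colour separation "
            f"{sep:.2f} < {params.min_colour_separation})"
        )


def segment_pair(images: tuple[np.ndarray, np.ndarray],
                 params: SegmentationParams | None = None
                 ) -> tuple[RegionMask, RegionMask]:
    """Segment both sides of a specimen."""
    return segment(images[0], params), segment(images[1], params)


def jaccard(mask_a: np.ndarray, mask_b: np.ndarray) -> float:
    """Jaccard overlap between two binary masks."""
    a, b = np.asarray(mask_a, bool), np.asarray(mask_b, bool)
    union = np.logical_or(a, b).sum()
    if union == 0:
        return 1.0
    return float(np.logical_and(a, b).sum() / union)


def load_image(path) -> np.ndarray:
    """Read an 8-bit RGB image (PNG/TIFF/JPEG) as a uint8 array."""
    return np.asarray(Image.open(Path(path)).convert("RGB"))


def save_mask(mask: RegionMask, path, params: SegmentationParams | None = None) -> None:
    """Write a mask as a 0/255 single-channel PNG plus a JSON sidecar."""
    path = Path(path)
    Image.fromarray((mask.mask.astype(np.uint8)) * 255).save(path)
    sidecar = {
        "roi_pixel_count": mask.roi_pixel_count,
        "params": asdict(params) if params is not None else None,
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))
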