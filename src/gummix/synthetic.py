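"""Synthetic two-coloured chewing-gum specimen generator.

Real mixing-test specimens are red/white two-layer gum wafers that are
chewed a known number of strokes, flattened, and scanned on both sides.
This module renders image pairs that emulate those scans so that the
whole pipeline — segmentation, feature extraction, selection, cascade
training and diagnosis — is testable without clinical data.

Mixing model
------------
A subject chews with a personal *mixing rate* ``r`` (per stroke).  After
``t`` strokes the specimen's mixing level is the saturating exponential

    m(t) = 1 - exp(-r * t)

so ``m(0) = 0`` (the pre-mastication state: one face fully red, the
other fully white) and ``m`` approaches 1 as strokes accumulate, which
matches the empirical observation that additional cycles beyond a few
tens add little further mixture.

Rendering
---------
The bolus is an irregular ellipse (low-order radial harmonics) centred
in the frame on a light-grey scanner-lid background.  Its texture is a
two-phase red/white patch field obtained by soft-thresholding smoothed
Gaussian noise: the patch length-scale shrinks and the soft (pink,
hue-blended) transition width grows with the mixing level, while the
red/white area balance moves from one-sided toward 50/50.  A mild
linear illumination gradient and additive Gaussian pixel noise emulate
flatbed-scanner imperfections.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass

import numpy as np
import pandas as pd
from PIL import Image
from scipy.ndimage import gaussian_filter

from .errors import ParameterError

#: Pure-phase sRGB colours of the unchewed gum layers.  The "white" layer
#: is cream-tinted, as real white gum is, so it carries a defined hue.
RED_RGB = np.array([198.0, 40.0, 55.0])
WHITE_RGB = np.array([235.0, 229.0, 205.0])


@dataclass(frozen=True)
class SyntheticConfig:
    """Study-design parameters of a synthetic calibration experiment.

    Defaults mirror a reference-population calibration: 80 subjects each
    chewing one specimen per cycle count in {0, 5, 10, 15, 20}.
    """

    n_subjects: int = 80
    cycles: tuple[int, ...] = (0, 5, 10, 15, 20)
    image_size: tuple[int, int] = (128, 128)  # (width, height) pixels
    subject_rate_mean: float = 0.05   # mixing per stroke
    subject_rate_sd: float = 0.0025
    blob_eccentricity_range: tuple[float, float] = (0.65, 0.95)  # minor/major axis
    noise_sd: float = 5.0             # 8-bit intensity units
    background_grey: int = 200
    seed: int = 0

    def __post_init__(self) -> None:
        cyc = tuple(int(c) for c in self.cycles)
        if len(cyc) == 0 or cyc[0] != 0:
            raise ParameterError("cycles must start at 0")
        if any(b <= a for a, b in zip(cyc, cyc[1:])):
            raise ParameterError("cycles must be strictly increasing")
        if self.n_subjects < 1:
            raise ParameterError("n_subjects must be >= 1")
        w, h = self.image_size
        if w < 64 or h < 64:
            raise ParameterError("image_size must be at least 64x64")
        if self.subject_rate_mean <= 0 or self.subject_rate_sd < 0:
            raise ParameterError("subject rate parameters must be positive")
        lo, hi = self.blob_eccentricity_range
        if not (0 < lo <= hi <= 1):
            raise ParameterError("blob_eccentricity_range must satisfy 0 < lo <= hi <= 1")
        object.__setattr__(self, "cycles", cyc)


@dataclass
class SyntheticSpecimen:
    """One generated specimen: two scan-like sides plus ground truth."""

    images: tuple[np.ndarray, np.ndarray]       # uint8 (H, W, 3) side A, side B
    roi_truth: tuple[np.ndarray, np.ndarray]    # bool (H, W) per side
    t: int                                      # chewing strokes applied
    subject_id: str
    mixing_level: float
    specimen_id: str = ""

    def __post_init__(self) -> None:
        if not self.specimen_id:
            self.specimen_id = f"{self.subject_id}-t{self.t:02d}"


def mixing_level(subject_rate: float, t: float) -> float:
    """Saturating mixing level ``1 - exp(-rate * t)``."""
    if subject_rate <= 0:
        raise ParameterError("subject_rate must be positive")
    if t < 0:
        raise ParameterError("chewing strokes t must be >= 0")
    return float(-np.expm1(-subject_rate * t))


def _blob_mask(rng: np.random.Generator, width: int, height: int,
               ecc_range: tuple[float, float]) -> np.ndarray:
    """Irregular ellipse mask, centred, single connected component.

    Star-convex by construction (radius is a smooth function of angle),
    with a 3-pixel margin to the frame border.
    """
    area_frac = rng.uniform(0.30, 0.40)
    ecc = rng.uniform(*ecc_range)
    angle = rng.uniform(0.0, np.pi)
    # radial perturbation: low-order harmonics, bounded amplitude
    n_harm = 4
    amps = rng.uniform(0.0, 0.05, size=n_harm) / np.arange(1, n_harm + 1)
    phases = rng.uniform(0.0, 2.0 * np.pi, size=n_harm)

    r0 = np.sqrt(area_frac * width * height / np.pi)
    a = r0 / np.sqrt(ecc)   # semi-major
    b = r0 * np.sqrt(ecc)   # semi-minor
    # keep the perturbed outline inside the frame with margin
    margin = 3.0
    max_r = a * (1.0 + amps.sum())
    limit = min(width, height) / 2.0 - margin
    if max_r > limit:
        scale = limit / max_r
        a *= scale
        b *= scale

    yy, xx = np.mgrid[0:height, 0:width]
    cx, cy = (width - 1) / 2.0, (height - 1) / 2.0
    dx, dy = xx - cx, yy - cy
    ca, sa = np.cos(angle), np.sin(angle)
    u = dx * ca + dy * sa
    w = -dx * sa + dy * ca
    theta = np.arctan2(w / b, u / a)
    pert = np.ones_like(theta)
    for k in range(n_harm):
        pert += amps[k] * np.cos((k + 2) * theta + phases[k])
    rad = np.sqrt((u / a) ** 2 + (w / b) ** 2)
    return rad <= pert


def _patch_weight_field(rng: np.random.Generator, mask: np.ndarray,
                        m: float, red_fraction: float) -> np.ndarray:
    """Per-pixel red weight in [0, 1] for a given mixing level.

    Smoothed Gaussian noise, rank-remapped inside the bolus and soft-
    thresholded: the smoothing length-scale is proportional to
    ``1 - m`` (coarse patches early, fine interleaving late) and the
    transition width grows with ``m`` (more pink blend shades as
    chewing folds the layers together).  Because the threshold acts on
    in-bolus ranks, both the red area fraction and the pink-blend mass
    are exact functions of the mixing level; the random field controls
    only where the patches sit.
    """
    if m <= 0.0:
        return np.full(mask.shape, 1.0 if red_fraction >= 0.5 else 0.0)
    sigma = 1.5 + 6.0 * (1.0 - m)
    g = gaussian_filter(rng.standard_normal(mask.shape), sigma=sigma, mode="reflect")
    # rank-remap within the bolus: the field supplies only the spatial
    # arrangement, while the red/pink/white value distribution is an
    # exact function of (m, red_fraction)
    inside = np.sort(g[mask])
    u = np.searchsorted(inside, g, side="right") / inside.size
    softness = 0.02 + 0.18 * m  # rank-space width of the pink transition
    return 1.0 / (1.0 + np.exp(-(u - (1.0 - red_fraction)) / softness))


def _render_side(rng: np.random.Generator, mask: np.ndarray, m: float,
                 red_fraction: float, config: SyntheticConfig) -> np.ndarray:
    height, width = mask.shape
    w_red = _patch_weight_field(rng, mask, m, red_fraction)
    colour = w_red[..., None] * RED_RGB + (1.0 - w_red[..., None]) * WHITE_RGB
    img = np.full((height, width, 3), float(config.background_grey))
    img[mask] = colour[mask]
    # mild horizontal illumination gradient, as an imperfect scanner lamp gives
    grad = rng.uniform(-0.03, 0.03)
    ramp = 1.0 + grad * (np.arange(width) - width / 2.0) / width
    img *= ramp[None, :, None]
    img += rng.normal(0.0, config.noise_sd, size=img.shape)
    return np.clip(np.round(img), 0, 255).astype(np.uint8)


def generate_specimen(t: int, subject_rate: float, config: SyntheticConfig,
                      seed: int, subject_id: str = "S000") -> SyntheticSpecimen:
    """Render both sides of one specimen chewed ``t`` strokes.

    At ``t = 0`` side A is the pure red face and side B the pure white
    face (the wafer is two stacked layers); for ``t > 0`` both sides
    share the specimen's mixing level with independent patch
    realisations.  Deterministic for a fixed ``(t, subject_rate, seed)``.
    """
    m = mixing_level(subject_rate, t)
    width, height = config.image_size
    rng = np.random.default_rng(seed)
    mask_a = _blob_mask(rng, width, height, config.blob_eccentricity_range)
    mask_b = _blob_mask(rng, width, height, config.blob_eccentricity_range)
    # red fraction: one-sided at m=0, converging to 50/50 as m -> 1
    red_a = 1.0 - 0.5 * m
    red_b = 0.5 * m
    img_a = _render_side(rng, mask_a, m, red_a, config)
    img_b = _render_side(rng, mask_b, m, red_b, config)
    return SyntheticSpecimen(
        images=(img_a, img_b), roi_truth=(mask_a, mask_b),
        t=int(t), subject_id=subject_id, mixing_level=m,
    )


def _draw_rates(rng: np.random.Generator, n: int, mean: float, sd: float) -> np.ndarray:
    rates = rng.normal(mean, sd, size=n)
    return np.clip(rates, 1e-6, None)


def generate_calibration_set(config: SyntheticConfig) -> list[SyntheticSpecimen]:
    """Generate the reference-population calibration set.

    Each of ``n_subjects`` subjects draws one personal mixing rate and
    chews one specimen per configured cycle count, giving
    ``n_subjects * len(cycles)`` specimens.
    """
    rng = np.random.default_rng(config.seed)
    rates = _draw_rates(rng, config.n_subjects, config.subject_rate_mean,
                        config.subject_rate_sd)
    specimens = []
    for i in range(config.n_subjects):
        subject_id = f"S{i:03d}"
        for t in config.cycles:
            seed = int(rng.integers(0, 2**31 - 1))
            specimens.append(
                generate_specimen(t, float(rates[i]), config, seed, subject_id)
            )
    return specimens


def generate_diagnosis_cohort(
    n_patients: int, pre_rate_mean: float, post_rate_mean: float,
    T: int, config: SyntheticConfig,
) -> tuple[list[SyntheticSpecimen], list[SyntheticSpecimen]]:
    """Pre/post-treatment patient cohorts, two specimens per appointment.

    Emulates a denture-treatment study: every patient chews two
    specimens at exactly ``T`` strokes before treatment (lower mixing
    rate) and two after (higher rate).  Returns ``(pre, post)`` lists of
    ``2 * n_patients`` specimens each.
    """
    if T <= 0:
        raise ParameterError("T must be positive")
    rng = np.random.default_rng(config.seed)
    # rate spread scales with the cohort mean (same CV as the reference
    # population), so a near-zero pre-treatment mean stays near zero
    cv = config.subject_rate_sd / config.subject_rate_mean
    pre, post = [], []
    for i in range(n_patients):
        pid = f"P{i:03d}"
        r_pre = float(_draw_rates(rng, 1, pre_rate_mean, cv * pre_rate_mean)[0])
        r_post = float(_draw_rates(rng, 1, post_rate_mean, cv * post_rate_mean)[0])
        for rep in range(2):
            seed = int(rng.integers(0, 2**31 - 1))
            s = generate_specimen(T, r_pre, config, seed, pid)
            s.specimen_id = f"{pid}-pre-{rep}"
            pre.append(s)
        for rep in range(2):
            seed = int(rng.integers(0, 2**31 - 1))
            s = generate_specimen(T, r_post, config, seed, pid)
            s.specimen_id = f"{pid}-post-{rep}"
            post.append(s)
    return pre, post


def dataset_digest(specimens: list[SyntheticSpecimen]) -> str:
    """SHA-256 digest over all pixel data and labels (reproducibility check)."""
    h = hashlib.sha256()
    for s in specimens:
        h.update(s.specimen_id.encode())
        h.update(np.int64(s.t).tobytes())
        for img in s.images:
            h.update(np.ascontiguousarray(img).tobytes())
    return h.hexdigest()


def write_dataset(specimens: list[SyntheticSpecimen], outdir) -> pd.DataFrame:
    """Write specimens as PNGs plus a CSV manifest; returns the manifest."""
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rows = []
    for s in specimens:
        for side, img in zip("AB", s.images):
            name = f"{s.specimen_id}-{side}.png"
            Image.fromarray(img).save(outdir / name)
            rows.append({
                "specimen_id": s.specimen_id, "subject_id": s.subject_id,
                "side": side, "t": s.t, "mixing_level": s.mixing_level,
                "path": name,
            })
    manifest = pd.DataFrame(rows)
    manifest.to_csv(outdir / "manifest.csv", index=False)
    return manifest


def load_dataset(manifest_path) -> list[SyntheticSpecimen]:
    """Rebuild specimens from a manifest written by :func:`write_dataset`.

    Ground-truth masks are not stored on disk; reloaded specimens carry
    all-false placeholder masks and are meant for pipeline input only.
    """
    from pathlib import Path

    manifest_path = Path(manifest_path)
    base = manifest_path.parent
    df = pd.read_csv(manifest_path)
    specimens = []
    for sid, grp in df.groupby("specimen_id", sort=False):
        grp = grp.set_index("side")
        imgs = tuple(
            np.asarray(Image.open(base / grp.loc[side, "path"]).convert("RGB"))
            for side in "AB"
        )
        empty = np.zeros(imgs[0].shape[:2], dtype=bool)
        specimens.append(SyntheticSpecimen(
            images=imgs, roi_truth=(empty, empty),
            t=int(grp["t"].iloc[0]), subject_id=str(grp["subject_id"].iloc[0]),
            mixing_level=float(grp["mixing_level"].iloc[0]), specimen_id=str(sid),
        ))
    return specimens
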