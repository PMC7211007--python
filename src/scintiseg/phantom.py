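"""Synthetic planar-scintigram phantoms.

Radioiodine post-ablation whole-body scans of thyroid-cancer patients show a
low-intensity body silhouette, a bright thyroid-remnant focus in the
thyroid-bed region, zero or more smaller metastatic-lymph-node (mLN) foci
lateral/inferior to it, and physiological oral-cavity uptake above — all
degraded by camera blur and count noise, with heavily overlapping gray-scale
ranges between the classes.  This module generates seeded scan/label pairs
with that statistical structure so the whole pipeline is testable without
clinical data.

Labels follow the clinical convention: 0 background (including physiological
uptake), 1 mLN, 2 remnant tissue.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["PhantomSpec", "PlacementError", "generate_scan", "generate_cohort",
           "ellipse_mask"]

LABEL_BACKGROUND = 0
LABEL_MLN = 1
LABEL_REMNANT = 2


class PlacementError(RuntimeError):
    """Raised when foci cannot be placed without overlap."""


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of the synthetic scan generator.

    Intensity means are in 8-bit units; the defaults deliberately overlap
    (remnant brighter than mLN, both above the 160 foreground threshold, oral
    cavity in the same range) to preserve the clinical difficulty of
    separating the mLN from adjacent tissue of similar gray value.
    """

    image_height: int = 230
    image_width: int = 230
    n_mln: int = 2                    # maximum number of mLN foci
    mln_presence_prob: float = 0.8    # P(scan contains >=1 mLN)

    background_mean: float = 12.0
    background_spread: float = 0.0
    silhouette_mean: float = 90.0
    silhouette_spread: float = 6.0
    remnant_mean: float = 205.0
    remnant_spread: float = 18.0
    mln_mean: float = 185.0
    mln_spread: float = 18.0
    oral_mean: float = 195.0
    oral_spread: float = 18.0

    # Half-axes (pixels) drawn uniformly from [lo, hi].
    remnant_axes: tuple[tuple[float, float], tuple[float, float]] = ((11.0, 16.0), (8.0, 12.0))
    mln_axes: tuple[tuple[float, float], tuple[float, float]] = ((5.0, 9.0), (4.0, 7.0))
    oral_axes: tuple[tuple[float, float], tuple[float, float]] = ((8.0, 12.0), (6.0, 9.0))

    blur_sigma: float = 1.2
    noise_scale: float = 0.35         # Poisson count-noise factor; 0 disables
    max_place_attempts: int = 200

    def __post_init__(self) -> None:
        for name in ("background_mean", "silhouette_mean", "remnant_mean",
                     "mln_mean", "oral_mean"):
            v = getattr(self, name)
            if not 0.0 <= v <= 255.0:
                raise ValueError(f"{name}={v} outside [0, 255]")
        if self.blur_sigma < 0:
            raise ValueError("blur_sigma must be >= 0")
        if self.noise_scale < 0:
            raise ValueError("noise_scale must be >= 0")
        if not 0.0 <= self.mln_presence_prob <= 1.0:
            raise ValueError("mln_presence_prob must be in [0, 1]")
        if self.n_mln < 0 or self.n_mln > 3:
            raise ValueError("n_mln must be in 0..3")
        if self.image_height < 32 or self.image_width < 32:
            raise ValueError("image must be at least 32x32")


def ellipse_mask(shape: tuple[int, int], center: tuple[float, float],
                 axes: tuple[float, float], angle: float = 0.0) -> np.ndarray:
    """Boolean raster of a rotated ellipse.

    A pixel (r, c) belongs to the ellipse iff its center lies inside
    ((x'/a)^2 + (y'/b)^2) <= 1 after rotating coordinates by ``angle``
    (radians) about ``center`` = (row, col); ``axes`` = (a, b) are the
    half-axes along the rotated column/row directions.
    """
    rr, cc = np.mgrid[0:shape[0], 0:shape[1]]
    dy = rr - center[0]
    dx = cc - center[1]
    ca, sa = np.cos(angle), np.sin(angle)
    x = dx * ca + dy * sa
    y = -dx * sa + dy * ca
    a, b = axes
    return (x / a) ** 2 + (y / b) ** 2 <= 1.0


def _draw_axes(rng: np.random.Generator,
               ranges: tuple[tuple[float, float], tuple[float, float]]) -> tuple[float, float]:
    (alo, ahi), (blo, bhi) = ranges
    return float(rng.uniform(alo, ahi)), float(rng.uniform(blo, bhi))


def _region_intensity(rng: np.random.Generator, mean: float, spread: float) -> float:
    return float(np.clip(rng.normal(mean, spread) if spread > 0 else mean, 0.0, 255.0))


def generate_scan(spec: PhantomSpec, seed: int) -> tuple[np.ndarray, np.ndarray]:
    """Generate one (scan, labels) pair.

    Rendering order: constant background, body-silhouette ellipse, oral-cavity
    focus (labelled background — physiological uptake is non-pathological),
    remnant focus in the upper-central band, then up to ``n_mln`` mLN foci
    lateral/inferior to the remnant, rejected if they would overlap it or each
    other.  The clean image is blurred, Poisson count noise is applied, and
    the result is clipped to [0, 255] uint8.  The label map records the
    pre-noise geometry.  Identical (spec, seed) give bit-identical outputs.
    """
    rng = np.random.default_rng(np.random.SeedSequence([int(seed) & 0x7FFFFFFF]))
    h, w = spec.image_height, spec.image_width
    img = np.full((h, w), _region_intensity(rng, spec.background_mean,
                                            spec.background_spread), dtype=float)
    labels = np.zeros((h, w), dtype=np.uint8)

    # Body silhouette: a broad vertical ellipse through the image center.
    sil = ellipse_mask((h, w), (h * 0.55, w * 0.5), (w * 0.33, h * 0.52))
    img[sil] = _region_intensity(rng, spec.silhouette_mean, spec.silhouette_spread)

    # Oral cavity: physiological uptake near the top, class 0.
    oc = ellipse_mask(
        (h, w),
        (h * rng.uniform(0.06, 0.12), w * rng.uniform(0.42, 0.58)),
        _draw_axes(rng, spec.oral_axes),
        rng.uniform(0, np.pi),
    )
    img[oc] = _region_intensity(rng, spec.oral_mean, spec.oral_spread)

    # Remnant: thyroid bed, upper-central band.
    rem = ellipse_mask(
        (h, w),
        (h * rng.uniform(0.26, 0.36), w * rng.uniform(0.42, 0.58)),
        _draw_axes(rng, spec.remnant_axes),
        rng.uniform(0, np.pi),
    )
    img[rem] = _region_intensity(rng, spec.remnant_mean, spec.remnant_spread)
    labels[rem] = LABEL_REMNANT

    # mLN foci: smaller, lateral/inferior to the remnant, disjoint from it.
    n_mln = 0
    if spec.n_mln > 0 and rng.uniform() < spec.mln_presence_prob:
        n_mln = int(rng.integers(1, spec.n_mln + 1))
    placed = 0
    for _ in range(spec.max_place_attempts):
        if placed == n_mln:
            break
        side = 1.0 if rng.uniform() < 0.5 else -1.0
        center = (h * rng.uniform(0.38, 0.62),
                  w * (0.5 + side * rng.uniform(0.08, 0.28)))
        m = ellipse_mask((h, w), center, _draw_axes(rng, spec.mln_axes),
                         rng.uniform(0, np.pi))
        if (m & (labels != LABEL_BACKGROUND)).any() or (m & oc).any():
            continue
        img[m] = _region_intensity(rng, spec.mln_mean, spec.mln_spread)
        labels[m] = LABEL_MLN
        placed += 1
    if placed < n_mln:
        raise PlacementError(
            f"could not place {n_mln} mLN foci without overlap in "
            f"{spec.max_place_attempts} attempts")

    if spec.blur_sigma > 0:
        from scipy.ndimage import gaussian_filter
        img = gaussian_filter(img, spec.blur_sigma, mode="reflect")
    if spec.noise_scale > 0:
        # Gamma-camera count statistics: fewer effective counts per pixel as
        # noise_scale grows.  counts ~ Poisson(I / s), image = counts * s.
        s = spec.noise_scale
        img = rng.poisson(np.clip(img, 0, None) / s).astype(float) * s
    scan = np.clip(np.rint(img), 0, 255).astype(np.uint8)
    return scan, labels


def _item_seed(seed: int, index: int) -> np.random.SeedSequence:
    # Splittable counter scheme: each cohort item gets an independent stream
    # derived from (seed, index), stable under reordering.
    return np.random.SeedSequence(entropy=int(seed) & 0x7FFFFFFF,
                                  spawn_key=(int(index),))


def generate_cohort(spec: PhantomSpec, n: int, seed: int) -> list[tuple[np.ndarray, np.ndarray]]:
    """Generate ``n`` independent scan/label pairs with per-item derived seeds."""
    if n < 1:
        raise ValueError("n must be >= 1")
    out = []
    for i in range(n):
        item_seed = int(_item_seed(seed, i).generate_state(1)[0] & 0x7FFFFFFF)
        out.append(generate_scan(spec, item_seed))
    return out
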