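"""Patch extraction, augmentation and masked multichannel stacks.

The pipeline trains a pixel classifier on 230x230 patches cropped around the
regions of interest.  Each patch is augmented geometrically (horizontal and
vertical flips, rotations by 90/180/270 degrees) and by Gaussian smoothing at
sigma = 2, 4 and 8; the smoothed channels double as per-pixel features.  The
foreground is isolated by thresholding the 8-bit intensities at 160 and
multiplying every channel by the binary mask.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import ndimage

__all__ = ["Patch", "MaskedStack", "crop_patch", "augment_geometric",
           "GEOMETRIC_TRANSFORMS", "gaussian_stack", "threshold_mask",
           "mask_stack", "remove_unwanted_components", "augment_full",
           "DEFAULT_THRESHOLD", "DEFAULT_SIGMAS"]

DEFAULT_THRESHOLD = 160
DEFAULT_SIGMAS = (2.0, 4.0, 8.0)

#: Fixed order of the geometric augmentation variants.
GEOMETRIC_TRANSFORMS = ("flip_h", "flip_v", "rot90", "rot180", "rot270")


@dataclass(frozen=True)
class Patch:
    """An intensity patch with its aligned label map and provenance."""

    intensities: np.ndarray        # 2-D uint8
    labels: np.ndarray             # 2-D uint8, codes {0, 1, 2}
    source_id: str = ""
    origin: tuple[int, int] = (0, 0)   # (row, col) crop origin, 0-based

    def __post_init__(self) -> None:
        if self.intensities.shape != self.labels.shape:
            raise ValueError("intensity/label shape mismatch: "
                             f"{self.intensities.shape} vs {self.labels.shape}")
        if min(self.origin) < 0:
            raise ValueError(f"negative crop origin {self.origin}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.intensities.shape


@dataclass(frozen=True)
class MaskedStack:
    """Foreground-masked feature channels in fixed order (raw, s2, s4, s8)."""

    channels: np.ndarray           # (n_channels, H, W) float
    mask: np.ndarray               # (H, W) bool
    sigmas: tuple[float, ...] = DEFAULT_SIGMAS

    def __post_init__(self) -> None:
        if self.channels.shape[1:] != self.mask.shape:
            raise ValueError("channel/mask shape mismatch")


def crop_patch(scan: np.ndarray, labels: np.ndarray, origin: tuple[int, int],
               size: int = 230, source_id: str = "") -> Patch:
    """Extract the exact ``size`` x ``size`` half-open window at ``origin``.

    No implicit padding: a window leaving the scan raises ``ValueError``
    naming the offending origin.
    """
    r, c = origin
    if r < 0 or c < 0 or r + size > scan.shape[0] or c + size > scan.shape[1]:
        raise ValueError(
            f"crop window origin={origin} size={size} exceeds scan shape {scan.shape}")
    return Patch(intensities=np.ascontiguousarray(scan[r:r + size, c:c + size]),
                 labels=np.ascontiguousarray(labels[r:r + size, c:c + size]),
                 source_id=source_id, origin=(r, c))


def _apply_geometric(a: np.ndarray, name: str) -> np.ndarray:
    if name == "flip_h":
        return a[:, ::-1].copy()
    if name == "flip_v":
        return a[::-1, :].copy()
    if name == "rot90":
        return np.rot90(a, 1).copy()
    if name == "rot180":
        return np.rot90(a, 2).copy()
    if name == "rot270":
        return np.rot90(a, 3).copy()
    raise ValueError(f"unknown transform {name!r}")


def augment_geometric(patch: Patch) -> list[Patch]:
    """The five geometric variants, labels transformed identically.

    Order is fixed: flip-H, flip-V, rot90, rot180, rot270.  Rotations change
    the shape of non-square patches, so those are rejected.
    """
    h, w = patch.shape
    if h != w:
        raise ValueError(f"geometric augmentation needs a square patch, got {h}x{w}")
    out = []
    for name in GEOMETRIC_TRANSFORMS:
        out.append(replace(patch,
                           intensities=_apply_geometric(patch.intensities, name),
                           labels=_apply_geometric(patch.labels, name),
                           source_id=f"{patch.source_id}:{name}"))
    return out


def gaussian_stack(patch: Patch | np.ndarray,
                   sigmas: tuple[float, ...] = DEFAULT_SIGMAS) -> np.ndarray:
    """Raw channel plus one Gaussian-smoothed channel per sigma.

    Smoothing uses a square truncated kernel of half-width ceil(3*sigma) with
    reflective boundaries, computed on a floating-point copy of the 8-bit
    intensities.  Returns an array of shape (1 + len(sigmas), H, W).
    """
    img = patch.intensities if isinstance(patch, Patch) else patch
    img = np.asarray(img, dtype=float)
    chans = [img.copy()]
    for s in sigmas:
        if s <= 0:
            raise ValueError(f"sigma must be positive, got {s}")
        trunc = np.ceil(3.0 * s) / s  # half-width ceil(3*sigma) pixels
        chans.append(ndimage.gaussian_filter(img, s, mode="reflect", truncate=trunc))
    return np.stack(chans)


def threshold_mask(patch: Patch | np.ndarray, threshold: int = DEFAULT_THRESHOLD) -> np.ndarray:
    """Foreground mask: 1 where intensity >= threshold (foreground-preserving)."""
    if not 0 <= threshold <= 255:
        raise ValueError(f"threshold {threshold} outside [0, 255]")
    img = patch.intensities if isinstance(patch, Patch) else patch
    return np.asarray(img) >= threshold


def mask_stack(mask: np.ndarray, channels: np.ndarray,
               sigmas: tuple[float, ...] = DEFAULT_SIGMAS) -> MaskedStack:
    """Multiply every channel by the binary foreground mask."""
    mask = np.asarray(mask, dtype=bool)
    channels = np.asarray(channels, dtype=float)
    if channels.shape[1:] != mask.shape:
        raise ValueError(f"mask shape {mask.shape} does not match channels "
                         f"{channels.shape[1:]}")
    return MaskedStack(channels=channels * mask[None, :, :], mask=mask,
                       sigmas=sigmas)


def remove_unwanted_components(mask: np.ndarray, min_area: int = 10) -> np.ndarray:
    """Drop connected components (8-connectivity) with area below ``min_area``.

    Used to strip small physiological-uptake and background specks from the
    foreground mask before feature extraction.
    """
    mask = np.asarray(mask, dtype=bool)
    lab, n = ndimage.label(mask, structure=np.ones((3, 3), dtype=int))
    if n == 0:
        return mask.copy()
    areas = np.bincount(lab.ravel())
    keep = np.zeros(n + 1, dtype=bool)
    keep[1:] = areas[1:] >= min_area
    return keep[lab]


def augment_full(patch: Patch, sigmas: tuple[float, ...] = DEFAULT_SIGMAS) -> list[Patch]:
    """Full augmentation of one patch: 1 original + 5 geometric + one
    Gaussian-smoothed variant per sigma (9 items with the default sigmas).

    Smoothed variants keep the original label map; their intensities are the
    smoothed channel rounded back to uint8.
    """
    items = [patch] + augment_geometric(patch)
    stack = gaussian_stack(patch, sigmas)
    for s, chan in zip(sigmas, stack[1:]):
        items.append(replace(patch,
                             intensities=np.clip(np.rint(chan), 0, 255).astype(np.uint8),
                             source_id=f"{patch.source_id}:gauss{s:g}"))
    return items
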