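"""Pixel-position priors.

Across training patches aligned on the region of interest, the probability of
a pixel *position* being mLN or remnant is estimated as the per-position
frequency of that label:

    p_met[r, c] = (1/N) sum_i 1{label_i[r, c] == 1}
    p_rem[r, c] = (1/N) sum_i 1{label_i[r, c] == 2}

with N the number of training label maps.  These two maps are fed to the
classifier as per-pixel features alongside the masked intensity channels.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

__all__ = ["PriorMaps", "estimate_priors", "prior_features",
           "save_priors", "load_priors"]


@dataclass(frozen=True)
class PriorMaps:
    p_met: np.ndarray     # P(position | mLN), float in [0, 1]
    p_rem: np.ndarray     # P(position | remnant)
    n_images: int

    def __post_init__(self) -> None:
        if self.p_met.shape != self.p_rem.shape:
            raise ValueError("prior map shapes differ")

    @property
    def shape(self) -> tuple[int, int]:
        return self.p_met.shape


def estimate_priors(label_patches: Sequence[np.ndarray]) -> PriorMaps:
    """Per-position label frequencies over N aligned label maps."""
    if len(label_patches) == 0:
        raise ValueError("need at least one label patch")
    shape = np.asarray(label_patches[0]).shape
    met = np.zeros(shape, dtype=float)
    rem = np.zeros(shape, dtype=float)
    for lab in label_patches:
        lab = np.asarray(lab)
        if lab.shape != shape:
            raise ValueError(f"label shape {lab.shape} != {shape}")
        met += lab == 1
        rem += lab == 2
    n = len(label_patches)
    return PriorMaps(p_met=met / n, p_rem=rem / n, n_images=n)


def prior_features(priors: PriorMaps, position: tuple[int, int]) -> tuple[float, float]:
    """(p_met, p_rem) at one (row, col) position."""
    r, c = position
    h, w = priors.shape
    if not (0 <= r < h and 0 <= c < w):
        raise IndexError(f"position {position} outside prior maps of shape {(h, w)}")
    return float(priors.p_met[r, c]), float(priors.p_rem[r, c])


def save_priors(priors: PriorMaps, path: str | Path) -> None:
    """Persist as a 2-channel float TIFF plus a JSON sidecar (N, class codes)."""
    import tifffile

    path = Path(path)
    tifffile.imwrite(path, np.stack([priors.p_met, priors.p_rem]).astype(np.float32))
    sidecar = {"n_images": priors.n_images,
               "channels": {"0": "p_met (class 1)", "1": "p_rem (class 2)"}}
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar, indent=2))


def load_priors(path: str | Path) -> PriorMaps:
    import tifffile

    path = Path(path)
    arr = tifffile.imread(path).astype(float)
    meta = json.loads(path.with_suffix(path.suffix + ".json").read_text())
    return PriorMaps(p_met=arr[0], p_rem=arr[1], n_images=int(meta["n_images"]))
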