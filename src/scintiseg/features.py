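"""Per-pixel feature tables for the pixel-wise classifier.

Each sampled pixel becomes one row with six features — the masked raw
intensity and the three masked Gaussian channels (each scaled to [0, 1] by
/255), plus the two pixel-position priors — and its ground-truth label.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .preprocess import MaskedStack
from .priors import PriorMaps

__all__ = ["FEATURE_COLUMNS", "build_feature_table", "feature_matrix"]

FEATURE_COLUMNS = ["f_raw", "f_s2", "f_s4", "f_s8", "p_met", "p_rem"]
TABLE_COLUMNS = ["patch_id", "row", "col", *FEATURE_COLUMNS, "label"]


def _pixel_features(stack: MaskedStack, priors: PriorMaps,
                    rows: np.ndarray, cols: np.ndarray) -> np.ndarray:
    inten = stack.channels[:, rows, cols].T / 255.0     # (n, 4)
    pm = priors.p_met[rows, cols]
    pr = priors.p_rem[rows, cols]
    return np.column_stack([inten, pm, pr])


def build_feature_table(stack: MaskedStack, priors: PriorMaps,
                        labels: np.ndarray, *, background_ratio: float = 1.0,
                        all_pixels: bool = False, seed: int = 0,
                        patch_id: str = "") -> pd.DataFrame:
    """Assemble the per-pixel table for one patch.

    Default sampling takes every mask-foreground pixel plus a uniform random
    sample of background (off-mask) pixels of size ``background_ratio`` times
    the foreground count (seeded).  ``all_pixels=True`` keeps every pixel of
    the patch instead, reproducing a training set with the full class
    imbalance.
    """
    labels = np.asarray(labels)
    if stack.mask.shape != labels.shape or priors.shape != labels.shape:
        raise ValueError("stack, priors and labels must share one shape")
    if all_pixels:
        rr, cc = np.mgrid[0:labels.shape[0], 0:labels.shape[1]]
        rows, cols = rr.ravel(), cc.ravel()
    else:
        fg_r, fg_c = np.nonzero(stack.mask)
        bg_r, bg_c = np.nonzero(~stack.mask)
        n_bg = int(round(background_ratio * fg_r.size))
        if fg_r.size == 0 and n_bg == 0:
            raise ValueError("empty mask and zero background sample: no pixels to extract")
        rng = np.random.default_rng(seed)
        if n_bg > 0 and bg_r.size > 0:
            idx = rng.choice(bg_r.size, size=min(n_bg, bg_r.size), replace=False)
            rows = np.concatenate([fg_r, bg_r[idx]])
            cols = np.concatenate([fg_c, bg_c[idx]])
        else:
            rows, cols = fg_r, fg_c
    feats = _pixel_features(stack, priors, rows, cols)
    table = pd.DataFrame({
        "patch_id": patch_id, "row": rows, "col": cols,
        **{name: feats[:, j] for j, name in enumerate(FEATURE_COLUMNS)},
        "label": labels[rows, cols].astype(int),
    })
    return table[TABLE_COLUMNS]


def feature_matrix(table: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    """(X, y) views of a feature table for training/prediction."""
    return table[FEATURE_COLUMNS].to_numpy(dtype=float), table["label"].to_numpy(dtype=int)
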