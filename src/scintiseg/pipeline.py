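"""End-to-end orchestration: training the pixel classifier on a set of
labelled patches and segmenting new scans with it.

``train_pipeline`` wires the stages together in the canonical order:
geometric/Gaussian augmentation of the training patches, pixel-position
prior estimation on the training labels, threshold masking and masked
Gaussian stacks, per-pixel feature sampling, then mini-batch Adam training
of the network.  ``predict_pipeline`` applies the same preprocessing to a
scan, classifies every foreground pixel, and optionally size-filters the
result.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .config import RunConfig
from .features import build_feature_table
from .mfdn import (MFDNModel, SegmentationResult, build_model, predict_labelmap,
                   train)
from .postprocess import size_filter
from .preprocess import (Patch, augment_full, augment_geometric, gaussian_stack,
                         mask_stack, remove_unwanted_components, threshold_mask)
from .priors import PriorMaps, estimate_priors

__all__ = ["FittedPipeline", "train_pipeline", "predict_pipeline"]


@dataclass
class FittedPipeline:
    model: MFDNModel
    priors: PriorMaps
    config: RunConfig
    curve: pd.DataFrame
    seed: int = 0

    @property
    def final_val_loss(self) -> float:
        """Last recorded validation loss — the generalisation error proxy."""
        vals = self.curve["val_loss"].dropna()
        return float(vals.iloc[-1]) if len(vals) else float("nan")


def _augmented_patches(items: Sequence[tuple[np.ndarray, np.ndarray]],
                       cfg: RunConfig) -> list[Patch]:
    patches = []
    for i, (scan, labels) in enumerate(items):
        p = Patch(intensities=np.asarray(scan, dtype=np.uint8),
                  labels=np.asarray(labels, dtype=np.uint8), source_id=f"item{i}")
        if cfg.augment_geometric and cfg.augment_gaussian:
            patches.extend(augment_full(p, cfg.sigmas))
        elif cfg.augment_geometric:
            patches.extend([p, *augment_geometric(p)])
        else:
            patches.append(p)
    return patches


def _table_for_patch(patch: Patch, priors: PriorMaps, cfg: RunConfig,
                     seed: int) -> pd.DataFrame | None:
    """Feature table for one patch, or None when the patch has no foreground
    (e.g. a heavily smoothed variant falling entirely below the threshold)."""
    mask = threshold_mask(patch, cfg.threshold)
    if cfg.mask_min_area > 0:
        mask = remove_unwanted_components(mask, cfg.mask_min_area)
    if not cfg.all_pixels and not mask.any():
        return None
    stack = mask_stack(mask, gaussian_stack(patch, cfg.sigmas), sigmas=cfg.sigmas)
    return build_feature_table(stack, priors, patch.labels,
                               background_ratio=cfg.background_ratio,
                               all_pixels=cfg.all_pixels, seed=seed,
                               patch_id=patch.source_id)


def train_pipeline(items: Sequence[tuple[np.ndarray, np.ndarray]],
                   cfg: RunConfig | None = None, *, seed: int = 0,
                   val_items: Sequence[tuple[np.ndarray, np.ndarray]] | None = None,
                   ) -> FittedPipeline:
    """Fit the whole pipeline on (scan, labels) patch pairs.

    If ``val_items`` is not given, the last ``val_fraction`` of a seeded
    shuffle of ``items`` is held out for the validation curve.  Priors are
    estimated from the training items only (augmented variants included when
    configured), never from validation data.
    """
    cfg = cfg or RunConfig()
    items = list(items)
    if val_items is None and cfg.val_fraction > 0 and len(items) >= 5:
        rng = np.random.default_rng(seed)
        order = rng.permutation(len(items))
        n_val = max(1, int(round(cfg.val_fraction * len(items))))
        val_items = [items[i] for i in order[:n_val]]
        items = [items[i] for i in order[n_val:]]
    patches = _augmented_patches(items, cfg)

    prior_source = patches if cfg.priors_use_augmented else [
        Patch(np.asarray(s, dtype=np.uint8), np.asarray(l, dtype=np.uint8))
        for s, l in items]
    priors = estimate_priors([p.labels for p in prior_source])

    train_tables = [t for t in
                    (_table_for_patch(p, priors, cfg, seed=seed + 7919 * j)
                     for j, p in enumerate(patches)) if t is not None]
    if not train_tables:
        raise ValueError("no training patch has foreground pixels above the threshold")
    train_table = pd.concat(train_tables, ignore_index=True)
    val_table = None
    if val_items:
        val_tables = [t for t in
                      (_table_for_patch(
                          Patch(np.asarray(s, dtype=np.uint8),
                                np.asarray(l, dtype=np.uint8), source_id=f"val{j}"),
                          priors, cfg, seed=seed + 104729 + j)
                       for j, (s, l) in enumerate(val_items)) if t is not None]
        val_table = pd.concat(val_tables, ignore_index=True) if val_tables else None

    model = build_model(input_dim=6, activation=cfg.activation, seed=seed)
    model, curve = train(model, train_table, val_table, cfg.train_config(seed=seed))
    return FittedPipeline(model=model, priors=priors, config=cfg, curve=curve,
                          seed=seed)


def predict_pipeline(fitted: FittedPipeline, scan: np.ndarray, *,
                     postprocess: bool | None = None,
                     scan_id: str = "") -> SegmentationResult:
    """Segment one scan with a fitted pipeline."""
    cfg = fitted.config
    result = predict_labelmap(fitted.model, scan, fitted.priors,
                              threshold=cfg.threshold, sigmas=cfg.sigmas,
                              scan_id=scan_id)
    do_post = cfg.postprocess if postprocess is None else postprocess
    if do_post:
        filtered = size_filter(result.labels, cfg.min_area, cfg.connectivity,
                               classes=cfg.filter_classes)
        result = SegmentationResult(labels=filtered,
                                    probabilities=result.probabilities,
                                    model_id=result.model_id, scan_id=scan_id)
    return result
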