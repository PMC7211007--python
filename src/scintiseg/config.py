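"""Run configuration: defaults, YAML loading, validation.

Defaults encode the reference training recipe: 230x230 patches, foreground
threshold 160, Gaussian sigmas 2/4/8, 20 epochs of Adam at batch 64 with
initial learning rate 1e-3 dropped x0.1 every 10 epochs, L2 1e-4, 30-px
size filter, five-fold cross-validation.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass
from pathlib import Path

import yaml

__all__ = ["RunConfig", "load_config", "config_hash"]

# field name -> (lo, hi) inclusive range checks for scalar numeric fields
_RANGES = {
    "patch_size": (16, 4096),
    "threshold": (0, 255),
    "epochs": (0, 10000),
    "batch_size": (1, 1 << 20),
    "learning_rate": (1e-12, 10.0),
    "lr_drop_factor": (1e-12, 1.0),
    "lr_drop_period": (1, 10000),
    "l2": (0.0, 1.0),
    "beta1": (0.0, 1.0),
    "beta2": (0.0, 1.0),
    "epsilon": (1e-300, 1.0),
    "validation_frequency": (1, 1 << 31),
    "background_ratio": (0.0, 1000.0),
    "mask_min_area": (0, 1 << 20),
    "min_area": (1, 1 << 20),
    "connectivity": (4, 8),
    "k": (2, 1000),
    "val_fraction": (0.0, 0.9),
}


@dataclass(frozen=True)
class RunConfig:
    # preprocessing
    patch_size: int = 230
    threshold: int = 160
    sigmas: tuple[float, ...] = (2.0, 4.0, 8.0)
    mask_min_area: int = 10            # small-speck removal; 0 disables
    augment_geometric: bool = True
    augment_gaussian: bool = True      # smoothed variants as extra train items
    priors_use_augmented: bool = True
    # sampling
    background_ratio: float = 1.0
    all_pixels: bool = False
    val_fraction: float = 0.2
    # network / optimisation
    activation: str = "relu"
    epochs: int = 20
    batch_size: int = 64
    learning_rate: float = 1e-3
    lr_drop_factor: float = 0.1
    lr_drop_period: int = 10
    l2: float = 1e-4
    beta1: float = 0.9
    beta2: float = 0.999
    epsilon: float = 1e-8
    validation_frequency: int = 1200
    # post-processing / evaluation
    postprocess: bool = True
    min_area: int = 30
    connectivity: int = 8
    filter_classes: tuple[int, ...] = (1, 2)
    k: int = 5

    def __post_init__(self) -> None:
        errors = _range_errors(dataclasses.asdict(self))
        if self.activation not in ("relu", "sigmoid", "tanh"):
            errors.append(f"activation={self.activation!r} not in relu/sigmoid/tanh")
        if any(s <= 0 for s in self.sigmas):
            errors.append(f"sigmas={self.sigmas} must all be positive")
        if self.connectivity not in (4, 8):
            errors.append(f"connectivity={self.connectivity} must be 4 or 8")
        if errors:
            raise ValueError("invalid configuration: " + "; ".join(errors))

    def train_config(self, seed: int = 0):
        from .mfdn import TrainConfig
        return TrainConfig(epochs=self.epochs, batch_size=self.batch_size,
                           learning_rate=self.learning_rate,
                           lr_drop_factor=self.lr_drop_factor,
                           lr_drop_period=self.lr_drop_period, l2=self.l2,
                           beta1=self.beta1, beta2=self.beta2,
                           epsilon=self.epsilon,
                           validation_frequency=self.validation_frequency,
                           seed=seed)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["sigmas"] = list(d["sigmas"])
        d["filter_classes"] = list(d["filter_classes"])
        return d


def _range_errors(d: dict) -> list[str]:
    errors = []
    for name, (lo, hi) in _RANGES.items():
        v = d.get(name)
        if v is not None and not lo <= v <= hi:
            errors.append(f"{name}={v} outside [{lo}, {hi}]")
    return errors


def load_config(path: str | Path | None = None, overrides: dict | None = None) -> RunConfig:
    """Build a validated RunConfig from a YAML file and/or override dict.

    Unknown keys and out-of-range values raise ``ValueError`` listing every
    offender.  An empty or missing file yields the full default set.
    """
    raw: dict = {}
    if path is not None:
        text = Path(path).read_text()
        loaded = yaml.safe_load(text)
        if loaded is None:
            loaded = {}
        if not isinstance(loaded, dict):
            raise ValueError(f"config file {path} must contain a mapping")
        raw.update(loaded)
    if overrides:
        raw.update(overrides)
    known = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = sorted(set(raw) - known)
    if unknown:
        raise ValueError("invalid configuration: unknown keys: " + ", ".join(unknown))
    for name in ("sigmas", "filter_classes"):
        if name in raw and isinstance(raw[name], list):
            raw[name] = tuple(raw[name])
    return RunConfig(**raw)


def config_hash(cfg: RunConfig) -> str:
    return hashlib.sha256(json.dumps(cfg.to_dict(), sort_keys=True).encode()).hexdigest()[:16]
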