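"""Reading and writing scans, label maps and run manifests.

Scans are 8-bit grayscale PNG or TIFF.  Label maps are indexed PNG with a
fixed three-entry palette — 0 black (background), 1 red (mLN), 2 green
(remnant) — matching the display convention for localization overlays.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
from PIL import Image

__all__ = ["read_scan", "write_scan", "read_labelmap", "write_labelmap",
           "write_manifest", "LABEL_PALETTE"]

#: class code -> RGB
LABEL_PALETTE = {0: (0, 0, 0), 1: (255, 0, 0), 2: (0, 255, 0)}


def read_scan(path: str | Path) -> np.ndarray:
    """Load an 8-bit grayscale PNG/TIFF scan as a uint8 array."""
    img = Image.open(path)
    if img.mode != "L":
        raise ValueError(f"{path}: expected 8-bit grayscale (mode 'L'), "
                         f"got mode {img.mode!r}")
    return np.asarray(img, dtype=np.uint8)


def write_scan(scan: np.ndarray, path: str | Path) -> None:
    scan = np.asarray(scan)
    if scan.dtype != np.uint8:
        raise ValueError(f"scan must be uint8, got {scan.dtype}")
    Image.fromarray(scan, mode="L").save(path)


def _flat_palette() -> list[int]:
    flat = []
    for code in range(3):
        flat.extend(LABEL_PALETTE[code])
    return flat


def write_labelmap(labels: np.ndarray, path: str | Path) -> None:
    """Write a {0,1,2} label map as indexed PNG with the fixed palette."""
    labels = np.asarray(labels)
    bad = np.setdiff1d(np.unique(labels), [0, 1, 2])
    if bad.size:
        raise ValueError(f"label values outside {{0,1,2}}: {bad.tolist()}")
    img = Image.fromarray(labels.astype(np.uint8), mode="P")
    img.putpalette(_flat_palette())
    img.save(path)


def read_labelmap(path: str | Path) -> np.ndarray:
    """Read an indexed-PNG label map, rejecting foreign palettes or codes."""
    img = Image.open(path)
    if img.mode != "P":
        raise ValueError(f"{path}: expected indexed PNG (mode 'P'), got {img.mode!r}")
    arr = np.asarray(img, dtype=np.uint8)
    bad = np.setdiff1d(np.unique(arr), [0, 1, 2])
    if bad.size:
        raise ValueError(f"{path}: palette entries outside {{0,1,2}}: {bad.tolist()}")
    palette = img.getpalette()[:9]
    if palette != _flat_palette():
        raise ValueError(f"{path}: unknown label palette {palette}")
    return arr


def write_manifest(out_dir: str | Path, *, command: str, seed: int | None,
                   config_dict: dict, extra: dict | None = None) -> Path:
    """Run manifest: config hash, seed and package version, enough to
    reproduce the command's outputs bit-for-bit."""
    from . import __version__

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    payload = {
        "command": command,
        "seed": seed,
        "config": config_dict,
        "config_sha256": hashlib.sha256(
            json.dumps(config_dict, sort_keys=True).encode()).hexdigest(),
        "package_version": __version__,
    }
    if extra:
        payload.update(extra)
    path = out_dir / "manifest.json"
    path.write_text(json.dumps(payload, indent=2))
    return path
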