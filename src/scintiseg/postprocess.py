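"""Connected-component size filtering of predicted label maps.

Small spurious foci — typically where remnant predictions overlap the oral
cavity — are removed by relabelling, per class, every connected component
with area below a minimum (default 30 px, 8-connectivity) to background.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

__all__ = ["size_filter", "DEFAULT_MIN_AREA"]

DEFAULT_MIN_AREA = 30

_STRUCTURES = {
    4: np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=int),
    8: np.ones((3, 3), dtype=int),
}


def size_filter(labels: np.ndarray, min_area: int = DEFAULT_MIN_AREA,
                connectivity: int = 8,
                classes: tuple[int, ...] = (1, 2)) -> np.ndarray:
    """Remove per-class components with area < ``min_area``.

    Classes are filtered independently; components of exactly ``min_area``
    pixels survive; class 0 is never touched.  Idempotent and never adds
    pixels.
    """
    if min_area < 1:
        raise ValueError("min_area must be >= 1")
    if connectivity not in _STRUCTURES:
        raise ValueError("connectivity must be 4 or 8")
    labels = np.asarray(labels)
    out = labels.copy()
    structure = _STRUCTURES[connectivity]
    for cls in classes:
        comp, n = ndimage.label(labels == cls, structure=structure)
        if n == 0:
            continue
        areas = np.bincount(comp.ravel())
        drop = np.zeros(n + 1, dtype=bool)
        drop[1:] = areas[1:] < min_area
        out[drop[comp]] = 0
    return out
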