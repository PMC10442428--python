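"""Segmentation scoring: the 3-D soft dice overlap.

    DS = 2 sum(t_i g_i) / (sum(t_i^2) + sum(g_i^2) + eps),   eps = 1e-5

with binary prediction ``t`` and ground truth ``g``.  The stabilizing
``eps`` makes the two-empty-masks case well defined (DS = 0) and keeps
DS strictly below 1 even for a perfect match.
"""

from __future__ import annotations

import numpy as np

from .errors import ShapeMismatchError

__all__ = ["soft_dice"]

DEFAULT_EPSILON = 1e-5


def soft_dice(pred: np.ndarray, truth: np.ndarray, epsilon: float = DEFAULT_EPSILON) -> float:
    """Soft dice score between two binary masks of identical shape.

    Works for 2-D or 3-D arrays; any nonzero entry counts as 1.
    """
    pred = np.asarray(pred)
    truth = np.asarray(truth)
    if pred.shape != truth.shape:
        raise ShapeMismatchError(f"prediction {pred.shape} vs ground truth {truth.shape}")
    t = (pred != 0).astype(float)
    g = (truth != 0).astype(float)
    num = 2.0 * float((t * g).sum())
    den = float((t * t).sum() + (g * g).sum()) + epsilon
    return num / den
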