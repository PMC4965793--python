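"""Plug-in (empirical) information measures on count tensors.

All quantities are in bits (base-2 logarithms) and use the maximum-likelihood
plug-in estimator: cell probabilities are cell counts divided by the total,
and ``0 * log 0`` is taken to be 0.

The central quantity is the interaction information

    I(X1; X2; Y) = I(X1, X2; Y) - I(X1; Y) - I(X2; Y)

computed from a 3-D contingency tensor with axes (x1 bin, x2 bin, class).
Positive values indicate synergy (the pair predicts the class better than
its parts), negative values redundancy.
"""

from __future__ import annotations

import numpy as np

__all__ = ["entropy_bits", "interaction_bits", "conditional_decomposition"]


def entropy_bits(counts: np.ndarray) -> float:
    """Shannon entropy in bits of the empirical distribution of ``counts``.

    ``counts`` may have any shape; it is flattened. Zero cells contribute 0.
    """
    c = np.asarray(counts, dtype=float).ravel()
    if np.any(c < 0):
        raise ValueError("counts must be nonnegative")
    total = c.sum()
    if total <= 0:
        return 0.0
    p = c[c > 0] / total
    return float(-(p * np.log2(p)).sum())


def _validate_tensor(cell_counts: np.ndarray) -> np.ndarray:
    t = np.asarray(cell_counts, dtype=float)
    if t.ndim != 3:
        raise ValueError("cell_counts must be a 3-D tensor (x1 bins, x2 bins, classes)")
    if np.any(t < 0):
        raise ValueError("cell_counts must be nonnegative")
    if t.sum() <= 0:
        raise ValueError("cell_counts must contain at least one observation")
    return t


def interaction_bits(cell_counts: np.ndarray) -> float:
    """Interaction information I(X1;X2;Y) in bits from a 3-D count tensor.

    Uses the entropy expansion
    ``-H(X1,X2,Y) + H(X1,X2) + H(X1,Y) + H(X2,Y) - H(X1) - H(X2) - H(Y)``.
    A tensor with all mass in one cell is degenerate and returns 0.
    """
    t = _validate_tensor(cell_counts)
    h123 = entropy_bits(t)
    h12 = entropy_bits(t.sum(axis=2))
    h13 = entropy_bits(t.sum(axis=1))
    h23 = entropy_bits(t.sum(axis=0))
    h1 = entropy_bits(t.sum(axis=(1, 2)))
    h2 = entropy_bits(t.sum(axis=(0, 2)))
    h3 = entropy_bits(t.sum(axis=(0, 1)))
    return -h123 + h12 + h13 + h23 - h1 - h2 - h3


def conditional_decomposition(cell_counts: np.ndarray) -> tuple[float, float]:
    """The two conditional forms of the interaction information.

    Returns ``(I(X2;Y|X1) - I(X2;Y), I(X1;Y|X2) - I(X1;Y))``.  Both components
    are algebraically identical to :func:`interaction_bits`; the function is
    exposed as a numerical self-check of the entropy bookkeeping.
    """
    t = _validate_tensor(cell_counts)
    h123 = entropy_bits(t)
    h12 = entropy_bits(t.sum(axis=2))
    h13 = entropy_bits(t.sum(axis=1))
    h23 = entropy_bits(t.sum(axis=0))
    h1 = entropy_bits(t.sum(axis=(1, 2)))
    h2 = entropy_bits(t.sum(axis=(0, 2)))
    h3 = entropy_bits(t.sum(axis=(0, 1)))
    # I(X2;Y|X1) = H(X2,X1) + H(Y,X1) - H(X1) - H(X1,X2,Y)
    i_23_g1 = h12 + h13 - h1 - h123
    i_23 = h2 + h3 - h23
    # I(X1;Y|X2) = H(X1,X2) + H(Y,X2) - H(X2) - H(X1,X2,Y)
    i_13_g2 = h12 + h23 - h2 - h123
    i_13 = h1 + h3 - h13
    return (i_23_g1 - i_23, i_13_g2 - i_13)
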