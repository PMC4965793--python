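"""Dynamic programming over superclump boundaries.

Both the two- and three-variable grid optimizations reduce to the same
problem: with the fixed-axis partition frozen, the objective (mutual
information, resp. interaction information) decomposes as a constant plus a
sum of per-column scores, where a column is a contiguous interval of
superclumps.  The optimum over all partitions of the free axis into ``l``
columns whose cuts lie on superclump boundaries is then found exactly by the
standard last-cut recursion.

Column scores, with p's relative to the full sample size n and
``g(m) = (m/n) * log2(m/n)``:

* two variables, fixed row partition Q:
  ``phi2(col) = -g(m_col) + sum_q g(m_{col,q})`` and
  ``I(P;Q) = H(Q) + sum_cols phi2``;
* three variables, fixed x1 partition and class axis:
  ``phi3(col) = -sum_i g(m_{i,col}) - sum_j g(m_{col,j}) + g(m_col)
  + sum_ij g(m_{i,col,j})`` and
  ``I(X1;X2;Y) = K + sum_cols phi3`` with ``K = H(X1,Y) - H(X1) - H(Y)``
  (i.e. ``-I(X1;Y)``), which does not depend on the column partition.
"""

from __future__ import annotations

import numpy as np

__all__ = ["interval_phi2", "interval_phi3", "optimize_partitions"]


def _g(m: np.ndarray, n: float) -> np.ndarray:
    """Elementwise (m/n) * log2(m/n) with 0 at m = 0."""
    p = np.asarray(m, dtype=float) / n
    out = np.zeros_like(p)
    np.log2(p, out=out, where=p > 0)
    out *= p
    return out


def _interval_diffs(prefix: np.ndarray) -> np.ndarray:
    """All interval sums from a prefix array of shape (U+1, d) -> (U+1, U+1, d)."""
    return prefix[None, :, :] - prefix[:, None, :]


def interval_phi2(counts: np.ndarray, n: int) -> np.ndarray:
    """phi2 for every superclump interval (s, t]; shape (U+1, U+1), s < t valid."""
    prefix = np.concatenate(
        (np.zeros((1, counts.shape[1])), np.cumsum(counts, axis=0)), axis=0
    )
    cell = _interval_diffs(prefix)
    tot = cell.sum(axis=2)
    return _g(cell, n).sum(axis=2) - _g(tot, n)


def interval_phi3(counts: np.ndarray, n: int, n_x1_bins: int, n_classes: int) -> np.ndarray:
    """phi3 for every superclump interval (s, t]; shape (U+1, U+1).

    ``counts`` is (U, n_x1_bins * n_classes) with joint state x1_bin * P + class.
    """
    U = counts.shape[0]
    c3 = counts.reshape(U, n_x1_bins, n_classes)
    # build each margin's own prefix so the interval diff happens at the
    # smallest possible dimensionality
    pref_cell = np.concatenate(
        (np.zeros((1, n_x1_bins * n_classes)), np.cumsum(counts, axis=0)), axis=0
    )
    pref_x1 = np.concatenate(
        (np.zeros((1, n_x1_bins)), np.cumsum(c3.sum(axis=2), axis=0)), axis=0
    )
    pref_y = np.concatenate(
        (np.zeros((1, n_classes)), np.cumsum(c3.sum(axis=1), axis=0)), axis=0
    )
    pref_tot = pref_x1.sum(axis=1)
    return (
        _g(_interval_diffs(pref_cell), n).sum(axis=2)
        - _g(_interval_diffs(pref_x1), n).sum(axis=2)
        - _g(_interval_diffs(pref_y), n).sum(axis=2)
        + _g(pref_tot[None, :] - pref_tot[:, None], n)
    )


def optimize_partitions(phi: np.ndarray, max_parts: int, *, minimize: bool = False) -> np.ndarray:
    """Exact optimum of the column-score sum over partitions into l parts.

    ``phi[s, t]`` is the score of the column covering superclumps ``s..t-1``.
    Returns an array ``opt`` indexed ``l = 2..max_parts`` (``opt[l-2]``) with
    the optimal total over partitions of all U superclumps into exactly ``l``
    nonempty columns; ``NaN`` where ``l`` exceeds the number of superclumps.
    """
    U = phi.shape[0] - 1
    sign = -1.0 if minimize else 1.0
    work = sign * phi
    bad = ~np.tri(U + 1, U + 1, -1, dtype=bool).T  # s >= t
    work = np.where(bad, -np.inf, work)
    out = np.full(max(max_parts - 1, 0), np.nan)
    if max_parts < 2:
        return out
    best_prev = work[0].copy()  # F(1, t)
    for l in range(2, max_parts + 1):
        best = (best_prev[:, None] + work).max(axis=0)
        if np.isfinite(best[U]):
            out[l - 2] = sign * best[U]
        best_prev = best
        if l > U:
            break
    return out
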