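"""Independent reference implementations used only to check the package.

Everything here is deliberately naive: direct loop transcriptions,
exhaustive enumeration over cut subsets, and entropy sums via scipy.  None
of it shares the dynamic-programming or vectorized code paths under test.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np
from scipy.stats import entropy as _scipy_entropy


def entropy2(counts) -> float:
    """Shannon entropy (bits) via scipy on flattened nonnegative counts."""
    c = np.asarray(counts, dtype=float).ravel()
    return float(_scipy_entropy(c / c.sum(), base=2))


def interaction_from_entropies(t: np.ndarray) -> float:
    """I(X1;X2;Y) as an entropy sum, computed entirely through scipy."""
    t = np.asarray(t, dtype=float)
    return (
        -entropy2(t)
        + entropy2(t.sum(axis=2))
        + entropy2(t.sum(axis=1))
        + entropy2(t.sum(axis=0))
        - entropy2(t.sum(axis=(1, 2)))
        - entropy2(t.sum(axis=(0, 2)))
        - entropy2(t.sum(axis=(0, 1)))
    )


def greedy_partition_reference(masses, k):
    """Loop transcription of the balanced greedy sweep over mass blocks."""
    masses = list(masses)
    nb = len(masses)
    pm = [0]
    for m in masses:
        pm.append(pm[-1] + m)
    total = pm[-1]
    edges = [0]
    start, used = 0, 0
    while start < nb and used < k - 1:
        d = (total - pm[start]) / (k - used)
        m, j = 0, start
        while j < nb:
            s = masses[j]
            if m > 0 and abs(m + s - d) >= abs(m - d):
                break
            m += s
            j += 1
        if j >= nb:
            break
        edges.append(j)
        start, used = j, used + 1
    edges.append(nb)
    return edges


def tensor_from_partition(unit_counts, cuts, n_x1_bins, n_classes):
    """3-D contingency tensor for a column partition of superclump units.

    ``cuts`` are interior unit-index boundaries; columns are the resulting
    intervals.
    """
    unit_counts = np.asarray(unit_counts)
    edges = [0, *cuts, unit_counts.shape[0]]
    cols = [
        unit_counts[edges[i]:edges[i + 1]].sum(axis=0)
        for i in range(len(edges) - 1)
    ]
    # states are x1_bin * P + class; tensor axes (x1, column, class)
    t = np.stack(cols, axis=0).reshape(len(cols), n_x1_bins, n_classes)
    return np.transpose(t, (1, 0, 2))


def best_partition_exhaustive(unit_counts, l, n_x1_bins, n_classes, minimize=False):
    """Exact optimum interaction over all partitions into exactly l columns.

    Enumerates every subset of l - 1 interior boundaries; the objective is
    computed through the entropy-sum route, independent of the DP.
    Returns NaN when too few boundaries exist.
    """
    U = np.asarray(unit_counts).shape[0]
    if U < l:
        return float("nan")
    best = None
    for cuts in combinations(range(1, U), l - 1):
        t = tensor_from_partition(unit_counts, cuts, n_x1_bins, n_classes)
        val = interaction_from_entropies(t)
        if best is None or (val < best if minimize else val > best):
            best = val
    return best


def venn_counts_reference(lists):
    """Set-algebra Venn cells for a list of id lists."""
    sets = [set(l) for l in lists]
    out = {}
    for g in set().union(*sets):
        key = tuple(int(g in s) for s in sets)
        out[key] = out.get(key, 0) + 1
    return out
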