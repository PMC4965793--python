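"""Axis partitioning primitives: greedy equipartition, runs and superclumps.

The grid search never places a cut between tied values: a block of points
sharing the same coordinate is atomic.  Both the fixed-axis equipartition and
the merging of an over-long run sequence into at most ``cap`` superclumps use
the same greedy sweep, which closes the current bin just before the block
whose inclusion would overshoot the running target size by at least as much
as stopping short would undershoot it, re-targeting the remaining mass after
every cut.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

__all__ = [
    "greedy_block_partition",
    "equipartition_axis",
    "tie_blocks",
    "SuperclumpSequence",
    "get_superclumps_partition_3d",
]


def greedy_block_partition(block_masses: np.ndarray, k: int) -> np.ndarray:
    """Partition an ordered sequence of atomic mass blocks into at most ``k`` groups.

    Returns edge indices ``e`` with ``e[0] == 0`` and ``e[-1] == B`` (number of
    blocks); group ``i`` is ``blocks[e[i]:e[i+1]]``.  Group sizes track
    ``remaining mass / remaining groups`` as closely as the atomic blocks allow.
    Fewer than ``k`` groups are returned when a large block swallows the
    target of several.
    """
    masses = np.asarray(block_masses)
    nblocks = masses.size
    if k < 1:
        raise ValueError("k must be >= 1")
    if nblocks == 0:
        return np.array([0], dtype=np.intp)
    if np.all(masses == 1):
        # unit masses: the sweep reduces to integer apportionment, bin size
        # ceil(remaining/bins_left - 1/2), computed in exact integer arithmetic
        edges = [0]
        e = 0
        for used in range(k - 1):
            a, b = nblocks - e, k - used
            size = (2 * a + b - 1) // (2 * b)
            e += max(size, 1)
            if e >= nblocks:
                break
            edges.append(e)
        edges.append(nblocks)
        return np.asarray(edges, dtype=np.intp)
    masses = masses.astype(float)
    pm = np.concatenate(([0.0], np.cumsum(masses)))
    total = pm[-1]
    # s[j] = pm[j] + pm[j+1]; strictly increasing for positive masses, so the
    # first block before which to cut can be found by bisection.
    s = pm[:-1] + pm[1:]
    edges = [0]
    start = 0
    used = 0
    while start < nblocks and used < k - 1:
        target = (total - pm[start]) / (k - used)
        j = int(np.searchsorted(s, 2.0 * (pm[start] + target), side="left"))
        j = max(j, start + 1)
        if j >= nblocks:
            break
        edges.append(j)
        start = j
        used += 1
    edges.append(nblocks)
    return np.asarray(edges, dtype=np.intp)


def tie_blocks(sorted_values: np.ndarray) -> np.ndarray:
    """Start indices of tie blocks in an ascending-sorted array (plus end sentinel)."""
    v = np.asarray(sorted_values)
    if v.size == 0:
        return np.array([0], dtype=np.intp)
    starts = np.flatnonzero(np.concatenate(([True], v[1:] != v[:-1])))
    return np.concatenate((starts, [v.size])).astype(np.intp)


def equipartition_axis(values: np.ndarray, k: int, *, order: np.ndarray | None = None) -> np.ndarray:
    """Assign each point an axis bin so occupancies are as equal as ties allow.

    ``k`` is the target bin count; tied values never straddle a boundary, so
    fewer bins may result (a warning is issued if everything collapses to one
    bin while ``k > 1``).  Returns an integer bin label per point, in the
    original order of ``values``.  ``order`` may supply a precomputed stable
    argsort of ``values``.
    """
    v = np.asarray(values)
    n = v.size
    if k < 1:
        raise ValueError("k must be >= 1")
    if n < k:
        raise ValueError(f"cannot split {n} points into {k} bins")
    if order is None:
        order = np.argsort(v, kind="stable")
    sv = v[order]
    blocks = tie_blocks(sv)
    block_sizes = np.diff(blocks)
    edges = greedy_block_partition(block_sizes, k)
    nbins = len(edges) - 1
    if nbins == 1 and k > 1:
        warnings.warn(
            "axis values admit only a single bin (all-tied values); "
            "partition collapsed to 1 bin",
            stacklevel=2,
        )
    # blocks[edges] are point-index boundaries in sorted order
    point_edges = blocks[edges]
    bin_sorted = np.repeat(np.arange(nbins), np.diff(point_edges))
    labels = np.empty(n, dtype=np.intp)
    labels[order] = bin_sorted
    return labels


@dataclass
class SuperclumpSequence:
    """Ordered candidate-cut units along the free (x2) axis.

    ``starts`` has ``n_units + 1`` entries: unit ``u`` covers positions
    ``starts[u]:starts[u+1]`` of the x2-sorted data.  ``counts`` is the
    per-unit contingency over joint states ``x1_bin * P + class``.
    Interior entries of ``starts`` are the candidate x2-axis cut positions.
    """

    starts: np.ndarray
    counts: np.ndarray  # (n_units, n_states)
    n_states: int

    @property
    def n_units(self) -> int:
        return self.counts.shape[0]

    @property
    def sizes(self) -> np.ndarray:
        return np.diff(self.starts)


def _raw_units(attr: np.ndarray, blocks: np.ndarray) -> np.ndarray:
    """Unit id per x2 tie block: maximal runs of a shared attribute.

    A tie block that mixes attributes is indivisible and forms its own unit.
    """
    nb = len(blocks) - 1
    amin = np.minimum.reduceat(attr, blocks[:-1])
    amax = np.maximum.reduceat(attr, blocks[:-1])
    battr = np.where(amin == amax, amin, -1)
    if nb == 1:
        return np.zeros(1, dtype=np.intp)
    brk = (battr[1:] != battr[:-1]) | (battr[1:] == -1) | (battr[:-1] == -1)
    return np.concatenate(([0], np.cumsum(brk))).astype(np.intp)


def get_superclumps_partition_3d(
    x1_bins: np.ndarray,
    y: np.ndarray,
    n_classes: int,
    cap: int,
    *,
    x2_tie_blocks: np.ndarray,
    n_x1_bins: int,
    class_only: bool = False,
) -> SuperclumpSequence:
    """Build the superclump sequence for data already sorted by x2.

    Points are grouped into maximal runs (in x2 rank order) sharing the same
    class and — unless ``class_only`` — the same x1 bin; tied x2 values are
    never split, and a tie block spanning several classes forms a unit of its
    own.  If more than ``cap`` runs result, adjacent runs are merged by a
    greedy equipartition of run masses into at most ``cap`` superclumps.

    ``x1_bins`` and ``y`` are per-point arrays in x2-sorted order;
    ``x2_tie_blocks`` is the output of :func:`tie_blocks` on the sorted x2
    values.
    """
    if cap < 2:
        raise ValueError("cap must be >= 2")
    n = y.size
    state = x1_bins * n_classes + y
    run_attr = y if class_only else state
    unit_of_block = _raw_units(run_attr, x2_tie_blocks)
    n_units = int(unit_of_block[-1]) + 1
    # per-unit boundaries in point positions
    first_block_of_unit = np.flatnonzero(
        np.concatenate(([True], unit_of_block[1:] != unit_of_block[:-1]))
    )
    starts = np.concatenate((x2_tie_blocks[first_block_of_unit], [n]))
    if n_units > cap:
        # merge before tabulating so the count matrix is built once, at the
        # merged resolution
        edges = greedy_block_partition(np.diff(starts), cap)
        starts = starts[edges]
        n_units = len(starts) - 1
    n_states = n_x1_bins * n_classes
    unit_of_point = np.repeat(np.arange(n_units), np.diff(starts))
    counts = np.bincount(
        unit_of_point * n_states + state, minlength=n_units * n_states
    ).reshape(n_units, n_states)
    return SuperclumpSequence(starts=starts, counts=counts, n_states=n_states)
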