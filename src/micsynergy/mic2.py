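"""Two-variable maximal information coefficient MIC(X; Y).

The estimator follows the equipartition / clumps / dynamic-programming
approximation of Reshef et al.: for every grid shape (x, y) inside the
budget ``x * y <= n ** a``, one axis is equipartitioned and the other is
optimized exactly over clump boundaries; the characteristic-matrix entry is
the mutual information normalized by ``log2(min(x, y))`` and the score is
the matrix maximum.  Both orientations are evaluated.  When y is a class
label with P levels the y-axis partition is capped at P bins.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np

from ._dp import interval_phi2, optimize_partitions
from ._partition import equipartition_axis, get_superclumps_partition_3d, tie_blocks
from .info import entropy_bits

__all__ = ["Mic2Result", "mic2"]

MIN_SAMPLES = 10


@dataclass
class Mic2Result:
    score: float
    best_grid: tuple[int, int]
    raw_mi: float


def _entries_2d(
    fixed: np.ndarray,
    free: np.ndarray,
    n: int,
    B: float,
    c: float,
    fixed_cap: int | None,
) -> dict[tuple[int, int], tuple[float, float]]:
    """Entries {(fixed_bins, free_bins): (normalized value, raw MI bits)}.

    The fixed axis is equipartitioned into q bins; the free axis is optimized
    over clump boundaries (runs homogeneous in fixed-axis bin, ties atomic)
    into l = 2..floor(B / q) bins with the clump count capped at c * l_max.
    """
    order_free = np.argsort(free, kind="stable")
    blocks = tie_blocks(free[order_free])
    order_fix = np.argsort(fixed, kind="stable")
    entries: dict[tuple[int, int], tuple[float, float]] = {}
    q_hi = int(B / 2)
    if fixed_cap is not None:
        q_hi = min(q_hi, fixed_cap)
    seen_nq: set[int] = set()
    for q in range(2, q_hi + 1):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            qlab = equipartition_axis(fixed, q, order=order_fix)
        nq = int(qlab.max()) + 1
        if nq < 2 or nq in seen_nq:
            if nq < 2:
                break
            continue
        seen_nq.add(nq)
        l_max = int(B / nq)
        if l_max < 2:
            continue
        qlab2 = qlab[order_free]
        # reuse the run/merge machinery: the fixed-axis bin plays the class role
        sc = get_superclumps_partition_3d(
            np.zeros(n, dtype=np.intp), qlab2, nq, cap=max(2, c * l_max),
            x2_tie_blocks=blocks, n_x1_bins=1,
        )
        phi = interval_phi2(sc.counts, n)
        hq = entropy_bits(np.bincount(qlab, minlength=nq))
        raw = hq + optimize_partitions(phi, l_max)
        raw = np.fmax.accumulate(raw)
        for i, l in enumerate(range(2, l_max + 1)):
            if np.isnan(raw[i]):
                continue
            value = float(min(raw[i] / math.log2(min(l, nq)), 1.0))
            key = (nq, l)
            if key not in entries or value > entries[key][0]:
                entries[key] = (value, float(raw[i]))
    return entries


def mic2(
    x: np.ndarray,
    y: np.ndarray,
    a: float = 0.6,
    c: float = 5,
    discrete_y: bool | str = "auto",
) -> Mic2Result:
    """MIC(X; Y) with exponent ``a`` (grid budget n**a) and clump factor ``c``.

    ``discrete_y='auto'`` treats y as a class label when it has at most 10
    distinct values; a discrete y caps the y-axis at its number of levels.
    A constant x or y is degenerate: the score is 0 and a warning is issued.
    """
    x = np.asarray(x, dtype=float)
    yv = np.asarray(y, dtype=float)
    if x.shape != yv.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D arrays of equal length")
    n = x.size
    if n < MIN_SAMPLES:
        raise ValueError(f"need at least {MIN_SAMPLES} samples, got {n}")
    n_x = np.unique(x).size
    n_y = np.unique(yv).size
    if n_x < 2 or n_y < 2:
        warnings.warn("constant variable: MIC(X;Y) set to 0")
        return Mic2Result(0.0, (1, 1), 0.0)
    if discrete_y == "auto":
        discrete_y = n_y <= 10
    B = n**a
    y_cap = n_y if discrete_y else None
    entries: dict[tuple[int, int], tuple[float, float]] = {}
    # orientation 1: equipartition the y axis, optimize x-axis cuts
    for (q, l), vr in _entries_2d(yv, x, n, B, c, y_cap).items():
        key = (l, q)
        if key not in entries or vr[0] > entries[key][0]:
            entries[key] = vr
    # orientation 2: equipartition the x axis, optimize y-axis cuts
    for (q, l), vr in _entries_2d(x, yv, n, B, c, None).items():
        key = (q, l)
        if key not in entries or vr[0] > entries[key][0]:
            entries[key] = vr
    if not entries:
        warnings.warn(f"no admissible grid for n={n} with a={a}; MIC(X;Y) set to 0")
        return Mic2Result(0.0, (1, 1), 0.0)

    def sort_key(item):
        (xb, yb), (value, _) = item
        return (-value, xb * yb, xb, yb)

    (xb, yb), (value, raw) = min(entries.items(), key=sort_key)
    return Mic2Result(float(value), (xb, yb), float(raw))
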