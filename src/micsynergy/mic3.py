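"""Signed three-variable maximal information coefficient MIC(X1; X2; Y).

Y is discrete with P classes, so the class axis of every grid is fixed at P
bins.  With the x1 axis frozen at an equipartition into ``x1`` bins, the grid
budget for the free 2-D subproblem is ``x2 * y <= (n / x1) ** a`` and the
normalization benchmark is ``log2(min(x2, y))``.  The fixed axis itself
sweeps 2..n**a / 2 (the total-grid budget on the two continuous axes);
sweeping it further is statistically harmful — with more than ~n**a fixed
bins the plug-in interaction acquires an O(x1 / n) bias that inflates the
score of independent data.  For every admissible fixed
size the free (x2) axis is optimized exactly — over candidate cuts on
superclump boundaries — by dynamic programming, in both directions: the
maximum captures synergy, the minimum redundancy.  Each characteristic-matrix
entry keeps the signed normalized value of larger magnitude, and the
reported score is the entry of maximal absolute value with its sign retained
(+1 for pure synergy such as an exclusive-or label, -1 for full redundancy).
Both orientations (x1 fixed / x2 fixed) are swept, so the score is symmetric
in the two continuous variables.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

from ._dp import interval_phi3, optimize_partitions
from ._partition import (
    SuperclumpSequence,
    equipartition_axis,
    get_superclumps_partition_3d,
    tie_blocks,
)
from .info import entropy_bits

__all__ = [
    "TripletDataset",
    "CharacteristicMatrix3D",
    "InteractionResult",
    "optimize_x2_axis",
    "characteristic_matrix_3d",
    "mic3",
    "joint_effect",
]

MIN_SAMPLES = 10


@dataclass
class TripletDataset:
    """n samples of two continuous variables and a discrete class label."""

    x1: np.ndarray
    x2: np.ndarray
    y: np.ndarray

    def __post_init__(self) -> None:
        self.x1 = np.asarray(self.x1, dtype=float)
        self.x2 = np.asarray(self.x2, dtype=float)
        self.y = np.asarray(self.y)
        if not (self.x1.shape == self.x2.shape == self.y.shape) or self.x1.ndim != 1:
            raise ValueError("x1, x2, y must be 1-D arrays of equal length")
        classes, coded = np.unique(self.y, return_inverse=True)
        if classes.size < 2:
            raise ValueError("y must contain at least two classes")
        self.y = coded.astype(np.intp)
        self.classes_ = classes

    @property
    def n(self) -> int:
        return self.x1.size

    @property
    def n_classes(self) -> int:
        return int(self.y.max()) + 1

    def swapped(self) -> "TripletDataset":
        return TripletDataset(self.x2.copy(), self.x1.copy(), self.y.copy())


@dataclass
class CharacteristicMatrix3D:
    """Normalized interaction values indexed by orientation and grid size.

    ``entries[(orientation, fixed_bins, free_bins)]`` is the signed normalized
    value; ``raw[(...)]`` the corresponding interaction in bits.  Orientation
    is ``"x1-fixed"`` or ``"x2-fixed"`` (roles of the two continuous columns
    exchanged).
    """

    a: float
    c: float
    n: int
    n_classes: int
    entries: dict = field(default_factory=dict)
    raw: dict = field(default_factory=dict)


@dataclass
class InteractionResult:
    mic3: float
    best_grid: tuple[int, int, int]
    orientation: str
    raw_interaction: float


def _interaction_constant(fix_labels: np.ndarray, y: np.ndarray, nb: int, P: int, n: int) -> float:
    """K = H(X1,Y) - H(X1) - H(Y), the column-independent part of the interaction."""
    joint = np.bincount(fix_labels * P + y, minlength=nb * P).reshape(nb, P)
    return entropy_bits(joint) - entropy_bits(joint.sum(axis=1)) - entropy_bits(joint.sum(axis=0))


def optimize_x2_axis(
    d: TripletDataset,
    x1_partition: np.ndarray,
    clumps: SuperclumpSequence,
    max_x2_bins: int,
    objective: str = "maximize",
) -> np.ndarray:
    """Optimal raw interaction (bits) for each free-axis bin count.

    ``d`` must be sorted by x2 with ``x1_partition`` the per-point x1-bin
    labels in the same order and ``clumps`` the matching superclump sequence.
    Returns an array indexed ``l = 2..max_x2_bins`` (element ``l - 2``); an
    entry is NaN when fewer boundaries than ``l - 1`` are available.
    """
    if max_x2_bins < 2:
        raise ValueError("max_x2_bins must be >= 2")
    if objective not in ("maximize", "minimize"):
        raise ValueError("objective must be 'maximize' or 'minimize'")
    nb = int(x1_partition.max()) + 1
    P = d.n_classes
    phi = interval_phi3(clumps.counts, d.n, nb, P)
    opt = optimize_partitions(phi, max_x2_bins, minimize=objective == "minimize")
    K = _interaction_constant(x1_partition, d.y, nb, P, d.n)
    return K + opt


def _orientation_entries(
    fix_vals: np.ndarray,
    free_vals: np.ndarray,
    y: np.ndarray,
    P: int,
    a: float,
    c: float,
    class_only: bool = False,
    max_fixed_bins: int | None = None,
) -> dict[tuple[int, int], tuple[float, float]]:
    """Sweep fixed-axis sizes; return {(fixed_bins, free_bins): (value, raw)}."""
    n = y.size
    if max_fixed_bins is None:
        # grid-size budget on the two continuous axes: x1 * x2 <= n**a, so
        # with at least 2 free bins the fixed axis sweeps 2..n**a / 2 (the
        # direct analogue of the two-variable row sweep)
        max_fixed_bins = max(2, int(n**a / 2))
    order_free = np.argsort(free_vals, kind="stable")
    ys = y[order_free]
    blocks = tie_blocks(free_vals[order_free])
    order_fix = np.argsort(fix_vals, kind="stable")
    entries: dict[tuple[int, int], tuple[float, float]] = {}
    kfix = 2
    while True:
        if kfix > max_fixed_bins:
            break
        max_free = int((n / kfix) ** a / P)
        if max_free < 2:
            break
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            labels = equipartition_axis(fix_vals, kfix, order=order_fix)
        nb = int(labels.max()) + 1
        if nb < 2:
            break  # fixed axis has collapsed; larger targets cannot help
        max_free = int((n / nb) ** a / P)
        if max_free < 2:
            kfix += 1
            continue
        lab2 = labels[order_free]
        sc = get_superclumps_partition_3d(
            lab2, ys, P, cap=max(2, c * max_free),
            x2_tie_blocks=blocks, n_x1_bins=nb, class_only=class_only,
        )
        phi = interval_phi3(sc.counts, n, nb, P)
        K = _interaction_constant(lab2, ys, nb, P, n)
        raw_max = K + optimize_partitions(phi, max_free)
        raw_min = K + optimize_partitions(phi, max_free, minimize=True)
        # a partition into fewer nonempty columns is realizable at any larger
        # size via empty columns, so take the running envelope over l
        raw_max = np.fmax.accumulate(raw_max)
        raw_min = np.fmin.accumulate(raw_min)
        for i, l in enumerate(range(2, max_free + 1)):
            norm = math.log2(min(l, P))
            cands = []
            if not np.isnan(raw_max[i]):
                cands.append((raw_max[i] / norm, raw_max[i]))
            if not np.isnan(raw_min[i]):
                cands.append((raw_min[i] / norm, raw_min[i]))
            if not cands:
                continue
            value, raw = max(cands, key=lambda vr: (abs(vr[0]), vr[0]))
            value = float(np.clip(value, -1.0, 1.0))
            key = (nb, l)
            if key not in entries or abs(value) > abs(entries[key][0]):
                entries[key] = (value, float(raw))
        kfix += 1
    return entries


def characteristic_matrix_3d(
    d: TripletDataset | None = None,
    a: float = 0.6,
    c: float = 5,
    *,
    x1: np.ndarray | None = None,
    x2: np.ndarray | None = None,
    y: np.ndarray | None = None,
    class_only_superclumps: bool = False,
    max_fixed_bins: int | None = None,
) -> CharacteristicMatrix3D:
    """Characteristic matrix of signed normalized interaction values.

    Raises if no grid is admissible under the ``(n / x1) ** a`` budget.
    """
    if d is None:
        d = TripletDataset(x1, x2, y)
    P = d.n_classes
    mat = CharacteristicMatrix3D(a=a, c=c, n=d.n, n_classes=P)
    for orientation, fix_vals, free_vals in (
        ("x1-fixed", d.x1, d.x2),
        ("x2-fixed", d.x2, d.x1),
    ):
        sub = _orientation_entries(
            fix_vals, free_vals, d.y, P, a, c,
            class_only=class_only_superclumps, max_fixed_bins=max_fixed_bins,
        )
        for (nb, l), (value, raw) in sub.items():
            mat.entries[(orientation, nb, l)] = value
            mat.raw[(orientation, nb, l)] = raw
    if not mat.entries:
        raise ValueError(
            f"no admissible grid for n={d.n} with a={a}: sample too small"
        )
    return mat


def mic3(
    x1: np.ndarray,
    x2: np.ndarray,
    y: np.ndarray,
    a: float = 0.6,
    c: float = 5,
    *,
    class_only_superclumps: bool = False,
    max_fixed_bins: int | None = None,
) -> InteractionResult:
    """Signed MIC(X1; X2; Y): extremal normalized interaction over grids.

    Returns the characteristic-matrix entry of maximal absolute value with
    its sign retained, along with the achieving grid and orientation.  Ties
    in magnitude prefer the smaller total grid, then the x1-fixed
    orientation.
    """
    x1 = np.asarray(x1, dtype=float)
    x2 = np.asarray(x2, dtype=float)
    if x1.size < MIN_SAMPLES:
        raise ValueError(f"need at least {MIN_SAMPLES} samples, got {x1.size}")
    if np.all(x1 == x1[0]) or np.all(x2 == x2[0]):
        warnings.warn("constant continuous variable: MIC(X1;X2;Y) set to 0")
        P = int(np.unique(np.asarray(y)).size)
        return InteractionResult(0.0, (1, 1, P), "x1-fixed", 0.0)
    d = TripletDataset(x1, x2, y)
    mat = characteristic_matrix_3d(
        d, a, c,
        class_only_superclumps=class_only_superclumps,
        max_fixed_bins=max_fixed_bins,
    )

    def sort_key(item):
        (orientation, nb, l), value = item
        return (-abs(value), nb * l, orientation != "x1-fixed", nb, l)

    (orientation, nb, l), value = min(mat.entries.items(), key=sort_key)
    raw = mat.raw[(orientation, nb, l)]
    grid = (nb, l, d.n_classes) if orientation == "x1-fixed" else (l, nb, d.n_classes)
    return InteractionResult(float(value), grid, orientation, float(raw))


def joint_effect(x1, x2, y, a: float = 0.6, c: float = 5) -> float:
    """MIC(X1;X2;Y) + MIC(X1;Y) + MIC(X2;Y); close to 1 when Y is a noiseless
    function of (X1, X2)."""
    from .mic2 import mic2

    return (
        mic3(x1, x2, y, a, c).mic3
        + mic2(x1, y, a, c).score
        + mic2(x2, y, a, c).score
    )
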