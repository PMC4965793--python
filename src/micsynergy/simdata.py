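"""Seeded generators for the simulation constructions used throughout.

Every generator is a pure function of its parameters and seed (NumPy
``default_rng``), drawing the continuous variables uniformly on the stated
domains and binarizing continuous responses at the sample median (strictly
greater than the median -> class 1, ties and the median itself -> class 0),
which keeps the two classes balanced to within one sample.

Scenarios:

* ``xor_synergy`` — X1, X2 ~ U(10, 30); Y is the exclusive-or of their
  median binarizations (pure pair-wise synergy, MIC(X1;X2;Y) = 1).
* ``full_redundancy`` — X2 = X1 ~ U(0, 1); Y thresholds X1 at its median
  (full redundancy, MIC(X1;X2;Y) = -1).
* ``independent2`` / ``independent3`` — mutually independent variables,
  the null for calibrating MIC(X;Y) and MIC(X1;X2;Y).
* ``table2_fn`` A..J — ten noiseless two-argument functions with
  median-binarized response, the generality benchmark.
* ``abs_diff`` — Y = |X1 - X2| on the unit square (identical to function C),
  kept as a named scenario with default n = 200.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .mic3 import TripletDataset

__all__ = [
    "SimScenario",
    "TABLE2_FUNCTIONS",
    "median_binarize",
    "gen_xor_synergy",
    "gen_full_redundancy",
    "gen_independent",
    "gen_table2_function",
    "gen_abs_diff",
    "generate",
]

MIN_N = 10


def _check_n(n: int) -> None:
    if n < MIN_N:
        raise ValueError(f"n must be >= {MIN_N}, got {n}")


def median_binarize(values: np.ndarray) -> np.ndarray:
    """1 where the value strictly exceeds the sample median, else 0."""
    v = np.asarray(values, dtype=float)
    return (v > np.median(v)).astype(np.intp)


def gen_xor_synergy(n: int, seed: int) -> TripletDataset:
    """X1, X2 ~ U(10, 30); Y = XOR of the two median binarizations."""
    _check_n(n)
    rng = np.random.default_rng(seed)
    x1 = rng.uniform(10.0, 30.0, n)
    x2 = rng.uniform(10.0, 30.0, n)
    y = median_binarize(x1) ^ median_binarize(x2)
    return TripletDataset(x1, x2, y)


def gen_full_redundancy(n: int, seed: int) -> TripletDataset:
    """X2 identical to X1 ~ U(0, 1); Y indicates X1 above its median."""
    _check_n(n)
    rng = np.random.default_rng(seed)
    x1 = rng.uniform(0.0, 1.0, n)
    return TripletDataset(x1, x1.copy(), median_binarize(x1))


def gen_independent(n: int, three_vars: bool = True, seed: int = 0):
    """Mutually independent uniforms; the label binarizes its own draw.

    With ``three_vars`` returns a :class:`TripletDataset` (X1, X2, Y all
    independent); otherwise returns ``(x, y)`` for the two-variable null.
    """
    _check_n(n)
    rng = np.random.default_rng(seed)
    if three_vars:
        x1 = rng.uniform(0.0, 1.0, n)
        x2 = rng.uniform(0.0, 1.0, n)
        y = median_binarize(rng.uniform(0.0, 1.0, n))
        return TripletDataset(x1, x2, y)
    x = rng.uniform(0.0, 1.0, n)
    y = median_binarize(rng.uniform(0.0, 1.0, n))
    return x, y


# id -> (domain of X1, domain of X2, f(X1, X2))
TABLE2_FUNCTIONS = {
    "A": ((0.0, 1.0), (0.0, 1.0), lambda x1, x2: x1 + x2),
    "B": ((0.0, 1.0), (0.0, 1.0), lambda x1, x2: x1 - x2),
    "C": ((0.0, 1.0), (0.0, 1.0), lambda x1, x2: np.abs(x1 - x2)),
    "D": ((0.0, 1.0), (0.0, 1.0), lambda x1, x2: x1 * x2),
    "E": ((0.0, 1.0), (0.0, 1.0), lambda x1, x2: x1 / x2),
    "F": ((5.0, 23.3), (5.0, 23.3), lambda x1, x2: 10.0**x1 + 10.0**x2),
    "G": ((0.0, 1.0), (0.0, 1.0), lambda x1, x2: np.abs(1000.0**x1 - 1000.0**x2)),
    "H": (
        (0.0, 1.0),
        (0.0, 1.0),
        lambda x1, x2: np.abs(np.abs(x1 - 0.5) - np.abs(x2 - 0.5)),
    ),
    "I": (
        (0.0, 3.13),
        (1.5, 4.75),
        lambda x1, x2: np.log2(np.abs(np.sin(x1) - np.cos(x2))),
    ),
    "J": ((0.0, 3.0), (0.0, 3.0), lambda x1, x2: np.sin(x1) - np.sin(x2)),
}

# for E and I, arguments where f is undefined are rejected and redrawn
_DEGENERATE = {
    "E": lambda x1, x2: x2 == 0.0,
    "I": lambda x1, x2: np.sin(x1) == np.cos(x2),
}


def gen_table2_function(fn_id: str, n: int, seed: int) -> TripletDataset:
    """One of the ten noiseless functions; Y = 1 iff f exceeds its median."""
    _check_n(n)
    if fn_id not in TABLE2_FUNCTIONS:
        raise ValueError(f"unknown function id {fn_id!r}; expected one of A..J")
    (lo1, hi1), (lo2, hi2), f = TABLE2_FUNCTIONS[fn_id]
    rng = np.random.default_rng(seed)
    x1 = rng.uniform(lo1, hi1, n)
    x2 = rng.uniform(lo2, hi2, n)
    bad_fn = _DEGENERATE.get(fn_id)
    if bad_fn is not None:
        bad = bad_fn(x1, x2)
        while np.any(bad):
            idx = np.flatnonzero(bad)
            x1[idx] = rng.uniform(lo1, hi1, idx.size)
            x2[idx] = rng.uniform(lo2, hi2, idx.size)
            bad = np.zeros(n, dtype=bool)
            bad[idx] = bad_fn(x1[idx], x2[idx])
    return TripletDataset(x1, x2, median_binarize(f(x1, x2)))


def gen_abs_diff(n: int = 200, seed: int = 0) -> TripletDataset:
    """Y = |X1 - X2| on the unit square, median-binarized (function C)."""
    return gen_table2_function("C", n, seed)


@dataclass
class SimScenario:
    """A named simulation scenario; ``generate`` dispatches on it."""

    name: str
    n: int
    seed: int
    fn_id: str | None = None
    params: dict = field(default_factory=dict)

    NAMES = (
        "xor_synergy",
        "full_redundancy",
        "independent2",
        "independent3",
        "abs_diff",
        "table2_fn",
    )

    def __post_init__(self) -> None:
        if self.name not in self.NAMES:
            raise ValueError(f"unknown scenario {self.name!r}")
        if self.name == "table2_fn" and self.fn_id not in TABLE2_FUNCTIONS:
            raise ValueError("table2_fn requires fn_id in A..J")
        _check_n(self.n)


def generate(scenario: SimScenario):
    """Generate the dataset for a scenario (pure in scenario fields)."""
    s = scenario
    if s.name == "xor_synergy":
        return gen_xor_synergy(s.n, s.seed)
    if s.name == "full_redundancy":
        return gen_full_redundancy(s.n, s.seed)
    if s.name == "independent2":
        return gen_independent(s.n, three_vars=False, seed=s.seed)
    if s.name == "independent3":
        return gen_independent(s.n, three_vars=True, seed=s.seed)
    if s.name == "abs_diff":
        return gen_abs_diff(s.n, s.seed)
    return gen_table2_function(s.fn_id, s.n, s.seed)
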