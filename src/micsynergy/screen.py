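"""Gene-pair synergy screening over an expression matrix.

Scores every unordered gene pair with the signed three-variable MIC against
the sample class labels, ranks pairs, collapses a ranked pair list into a
deduplicated top-gene shortlist, and counts Venn-style overlaps between
shortlists.  Matrices follow the microarray convention of genes in rows.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from itertools import combinations
from pathlib import Path

import numpy as np
import pandas as pd

from .mic2 import mic2
from .mic3 import mic3

__all__ = [
    "ExpressionDataset",
    "PairScore",
    "read_expression",
    "rank_pairs",
    "rank_genes",
    "top_genes_from_pairs",
    "list_overlap",
    "write_pairs",
    "read_pairs",
]

logger = logging.getLogger(__name__)

_LABEL_ROW_NAMES = {"label", "labels", "class", "classes", "y"}


@dataclass
class ExpressionDataset:
    matrix: np.ndarray  # genes x samples
    gene_ids: list[str]
    labels: np.ndarray  # class per sample, coded 0..P-1

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        self.labels = np.asarray(self.labels)
        if self.matrix.ndim != 2:
            raise ValueError("matrix must be 2-D (genes x samples)")
        if self.matrix.shape[0] != len(self.gene_ids):
            raise ValueError("row count must equal number of gene ids")
        if self.matrix.shape[1] != self.labels.size:
            raise ValueError(
                f"label count ({self.labels.size}) does not match "
                f"sample count ({self.matrix.shape[1]})"
            )
        dup = pd.Index(self.gene_ids).duplicated()
        if dup.any():
            name = self.gene_ids[int(np.flatnonzero(dup)[0])]
            raise ValueError(f"duplicate gene id: {name!r}")
        classes, coded = np.unique(self.labels, return_inverse=True)
        if classes.size < 2:
            raise ValueError("labels must contain at least two classes")
        self.labels = coded.astype(np.intp)
        self.classes_ = classes

    @property
    def n_genes(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_samples(self) -> int:
        return self.matrix.shape[1]

    def gene(self, gene_id: str) -> np.ndarray:
        return self.matrix[self.gene_ids.index(gene_id)]


@dataclass
class PairScore:
    gene_a: str
    gene_b: str
    score: float
    rank: int = 0


def _sep_for(path: Path) -> str:
    return "," if path.suffix.lower() == ".csv" else "\t"


def read_expression(
    path: str | Path,
    labels_path: str | Path | None = None,
    orientation: str = "genes-in-rows",
) -> ExpressionDataset:
    """Read a delimited expression matrix (TSV/CSV by extension).

    Layout: first row sample ids, first column gene ids.  Class labels come
    either from a second row whose id is one of label/labels/class/classes/y,
    or from a sidecar ``labels_path`` (one label per line, or one delimited
    line).  ``orientation='samples-in-rows'`` transposes the matrix first.
    """
    path = Path(path)
    if not path.exists() or path.stat().st_size == 0:
        raise ValueError(f"empty or missing expression file: {path}")
    df = pd.read_csv(path, sep=_sep_for(path), index_col=0)
    if orientation == "samples-in-rows":
        df = df.T
    elif orientation != "genes-in-rows":
        raise ValueError(f"unknown orientation {orientation!r}")
    labels = None
    first = str(df.index[0]).strip().lower() if len(df.index) else ""
    if first in _LABEL_ROW_NAMES:
        labels = df.iloc[0].to_numpy()
        df = df.iloc[1:]
    if labels_path is not None:
        raw = Path(labels_path).read_text().split()
        labels = np.asarray(raw)
    if labels is None:
        raise ValueError(
            "no class labels: provide a label row or a sidecar labels file"
        )
    numeric = df.apply(pd.to_numeric, errors="coerce")
    if numeric.isna().to_numpy().any():
        r, c = np.argwhere(numeric.isna().to_numpy())[0]
        raise ValueError(
            f"non-numeric expression value at gene {df.index[r]!r}, "
            f"sample {df.columns[c]!r}"
        )
    return ExpressionDataset(
        numeric.to_numpy(), [str(g) for g in df.index], labels
    )


def _score_pair(xa, xb, labels, a, c):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return mic3(xa, xb, labels, a, c).mic3


def rank_pairs(
    d: ExpressionDataset,
    top_k_pairs: int,
    candidate_genes: list[str] | None = None,
    rank_by: str = "signed",
    a: float = 0.6,
    c: float = 5,
    workers: int = 1,
) -> list[PairScore]:
    """Score every unordered gene pair with MIC(X1;X2;Y) and rank them.

    Pairs are sorted descending by the signed score (``rank_by='abs'`` sorts
    by magnitude); ties break lexicographically on the id pair.  Within a
    pair, ids are stored in lexicographic order.
    """
    if top_k_pairs < 1:
        raise ValueError("top_k_pairs must be >= 1")
    if rank_by not in ("signed", "abs"):
        raise ValueError("rank_by must be 'signed' or 'abs'")
    ids = d.gene_ids
    if candidate_genes is not None:
        missing = set(candidate_genes) - set(ids)
        if missing:
            raise ValueError(f"unknown candidate genes: {sorted(missing)}")
        ids = [g for g in ids if g in set(candidate_genes)]
    if len(ids) < 2:
        raise ValueError("need at least two genes")
    pairs = [tuple(sorted(p)) for p in combinations(ids, 2)]
    pairs.sort()
    rows = {g: d.matrix[d.gene_ids.index(g)] for g in ids}
    if workers > 1:
        from joblib import Parallel, delayed

        scores = Parallel(n_jobs=workers)(
            delayed(_score_pair)(rows[ga], rows[gb], d.labels, a, c)
            for ga, gb in pairs
        )
    else:
        scores = [
            _score_pair(rows[ga], rows[gb], d.labels, a, c) for ga, gb in pairs
        ]
    keyfun = (lambda s: -abs(s)) if rank_by == "abs" else (lambda s: -s)
    ranked = sorted(zip(pairs, scores), key=lambda ps: (keyfun(ps[1]), ps[0]))
    if top_k_pairs > len(ranked):
        logger.warning(
            "top_k_pairs=%d exceeds the %d available pairs; returning all",
            top_k_pairs, len(ranked),
        )
        top_k_pairs = len(ranked)
    return [
        PairScore(ga, gb, float(s), rank=i + 1)
        for i, ((ga, gb), s) in enumerate(ranked[:top_k_pairs])
    ]


def rank_genes(
    d: ExpressionDataset, a: float = 0.6, c: float = 5
) -> list[tuple[str, float]]:
    """Individual-gene ranking by MIC(X;Y), the reference single-gene filter."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        scored = [
            (g, mic2(d.matrix[i], d.labels, a, c).score)
            for i, g in enumerate(d.gene_ids)
        ]
    return sorted(scored, key=lambda gs: (-gs[1], gs[0]))


def top_genes_from_pairs(pairs: list[PairScore], n_genes: int = 200) -> list[str]:
    """Walk ranked pairs collecting unseen gene ids until ``n_genes`` unique.

    The final pair may contribute two new ids; the list is truncated to
    exactly ``n_genes``.  If the pairs run out first, all collected genes are
    returned with a warning.
    """
    if n_genes < 1:
        raise ValueError("n_genes must be >= 1")
    seen: list[str] = []
    seen_set: set[str] = set()
    for p in pairs:
        for g in (p.gene_a, p.gene_b):
            if g not in seen_set:
                seen.append(g)
                seen_set.add(g)
        if len(seen) >= n_genes:
            return seen[:n_genes]
    logger.warning(
        "pair list exhausted with %d unique genes (< %d requested)",
        len(seen), n_genes,
    )
    return seen


def list_overlap(lists: list[list[str]]) -> dict[tuple[int, ...], int]:
    """Venn-cell counts for 2..4 gene lists.

    Returns a map from membership pattern (tuple of 0/1 per list) to the
    number of ids showing exactly that pattern; the all-zero cell is omitted.
    """
    if not 2 <= len(lists) <= 4:
        raise ValueError("list_overlap supports 2 to 4 lists")
    sets = []
    for i, lst in enumerate(lists):
        s = set(lst)
        if len(s) != len(lst):
            raise ValueError(f"list {i} contains duplicate ids")
        sets.append(s)
    counts: dict[tuple[int, ...], int] = {}
    for g in set().union(*sets):
        pattern = tuple(int(g in s) for s in sets)
        counts[pattern] = counts.get(pattern, 0) + 1
    return counts


def write_pairs(pairs: list[PairScore], path: str | Path) -> None:
    """Write ranked pairs as TSV with columns rank, gene_a, gene_b, mic3."""
    df = pd.DataFrame(
        {
            "rank": [p.rank for p in pairs],
            "gene_a": [p.gene_a for p in pairs],
            "gene_b": [p.gene_b for p in pairs],
            "mic3": [p.score for p in pairs],
        }
    )
    df.to_csv(path, sep="\t", index=False, float_format="%.8g")


def read_pairs(path: str | Path) -> list[PairScore]:
    df = pd.read_csv(path, sep="\t")
    return [
        PairScore(str(r.gene_a), str(r.gene_b), float(r.mic3), int(r.rank))
        for r in df.itertuples()
    ]
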