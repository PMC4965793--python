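"""Expression I/O, pair ranking, top-gene collection, list overlap."""

import numpy as np
import pytest

from micsynergy import (
    ExpressionDataset,
    PairScore,
    list_overlap,
    rank_pairs,
    read_expression,
    read_pairs,
    top_genes_from_pairs,
    write_pairs,
)
from micsynergy.simdata import gen_xor_synergy
from oracles import venn_counts_reference


def planted_matrix(n_noise, n_samples=100, seed=0):
    """Two genes encoding an XOR label plus independent noise genes."""
    d = gen_xor_synergy(n_samples, seed=seed)
    rng = np.random.default_rng(seed + 10_000)
    noise = rng.uniform(0, 1, (n_noise, n_samples))
    matrix = np.vstack([d.x1, d.x2, noise])
    ids = ["SYN1", "SYN2"] + [f"N{i:03d}" for i in range(n_noise)]
    return ExpressionDataset(matrix, ids, d.y)


def write_fixture(tmp_path, sep=",", suffix=".csv", label_row=True):
    rows = [
        "gene" + sep + sep.join(f"s{j}" for j in range(4)),
    ]
    if label_row:
        rows.append("label" + sep + "0" + sep + "0" + sep + "1" + sep + "1")
    rows += [
        "g1" + sep + "1.0" + sep + "2.0" + sep + "3.0" + sep + "4.0",
        "g2" + sep + "4.5" + sep + "3.5" + sep + "2.5" + sep + "1.5",
        "g3" + sep + "0.1" + sep + "0.4" + sep + "0.2" + sep + "0.3",
    ]
    p = tmp_path / f"expr{suffix}"
    p.write_text("\n".join(rows) + "\n")
    return p


class TestReadExpression:
    def test_basic_fixture_with_label_row(self, tmp_path):
        ds = read_expression(write_fixture(tmp_path))
        assert ds.n_genes == 3 and ds.n_samples == 4
        assert ds.gene_ids == ["g1", "g2", "g3"]
        assert ds.labels.tolist() == [0, 0, 1, 1]

    def test_csv_and_tsv_agree(self, tmp_path):
        a = read_expression(write_fixture(tmp_path, sep=",", suffix=".csv"))
        b = read_expression(write_fixture(tmp_path, sep="\t", suffix=".tsv"))
        assert np.array_equal(a.matrix, b.matrix)
        assert a.gene_ids == b.gene_ids

    def test_sidecar_labels(self, tmp_path):
        p = write_fixture(tmp_path, label_row=False)
        lp = tmp_path / "labels.txt"
        lp.write_text("a\na\nb\nb\n")
        ds = read_expression(p, labels_path=lp)
        assert ds.labels.tolist() == [0, 0, 1, 1]

    def test_duplicate_gene_id_named_in_error(self, tmp_path):
        p = tmp_path / "dup.csv"
        p.write_text("gene,s0,s1\nlabel,0,1\ngA,1,2\ngA,3,4\n")
        with pytest.raises(ValueError, match="gA"):
            read_expression(p)

    def test_non_numeric_cell_located(self, tmp_path):
        p = tmp_path / "bad.csv"
        p.write_text("gene,s0,s1\nlabel,0,1\ngA,1,oops\n")
        with pytest.raises(ValueError, match="gA"):
            read_expression(p)

    def test_label_count_mismatch(self, tmp_path):
        p = write_fixture(tmp_path, label_row=False)
        lp = tmp_path / "labels.txt"
        lp.write_text("0\n1\n")
        with pytest.raises(ValueError, match="label count"):
            read_expression(p, labels_path=lp)

    def test_missing_labels_rejected(self, tmp_path):
        with pytest.raises(ValueError, match="label"):
            read_expression(write_fixture(tmp_path, label_row=False))


class TestRankPairs:
    def test_two_genes_give_one_pair(self):
        ds = planted_matrix(0, n_samples=60, seed=1)
        pairs = rank_pairs(ds, top_k_pairs=5)
        assert len(pairs) == 1
        assert (pairs[0].gene_a, pairs[0].gene_b) == ("SYN1", "SYN2")

    def test_planted_pair_ranks_first(self):
        ds = planted_matrix(10, n_samples=100, seed=2)
        pairs = rank_pairs(ds, top_k_pairs=3)
        assert {pairs[0].gene_a, pairs[0].gene_b} == {"SYN1", "SYN2"}
        assert pairs[0].score > 0.8

    def test_deterministic_and_permutation_equivariant(self):
        ds = planted_matrix(6, n_samples=80, seed=3)
        ranked1 = rank_pairs(ds, top_k_pairs=10)
        ranked2 = rank_pairs(ds, top_k_pairs=10)
        perm = np.random.default_rng(0).permutation(ds.n_genes)
        shuffled = ExpressionDataset(
            ds.matrix[perm], [ds.gene_ids[i] for i in perm], ds.labels
        )
        ranked3 = rank_pairs(shuffled, top_k_pairs=10)
        as_tuples = lambda ps: [(p.gene_a, p.gene_b, round(p.score, 12)) for p in ps]
        assert as_tuples(ranked1) == as_tuples(ranked2) == as_tuples(ranked3)

    def test_workers_do_not_change_result(self):
        ds = planted_matrix(4, n_samples=60, seed=4)
        a = rank_pairs(ds, top_k_pairs=6, workers=1)
        b = rank_pairs(ds, top_k_pairs=6, workers=2)
        assert [(p.gene_a, p.gene_b, p.score) for p in a] == [
            (p.gene_a, p.gene_b, p.score) for p in b
        ]

    def test_candidate_restriction_and_validation(self):
        ds = planted_matrix(4, n_samples=60, seed=5)
        pairs = rank_pairs(ds, top_k_pairs=10, candidate_genes=["SYN1", "SYN2", "N000"])
        assert len(pairs) == 3
        with pytest.raises(ValueError, match="unknown candidate"):
            rank_pairs(ds, top_k_pairs=1, candidate_genes=["missing"])


class TestTopGenes:
    def test_simple_walk(self):
        pairs = [PairScore("g1", "g2", 0.9, 1), PairScore("g1", "g3", 0.8, 2)]
        assert top_genes_from_pairs(pairs, 3) == ["g1", "g2", "g3"]

    def test_hub_gene_collects_partners_in_rank_order(self):
        pairs = [PairScore("hub", f"p{i}", 1 - i / 10, i + 1) for i in range(8)]
        assert top_genes_from_pairs(pairs, 5) == ["hub", "p0", "p1", "p2", "p3"]

    def test_truncates_when_final_pair_adds_two(self):
        pairs = [PairScore(f"a{i}", f"b{i}", 1 - i / 10, i + 1) for i in range(5)]
        got = top_genes_from_pairs(pairs, 3)
        assert got == ["a0", "b0", "a1"]

    def test_exhausted_pairs_return_all_collected(self):
        pairs = [PairScore("x", "y", 0.5, 1)]
        assert top_genes_from_pairs(pairs, 10) == ["x", "y"]


class TestListOverlap:
    def test_identical_lists(self):
        counts = list_overlap([["a", "b"], ["a", "b"]])
        assert counts == {(1, 1): 2}

    def test_disjoint_lists(self):
        counts = list_overlap([["a"], ["b"]])
        assert counts == {(1, 0): 1, (0, 1): 1}

    def test_three_lists_match_set_algebra(self, rng):
        lists = [
            [f"g{i}" for i in rng.choice(40, size=15, replace=False)]
            for _ in range(3)
        ]
        assert list_overlap(lists) == venn_counts_reference(lists)

    def test_duplicates_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            list_overlap([["a", "a"], ["b"]])


class TestPairsIO:
    def test_round_trip(self, tmp_path):
        pairs = [
            PairScore("g1", "g2", 0.987654321, 1),
            PairScore("g3", "g4", -0.123456789, 2),
        ]
        p = tmp_path / "pairs.tsv"
        write_pairs(pairs, p)
        back = read_pairs(p)
        assert [(q.gene_a, q.gene_b, q.rank) for q in back] == [
            ("g1", "g2", 1), ("g3", "g4", 2)
        ]
        assert back[0].score == pytest.approx(0.987654321, rel=1e-6)

    def test_empty_list_writes_header_only(self, tmp_path):
        p = tmp_path / "empty.tsv"
        write_pairs([], p)
        assert p.read_text().splitlines()[0] == "rank\tgene_a\tgene_b\tmic3"
        assert read_pairs(p) == []
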