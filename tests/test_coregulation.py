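import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from crnets import (
    PPINetwork,
    RegulatorMatrix,
    RegulatoryNetwork,
    ValidationError,
    build_regulator_matrix,
    intersect_crnets,
    overlap_table,
    score_pairs,
    select_top_permille,
)
from crnets.coregulation import SimilarityScores


def phi_oracle(x, y):
    """Closed-form phi coefficient from the 2x2 contingency counts."""
    a = sum(1 for u, v in zip(x, y) if u == 1 and v == 1)
    b = sum(1 for u, v in zip(x, y) if u == 1 and v == 0)
    c = sum(1 for u, v in zip(x, y) if u == 0 and v == 1)
    d = sum(1 for u, v in zip(x, y) if u == 0 and v == 0)
    den = math.sqrt((a + b) * (c + d) * (a + c) * (b + d))
    return (a * d - b * c) / den if den else float("nan")


def make_matrix(arr, name="net"):
    arr = np.asarray(arr, dtype=np.uint8)
    return RegulatorMatrix(
        incidence=arr,
        regulator_ids=[f"r{i}" for i in range(arr.shape[0])],
        gene_ids=[f"g{i:02d}" for i in range(arr.shape[1])],
        source_network=name,
    )


class TestBuildRegulatorMatrix:
    def test_tr_edges_transcribed(self):
        net = RegulatoryNetwork(edges=frozenset({
            ("t1", "g1", "binding"), ("t1", "g2", "binding"), ("t2", "g2", "binding"),
        }))
        mat = build_regulator_matrix(net)
        assert mat.regulator_ids == ["t1", "t2"]
        assert mat.gene_ids == ["g1", "g2", "t1", "t2"]
        col = {g: mat.incidence[:, i].tolist() for i, g in enumerate(mat.gene_ids)}
        assert col["g1"] == [1, 0]
        assert col["g2"] == [1, 1]
        # TFs are genes too: their columns exist but are zero unless targeted
        assert col["t1"] == [0, 0] and col["t2"] == [0, 0]

    def test_ppi_uses_starting_node_as_regulator(self):
        net = PPINetwork(edges=frozenset({("p1", "p2")}))
        mat = build_regulator_matrix(net)
        assert mat.regulator_ids == ["p1"]
        assert mat.gene_ids == ["p1", "p2"]
        assert mat.incidence[:, 0].sum() == 0  # p1 has no upstream neighbour
        assert mat.incidence[0, 1] == 1

    def test_symmetrize_ppi_makes_both_columns_nonzero(self):
        net = PPINetwork(edges=frozenset({("p1", "p2")}))
        mat = build_regulator_matrix(net, symmetrize_ppi=True)
        assert mat.incidence[:, mat.gene_ids.index("p1")].sum() == 1
        assert mat.incidence[:, mat.gene_ids.index("p2")].sum() == 1

    def test_empty_network_rejected(self):
        with pytest.raises(ValidationError):
            build_regulator_matrix(PPINetwork(edges=frozenset()))


class TestScorePairs:
    def test_worked_examples(self):
        # columns: A=(1,1,0,0), B=(0,1,1,0), C=(1,1,0,0), D=(0,0,1,1)
        mat = make_matrix([[1, 0, 1, 0], [1, 1, 1, 0], [0, 1, 0, 1], [0, 0, 0, 1]])
        scores = dict(score_pairs(mat).items())
        assert scores[("g00", "g02")] == pytest.approx(1.0)  # identical regulator sets
        assert scores[("g00", "g01")] == pytest.approx(0.0, abs=1e-15)  # phi: a=b=c=d=1
        assert scores[("g00", "g03")] == pytest.approx(-1.0)  # complementary

    def test_zero_variance_column_excluded(self):
        mat = make_matrix([[1, 0, 0], [0, 1, 0]])
        scores = score_pairs(mat)
        assert scores.gene_ids == ["g00", "g01"]
        assert scores.n_undefined == 2  # the 2 pairs involving the all-zero g02
        assert len(scores) == 1

    def test_fewer_than_two_regulators_rejected(self):
        with pytest.raises(ValidationError):
            score_pairs(make_matrix([[1, 0, 1]]))

    def test_matches_phi_oracle_on_random_matrices(self):
        rng = np.random.default_rng(11)
        for _ in range(50):
            arr = (rng.random((8, 12)) < rng.uniform(0.2, 0.8)).astype(np.uint8)
            scores = score_pairs(make_matrix(arr))
            gidx = {g: i for i, g in enumerate([f"g{i:02d}" for i in range(12)])}
            for (g1, g2), r in scores.items():
                expected = phi_oracle(arr[:, gidx[g1]], arr[:, gidx[g2]])
                assert r == pytest.approx(expected, abs=1e-12)

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(st.integers(min_value=0, max_value=2 ** 96 - 1))
    def test_spearman_equals_pearson_on_binary(self, entropy):
        rng = np.random.default_rng(entropy)
        arr = (rng.random((8, 12)) < 0.4).astype(np.uint8)
        mat = make_matrix(arr)
        pe = score_pairs(mat, "pearson")
        sp = score_pairs(mat, "spearman")
        assert pe.gene_ids == sp.gene_ids
        np.testing.assert_allclose(sp.values, pe.values, atol=1e-12)

    def test_column_order_invariance(self):
        rng = np.random.default_rng(3)
        arr = (rng.random((6, 9)) < 0.5).astype(np.uint8)
        mat = make_matrix(arr)
        perm = rng.permutation(9)
        shuffled = RegulatorMatrix(
            incidence=arr[:, perm],
            regulator_ids=mat.regulator_ids,
            gene_ids=[mat.gene_ids[i] for i in perm],
            source_network="net",
        )
        a = dict(score_pairs(mat).items())
        b = dict(score_pairs(shuffled).items())
        assert set(a) == set(b)
        for k in a:
            assert a[k] == pytest.approx(b[k], abs=1e-12)


def scores_from_values(values):
    n = math.ceil((1 + math.sqrt(1 + 8 * len(values))) / 2)
    assert n * (n - 1) // 2 == len(values)
    return SimilarityScores(
        gene_ids=[f"g{i:03d}" for i in range(n)],
        values=np.asarray(values, dtype=float),
        method="pearson",
        n_undefined=0,
        source_network="net",
    )


class TestSelectTopPermille:
    def test_selects_k_largest(self):
        rng = np.random.default_rng(0)
        # 1000 scored pairs need C(n,2) = 1000 -> no integer n; use 46 genes (1035)
        values = rng.uniform(-1, 1, 1035)
        crnet = select_top_permille(scores_from_values(values), 5)
        assert len(crnet) == math.floor(0.005 * 1035) == 5
        assert min(crnet.edges.values()) >= np.sort(values)[-6]

    def test_ties_resolved_lexicographically(self):
        # 10 pairs (5 genes) all scored 1.0; permille=300 keeps k=3
        crnet = select_top_permille(scores_from_values([1.0] * 10), 300)
        assert sorted(crnet.pairs) == [
            ("g000", "g001"), ("g000", "g002"), ("g000", "g003"),
        ]

    def test_floor_law_and_nestedness(self):
        rng = np.random.default_rng(5)
        scores = scores_from_values(rng.uniform(-1, 1, 1770))
        previous = set()
        for pm in (1, 2, 3, 4, 5):
            crnet = select_top_permille(scores, pm)
            assert len(crnet) == math.floor(pm / 1000 * 1770)
            assert previous <= crnet.pairs
            previous = crnet.pairs

    def test_empty_cutoff_rejected(self):
        with pytest.raises(ValidationError, match="empty"):
            select_top_permille(scores_from_values([0.5, 0.2, 0.1]), 1)

    def test_permille_range_validated(self):
        scores = scores_from_values([0.5, 0.2, 0.1])
        for bad in (0, -1, 1001):
            with pytest.raises(ValidationError):
                select_top_permille(scores, bad)


class TestIntersectAndOverlap:
    def test_pairwise_intersection(self):
        a = {("a", "b"), ("c", "d")}
        b = {("c", "d"), ("e", "f")}
        assert intersect_crnets([a, b]) == {("c", "d")}
        assert intersect_crnets([a, a]) == a

    def test_three_way_singleton(self):
        shared = ("x", "y")
        sets = [{shared, ("a", f"b{i}")} for i in range(3)]
        assert intersect_crnets(sets) == {shared}

    def test_overlap_counts_match_brute_force(self):
        rng = np.random.default_rng(9)
        genes = [f"g{i}" for i in range(12)]
        def random_pairs():
            return {
                tuple(sorted(rng.choice(genes, 2, replace=False))) for _ in range(8)
            }
        sets = [random_pairs() for _ in range(3)]
        table = overlap_table(sets, names=["A", "B", "C"])
        union = sets[0] | sets[1] | sets[2]
        assert sum(table.values()) == len(union)
        # brute force every pair's region membership
        brute = {}
        for p in union:
            key = "&".join(n for n, s in zip("ABC", sets) if p in s)
            brute[key] = brute.get(key, 0) + 1
        for k, v in brute.items():
            assert table[k] == v
        assert table["A&B&C"] == len(sets[0] & sets[1] & sets[2])

    def test_nested_sets(self):
        a = {("a", "b")}
        b = {("a", "b"), ("c", "d")}
        table = overlap_table([a, b], names=["A", "B"])
        assert table["A&B"] == 1
        assert table["A"] == 0
        assert table["B"] == 1
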