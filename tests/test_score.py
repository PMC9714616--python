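"""Correlation binning, cumulative scoring, ranking — with brute-force oracle."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import riskscreen as rs
from riskscreen.score import CorrelationMatrix


def random_corr(rng, n):
    """Random valid correlation matrix via normalized Gram matrix."""
    x = rng.standard_normal((n, max(n + 1, 4)))
    g = x @ x.T
    d = np.sqrt(np.diag(g))
    r = g / np.outer(d, d)
    np.fill_diagonal(r, 1.0)
    return CorrelationMatrix(genes=[f"g{i}" for i in range(n)],
                             r=np.clip((r + r.T) / 2, -1, 1))


def brute_force_scores(matrix):
    """Naive double loop: the independent oracle for cumulative_scores."""
    def score(r):
        a = abs(r)
        if a < 0.4:
            return 0
        if a < 0.6:
            return 1
        if a < 0.8:
            return 2
        return 3

    out = {}
    for i, g in enumerate(matrix.genes):
        total = 0
        for j in range(len(matrix.genes)):
            if j != i:
                total += score(matrix.r[i, j])
        out[g] = total
    return out


class TestBin:
    @pytest.mark.parametrize("r,expected", [
        (0.35, 0), (-0.5, 1), (0.7, 2), (-0.9, 3),
        (0.0, 0), (1.0, 3), (-1.0, 3),
        (0.4, 1), (0.6, 2), (0.8, 3),       # left-closed boundaries
        (0.39999, 0), (0.59999, 1), (0.79999, 2),
    ])
    def test_bin_values(self, r, expected):
        assert rs.bin_correlation(r) == expected

    def test_out_of_range_errors(self):
        with pytest.raises(ValueError):
            rs.bin_correlation(1.5)


class TestPearson:
    def test_perfect_linear(self, toy_expression):
        values = pd.DataFrame(
            [[1.0, 2.0, 3.0, 4.0], [3.0, 5.0, 7.0, 9.0],
             [4.0, 3.0, 2.0, 1.0]],
            index=["g1", "g2", "g3"], columns=["t1", "t2", "t3", "t4"])
        ds = rs.ExpressionDataset("x", values, {c: "tumor" for c in values})
        corr = rs.pearson_matrix(ds, ["g1", "g2", "g3"], group="tumor")
        assert corr.r[0, 1] == pytest.approx(1.0)   # g2 = 2*g1 + 1
        assert corr.r[0, 2] == pytest.approx(-1.0)  # g3 = -g1
        assert np.allclose(np.diag(corr.r), 1.0)

    def test_independent_pair_small_r(self):
        rng = np.random.default_rng(8)
        values = pd.DataFrame(rng.standard_normal((2, 1000)),
                              index=["a", "b"],
                              columns=[f"s{i}" for i in range(1000)])
        ds = rs.ExpressionDataset("x", values, {c: "tumor" for c in values})
        corr = rs.pearson_matrix(ds, ["a", "b"])
        assert abs(corr.r[0, 1]) < 0.1

    def test_zero_variance_gene_excluded(self, caplog):
        values = pd.DataFrame(
            [[1.0, 2.0, 3.0], [5.0, 5.0, 5.0], [2.0, 1.0, 3.0]],
            index=["a", "flat", "b"], columns=["s1", "s2", "s3"])
        ds = rs.ExpressionDataset("x", values, {c: "tumor" for c in values})
        with caplog.at_level("WARNING"):
            corr = rs.pearson_matrix(ds, ["a", "flat", "b"])
        assert corr.genes == ["a", "b"]
        assert "zero-variance" in caplog.text

    def test_too_few_samples_errors(self):
        values = pd.DataFrame([[1.0, 2.0], [2.0, 1.0]], index=["a", "b"],
                              columns=["s1", "s2"])
        ds = rs.ExpressionDataset("x", values, {c: "tumor" for c in values})
        with pytest.raises(ValueError, match="3 samples"):
            rs.pearson_matrix(ds, ["a", "b"])


class TestCumulative:
    def test_three_gene_manual_binning(self):
        r = np.array([[1.0, 0.9, 0.5], [0.9, 1.0, 0.3], [0.5, 0.3, 1.0]])
        table = rs.cumulative_scores(
            CorrelationMatrix(genes=["g1", "g2", "g3"], r=r))
        assert table.cumulative == {"g1": 4, "g2": 3, "g3": 1}
        assert table.rank == {"g1": 1, "g2": 2, "g3": 3}

    def test_upper_bound_all_very_strong(self):
        n = 18
        r = np.full((n, n), 0.85)
        np.fill_diagonal(r, 1.0)
        table = rs.cumulative_scores(
            CorrelationMatrix(genes=[f"g{i}" for i in range(n)], r=r))
        assert all(v == 3 * (n - 1) == 51 for v in table.cumulative.values())

    def test_all_weak_scores_zero(self):
        r = np.full((3, 3), 0.1)
        np.fill_diagonal(r, 1.0)
        table = rs.cumulative_scores(
            CorrelationMatrix(genes=["a", "b", "c"], r=r))
        assert all(v == 0 for v in table.cumulative.values())

    @pytest.mark.parametrize("seed", range(30))
    def test_matches_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        matrix = random_corr(rng, int(rng.integers(2, 21)))
        table = rs.cumulative_scores(matrix)
        assert table.cumulative == brute_force_scores(matrix)

    @settings(deadline=None, max_examples=30)
    @given(st.integers(0, 2 ** 31 - 1))
    def test_handshake_identity(self, seed):
        rng = np.random.default_rng(seed)
        matrix = random_corr(rng, int(rng.integers(2, 15)))
        table = rs.cumulative_scores(matrix)
        upper = sum(table.pair_scores[i, j]
                    for i in range(len(matrix.genes))
                    for j in range(i + 1, len(matrix.genes)))
        assert sum(table.cumulative.values()) == 2 * upper
        assert all(0 <= v <= 3 * (len(matrix.genes) - 1)
                   for v in table.cumulative.values())

    def test_invariant_under_gene_permutation(self):
        rng = np.random.default_rng(99)
        matrix = random_corr(rng, 10)
        perm = rng.permutation(10)
        permuted = CorrelationMatrix(
            genes=[matrix.genes[i] for i in perm],
            r=matrix.r[np.ix_(perm, perm)])
        assert rs.cumulative_scores(matrix).cumulative == \
            rs.cumulative_scores(permuted).cumulative


class TestRank:
    def _table(self, cumulative):
        genes = list(cumulative)
        n = len(genes)
        table = rs.ScoreTable(genes=genes, pair_scores=np.zeros((n, n), int),
                              cumulative=dict(cumulative), rank={})
        distinct = sorted(set(cumulative.values()), reverse=True)
        table.rank = {g: distinct.index(v) + 1 for g, v in cumulative.items()}
        return table

    def test_top_k_with_shared_rank(self):
        table = self._table({"A": 21, "B": 21, "C": 20, "D": 19, "E": 18})
        top, expanded = rs.rank_core_genes(table, 4)
        assert top == ["A", "B", "C", "D"]
        assert not expanded

    def test_all_tied_returns_full_list_with_flag(self):
        table = self._table({"A": 5, "B": 5, "C": 5})
        top, expanded = rs.rank_core_genes(table, 1)
        assert top == ["A", "B", "C"] and expanded

    def test_k_equals_n(self):
        table = self._table({"A": 3, "B": 2, "C": 1})
        top, expanded = rs.rank_core_genes(table, 3)
        assert top == ["A", "B", "C"] and not expanded

    def test_k_out_of_range(self):
        table = self._table({"A": 3, "B": 2})
        with pytest.raises(ValueError):
            rs.rank_core_genes(table, 0)

    def test_core_module_tops_ranking(self, planted_world):
        from riskscreen.pipeline import _pool_tumor_samples
        truth = planted_world["truth"]
        pooled = _pool_tumor_samples(planted_world["cohorts"], truth.planted)
        corr = rs.pearson_matrix(pooled, truth.planted, group="tumor")
        table = rs.cumulative_scores(corr)
        top, _ = rs.rank_core_genes(table, len(truth.core_module))
        assert set(top) == set(truth.core_module)
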