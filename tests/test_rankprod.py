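"""Rank-product statistic, permutation p-values and DEG calling.

The permutation p-value is checked against an independent oracle that
enumerates *all* distinct reallocations of the replicates on a tiny
noise-free dataset, and the null calibration of the sampled version is
checked on pure-noise simulations.
"""

from __future__ import annotations

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from amascan import rankprod
from amascan.containers import ExpressionMatrix
from amascan.synthetic import SimulationConfig, simulate_expression


def make_expr(arrays: dict[str, list[float]], groups: dict[str, str]) -> ExpressionMatrix:
    genes = [f"g{i}" for i in range(len(next(iter(arrays.values()))))]
    values = pd.DataFrame(arrays, index=pd.Index(genes, name="gene"))
    return ExpressionMatrix(values=values, groups=groups)


class TestFoldChange:
    def test_sign_convention(self, tiny_expr):
        fc = rankprod.fold_change(tiny_expr, "A", "B")
        assert fc["flat"] == pytest.approx(1.0)
        assert fc["up4"] == pytest.approx(4.0)
        assert fc["down4"] == pytest.approx(-4.0)  # ratio 0.25 reported as -1/0.25

    def test_magnitude_at_least_one(self, tiny_expr):
        fc = rankprod.fold_change(tiny_expr, "A", "B")
        assert (fc.abs() >= 1.0).all()


class TestRankProduct:
    def test_consistent_winner_has_rp_one(self, tiny_expr):
        rp = rankprod.rank_product(tiny_expr, "A", "B", "up")
        assert rp["up4"] == pytest.approx(1.0)

    def test_hand_computed_geometric_means(self):
        # 3 genes, 1x2 replicates -> 2 comparisons with up-ranks
        # (1,2), (2,1), (3,3): RP = (sqrt(2), sqrt(2), 3)
        expr = make_expr(
            {"a1": [8.0, 4.0, 2.0], "b1": [80.0, 20.0, 2.0], "b2": [20.0, 80.0, 2.0]},
            {"a1": "A", "b1": "B", "b2": "B"},
        )
        rp = rankprod.rank_product(expr, "A", "B", "up")
        assert rp.to_numpy() == pytest.approx([np.sqrt(2), np.sqrt(2), 3.0])

    def test_identical_groups_tie_all_ranks(self):
        expr = make_expr(
            {"a1": [3.0, 5.0], "a2": [3.0, 5.0], "b1": [3.0, 5.0], "b2": [3.0, 5.0]},
            {"a1": "A", "a2": "A", "b1": "B", "b2": "B"},
        )
        rp = rankprod.rank_product(expr, "A", "B", "up")
        assert rp.nunique() == 1  # every gene shares the same average rank

    def test_direction_symmetry_under_group_swap(self, tiny_expr):
        fwd_up = rankprod.rank_product(tiny_expr, "A", "B", "up")
        rev_down = rankprod.rank_product(tiny_expr, "B", "A", "down")
        assert fwd_up.to_numpy() == pytest.approx(rev_down.to_numpy())

    def test_empty_group_rejected(self, tiny_expr):
        with pytest.raises(KeyError):
            rankprod.rank_product(tiny_expr, "A", "C", "up")


def exhaustive_permutation_pvalues(expr, group_a, group_b, n_perm):
    """Oracle: exact expectation of the sampled p-value by enumerating every
    reallocation of the pooled replicates (uniform over C(n_a+n_b, n_a))."""
    samples = expr.samples_of(group_a) + expr.samples_of(group_b)
    n_a = len(expr.samples_of(group_a))
    log_all = np.log(expr.values[samples].to_numpy(dtype=float))

    def stat(cols_a, cols_b, direction):
        la, lb = log_all[:, list(cols_a)], log_all[:, list(cols_b)]
        folds = (lb[:, None, :] - la[:, :, None]).reshape(log_all.shape[0], -1)
        keyed = -folds if direction == "up" else folds
        ranks = sps.rankdata(keyed, axis=0, method="average")
        return np.mean(np.log(ranks), axis=1)

    idx = range(len(samples))
    obs = {d: stat(range(n_a), range(n_a, len(samples)), d) for d in ("up", "down")}
    n_genes = log_all.shape[0]
    expected = {}
    for d in ("up", "down"):
        pools = []
        for a_set in itertools.combinations(idx, n_a):
            b_set = tuple(i for i in idx if i not in a_set)
            pools.append(stat(a_set, b_set, d))
        pool = np.stack(pools)  # (n_splits, genes)
        # expected #null <= obs per sampled permutation, then plug into the
        # pseudocount formula with n_perm samples
        frac_le = (pool[:, :, None] <= obs[d][None, None, :] + 1e-9).mean(axis=(0, 1)) * n_genes
        expected[d] = (1 + n_perm * frac_le) / (1 + n_genes * n_perm)
    return obs, expected


class TestPermutationPvalues:
    def test_matches_exhaustive_relabelling_oracle(self):
        """Sampled p-values converge to the exact enumeration over all
        C(4,2) replicate reallocations on noise-free data."""
        expr = make_expr(
            {
                "a1": [10.0, 50.0, 9.0, 30.0],
                "a2": [11.0, 52.0, 8.0, 29.0],
                "b1": [1000.0, 49.0, 10.0, 31.0],
                "b2": [990.0, 51.0, 11.0, 28.0],
            },
            {"a1": "A", "a2": "A", "b1": "B", "b2": "B"},
        )
        n_perm = 4000
        tab = rankprod.rank_product_pvalues(expr, "A", "B", n_perm=n_perm, seed=9)
        _, expected = exhaustive_permutation_pvalues(expr, "A", "B", n_perm)
        for d in ("up", "down"):
            got = tab[f"p_{d}"].to_numpy()
            # Monte-Carlo slack: counts fluctuate ~sqrt(expected hits)
            assert got == pytest.approx(expected[d], rel=0.25, abs=3e-4)

    def test_null_pvalues_are_uniform(self):
        """Pure-noise data: KS distance of raw p-values from uniform < 0.05."""
        cfg = SimulationConfig(
            seed=7, n_genes=10_000, n_de_genes=0,
            cluster_spec=("3L", 12_000_000, 500_000, 0),
        )
        expr, _ = simulate_expression(cfg)
        tab = rankprod.rank_product_pvalues(expr, "group1", "group2", n_perm=100, seed=5)
        for col in ("p_up", "p_down"):
            ks = sps.kstest(tab[col], "uniform").statistic
            assert ks < 0.05

    def test_fixed_seed_is_deterministic(self, tiny_expr):
        a = rankprod.rank_product_pvalues(tiny_expr, "A", "B", n_perm=50, seed=4)
        b = rankprod.rank_product_pvalues(tiny_expr, "A", "B", n_perm=50, seed=4)
        pd.testing.assert_frame_equal(a, b)

    def test_rejects_nonpositive_n_perm(self, tiny_expr):
        with pytest.raises(ValueError):
            rankprod.rank_product_pvalues(tiny_expr, "A", "B", n_perm=0)


class TestCallDegs:
    def _table(self, rows):
        tab = pd.DataFrame(rows, columns=["fold", "q"])
        tab.index = [f"g{i}" for i in range(len(rows))]
        return tab

    def test_q_cutoff_is_strict(self):
        tab = self._table([(3.0, 0.05), (3.0, 0.0499)])
        degs, reported = rankprod.call_degs(tab)
        assert list(degs.index) == ["g1"]
        assert list(reported.index) == ["g1"]

    def test_fold_filter_splits_deg_and_reported_sets(self):
        tab = self._table([(1.5, 0.01), (-2.0, 0.01), (2.5, 0.2)])
        degs, reported = rankprod.call_degs(tab)
        assert set(degs.index) == {"g0", "g1"}
        assert set(reported.index) == {"g1"}  # |fold| >= 2 required

    def test_empty_table_rejected(self):
        with pytest.raises(ValueError):
            rankprod.call_degs(self._table([]))


class TestNullErrorControl:
    def test_fdr_controlled_on_null_data(self):
        """With no planted effects the q<0.05 call rate stays near zero."""
        cfg = SimulationConfig(
            seed=13, n_genes=3000, n_de_genes=0,
            cluster_spec=("3L", 12_000_000, 500_000, 0),
        )
        expr, _ = simulate_expression(cfg)
        tab = rankprod.rank_product_table(expr, "group1", "group2", n_perm=100, seed=2)
        frac = (tab["q"] < 0.05).mean()
        # 0.05 + 3 Monte-Carlo standard errors at G genes
        assert frac <= 0.05 + 3 * np.sqrt(0.05 * 0.95 / len(tab))
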