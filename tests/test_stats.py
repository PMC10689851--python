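import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from wtme.io import ExpressionMatrix, GeneSetCollection
from wtme.stats import (
    bh_fdr,
    differential_expression,
    enrichment_running_sum,
    fisher_exact_twosided,
    mannwhitney_exact,
    preranked_gsea,
    representation_factor,
    threshold_de,
)


def hypergeom_tail_enumeration(N, m, n, k):
    """P(X >= k) by direct summation of the hypergeometric pmf."""
    total = 0.0
    for x in range(k, min(m, n) + 1):
        total += (
            math.comb(m, x) * math.comb(N - m, n - x) / math.comb(N, n)
        )
    return total


class TestRepresentationFactor:
    @pytest.mark.parametrize(
        "m,n,k,expected_rf",
        [
            (2286, 1582, 737, 3.4),  # two independent anaplastic cohorts, up genes
            (2286, 2368, 1016, 3.1),  # patient cohort vs cell-line panel, up genes
            (1833, 1631, 510, 2.8),  # patient cohort vs cell-line panel, down genes
        ],
    )
    def test_published_overlaps_reproduce_to_one_decimal(self, m, n, k, expected_rf):
        res = representation_factor(m, n, k, N=16475)
        assert round(res.rf, 1) == expected_rf
        assert res.method == "exact"
        assert res.p < 1e-4

    def test_overlap_at_expectation_gives_rf_one(self):
        m, n, N = 40, 50, 200
        k = round(m * n / N)
        assert representation_factor(m, n, k, N).rf == pytest.approx(1.0)

    def test_exact_tail_matches_enumeration(self):
        res = representation_factor(5, 8, 4, 20)
        assert res.p == pytest.approx(hypergeom_tail_enumeration(20, 5, 8, 4), rel=1e-12)

    @pytest.mark.parametrize("N", [10, 20, 30])
    def test_enumeration_oracle_over_small_universes(self, N, rng):
        for _ in range(10):
            m = int(rng.integers(1, N + 1))
            n = int(rng.integers(1, N + 1))
            k = int(rng.integers(max(0, m + n - N), min(m, n) + 1))
            res = representation_factor(m, n, k, N)
            assert res.p == pytest.approx(
                hypergeom_tail_enumeration(N, m, n, k), rel=1e-10
            )

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError, match="exceeds"):
            representation_factor(5, 5, 6, 100)
        with pytest.raises(ValueError, match="smaller"):
            representation_factor(50, 5, 3, 20)

    def test_normal_approximation_above_cutoff(self):
        res = representation_factor(200_000, 150_000, 25_000, 2_000_000)
        assert res.method == "normal"
        assert 0 <= res.p <= 1


class TestBhFdr:
    def test_single_p_unchanged(self):
        assert bh_fdr([0.04])[0] == pytest.approx(0.04)

    def test_hand_step_up(self):
        np.testing.assert_allclose(bh_fdr([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03])

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=20))
    @settings(max_examples=50, deadline=None)
    def test_order_invariance_and_range(self, ps):
        q = bh_fdr(ps)
        assert np.all((q >= 0) & (q <= 1))
        perm = np.random.default_rng(0).permutation(len(ps))
        q_perm = bh_fdr(np.asarray(ps)[perm])
        np.testing.assert_allclose(q_perm, q[perm])

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_fdr([0.5, 1.2])


def log_matrix(values, genes=None, samples=None):
    values = np.asarray(values, dtype=float)
    genes = genes or [f"g{i}" for i in range(values.shape[0])]
    samples = samples or [f"s{j}" for j in range(values.shape[1])]
    return ExpressionMatrix(pd.DataFrame(values, index=genes, columns=samples), "log2TPM")


class TestDifferentialExpression:
    def test_identical_groups_are_null(self, rng):
        block = rng.uniform(0, 5, size=(6, 3))
        m = log_matrix(np.hstack([block, block]))
        groups = {f"s{j}": (1 if j < 3 else 2) for j in range(6)}
        de = differential_expression(m, groups)
        np.testing.assert_allclose(de["log2fc"], 0.0)
        assert (de["p"] > 0.95).all()  # continuity correction keeps p just under 1

    def test_complete_five_vs_five_separation_exact_p(self):
        # complete rank separation: exact two-sided Mann-Whitney p = 2/252
        vals = np.array([[1, 2, 3, 4, 5, 6, 7, 8, 9, 10]], dtype=float)
        m = log_matrix(vals)
        groups = {f"s{j}": (1 if j < 5 else 2) for j in range(10)}
        de = differential_expression(m, groups)
        assert de["p"].iloc[0] == pytest.approx(2 / 252)
        assert round(de["p"].iloc[0], 3) == 0.008

    def test_exact_p_matches_full_enumeration_small_groups(self, rng):
        x = rng.normal(size=4)
        y = rng.normal(size=5)
        observed = mannwhitney_exact(x, y)
        # enumerate all C(9,4) assignments of the pooled values
        pooled = np.concatenate([x, y])
        u_obs = sum((xi > yj) for xi in x for yj in y)
        n_extreme = 0
        n_total = 0
        for idx in itertools.combinations(range(9), 4):
            xs = pooled[list(idx)]
            ys = pooled[[i for i in range(9) if i not in idx]]
            u = sum((xi > yj) for xi in xs for yj in ys)
            n_total += 1
            if abs(u - 10) >= abs(u_obs - 10):  # center of U range is mn/2 = 10
                n_extreme += 1
        assert observed == pytest.approx(n_extreme / n_total, rel=1e-9)

    def test_planted_shift_passes_filter(self):
        # a shift comfortably above the 2-fold threshold (2 log2 units = 4-fold)
        # must clear the strict FC/p/FDR filter in nearly every replicate
        hits = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            base = rng.normal(5, 0.2, size=(1, 100))
            shifted = base.copy()
            shifted[0, 50:] += 2.0
            m = log_matrix(shifted)
            groups = {f"s{j}": (1 if j < 50 else 2) for j in range(100)}
            de = differential_expression(m, groups)
            up, _ = threshold_de(de)
            hits += bool(up)
        assert hits >= 19  # >= 95% of replicates

    def test_small_group_rejected(self, rng):
        m = log_matrix(rng.uniform(size=(3, 4)))
        with pytest.raises(ValueError, match=">= 2"):
            differential_expression(m, {"s0": 1, "s1": 2, "s2": 2, "s3": 2})


class TestThresholdDe:
    def test_strict_boundaries_and_empty(self):
        de = pd.DataFrame(
            {
                "log2fc": [1.0, 1.01, -1.0, -1.01],
                "p": [0.01] * 4,
                "q": [0.1] * 4,
            },
            index=["at_up", "above_up", "at_down", "below_down"],
        )
        up, down = threshold_de(de)
        assert up == {"above_up"} and down == {"below_down"}
        up, down = threshold_de(pd.DataFrame(columns=["log2fc", "p", "q"]))
        assert up == set() and down == set()

    def test_matches_brute_force_row_scan(self, rng):
        de = pd.DataFrame(
            {
                "log2fc": rng.normal(0, 2, 200),
                "p": rng.uniform(0, 1, 200),
                "q": rng.uniform(0, 1, 200),
            },
            index=[f"g{i}" for i in range(200)],
        )
        up, down = threshold_de(de)
        for g, row in de.iterrows():
            fc = 2 ** row["log2fc"]
            expect_up = fc > 2 and row["p"] < 0.05 and row["q"] < 0.25
            expect_down = fc < 0.5 and row["p"] < 0.05 and row["q"] < 0.25
            assert (g in up) == expect_up
            assert (g in down) == expect_down


class TestFisherTwoSided:
    def test_published_contingency_value(self):
        # 4-of-5 vs 0-of-5 alteration split prints as P = 0.048
        assert fisher_exact_twosided([[4, 1], [0, 5]]) == pytest.approx(1 / 21)
        assert round(fisher_exact_twosided([[4, 1], [0, 5]]), 3) == 0.048


class TestPrerankedGsea:
    @staticmethod
    def ranked(n, rng=None, descending=True):
        vals = np.linspace(3, -3, n) if descending else (rng.normal(size=n))
        return pd.Series(vals, index=[f"g{i:02d}" for i in range(n)])

    def test_set_of_top_genes_reaches_es_one(self):
        scores = self.ranked(20)
        sets = GeneSetCollection({"top": [f"g{i:02d}" for i in range(5)]})
        res = preranked_gsea(scores, sets, n_permutations=50, seed=0)
        assert res.table.loc["top", "es"] == pytest.approx(1.0)

    def test_nes_sign_matches_es_sign(self, rng):
        scores = pd.Series(rng.normal(size=40), index=[f"g{i:02d}" for i in range(40)])
        sets = GeneSetCollection(
            {f"set{k}": list(rng.choice(scores.index, size=6, replace=False)) for k in range(5)}
        )
        res = preranked_gsea(scores, sets, n_permutations=100, seed=1)
        nonzero = res.table[res.table["es"] != 0]
        assert (np.sign(nonzero["nes"]) == np.sign(nonzero["es"])).all()

    def test_weight_zero_matches_unweighted_ks_oracle(self):
        # all-equal scores, weight 0: ES must equal the classic unweighted
        # KS statistic computed by explicit stepping, for every subset
        n = 8
        scores = np.zeros(n)
        for size in range(1, n):
            for subset in itertools.combinations(range(n), size):
                mask = np.zeros(n, dtype=bool)
                mask[list(subset)] = True
                running = enrichment_running_sum(scores, mask, weight=0.0)
                # oracle: step through positions maintaining both fractions
                cum_in = cum_out = 0
                best = 0.0
                for i in range(n):
                    if mask[i]:
                        cum_in += 1
                    else:
                        cum_out += 1
                    dev = cum_in / size - cum_out / (n - size)
                    if abs(dev) > abs(best):
                        best = dev
                i = int(np.argmax(np.abs(running)))
                assert running[i] == pytest.approx(best, abs=1e-12)

    def test_no_overlap_set_skipped_with_warning(self):
        scores = self.ranked(10)
        sets = GeneSetCollection({"ok": ["g00", "g01"], "ghost": ["zzz"]})
        with pytest.warns(UserWarning, match="ghost"):
            res = preranked_gsea(scores, sets, n_permutations=20, seed=0)
        assert list(res.table.index) == ["ok"]

    def test_p_values_stable_under_large_permutation_count(self):
        scores = self.ranked(60)
        sets = GeneSetCollection({"top": [f"g{i:02d}" for i in range(8)]})
        p1 = preranked_gsea(scores, sets, n_permutations=800, seed=3).table["p"].iloc[0]
        p2 = preranked_gsea(scores, sets, n_permutations=800, seed=7).table["p"].iloc[0]
        # Monte-Carlo error at 800 draws
        assert abs(p1 - p2) < 3 * np.sqrt(0.05 * 0.95 / 800) + 1e-3
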