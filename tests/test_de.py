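import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import txmod
from txmod.exceptions import EmptyResultError, ValidationError


class TestBenjaminiHochberg:
    def test_hand_computed_step_up(self):
        assert np.allclose(txmod.benjamini_hochberg([0.01, 0.02, 0.03]),
                           [0.03, 0.03, 0.03])

    def test_single_p_unchanged(self):
        assert txmod.benjamini_hochberg([0.2])[0] == pytest.approx(0.2)

    def test_all_ones(self):
        assert np.allclose(txmod.benjamini_hochberg([1.0, 1.0, 1.0]), 1.0)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValidationError):
            txmod.benjamini_hochberg([0.5, 1.5])

    @settings(deadline=None, max_examples=50)
    @given(st.lists(st.floats(0, 1), min_size=1, max_size=30))
    def test_q_dominates_p_and_order_equivariance(self, pvals):
        p = np.array(pvals)
        q = txmod.benjamini_hochberg(p)
        assert np.all(q >= p - 1e-12) and np.all(q <= 1.0)
        perm = np.random.default_rng(0).permutation(len(p))
        assert np.allclose(txmod.benjamini_hochberg(p[perm]), q[perm])


class TestDifferentialExpression:
    def _expr(self, rows, samples=None):
        values = np.array(rows, dtype=float)
        genes = [f"g{i}" for i in range(values.shape[0])]
        samples = samples or [f"s{j}" for j in range(values.shape[1])]
        return txmod.ExpressionMatrix(genes, samples, values)

    def test_separated_groups_significant_up(self):
        expr = self._expr([[10, 11, 12, 0, 1, 2],
                           [5, 5, 5, 5, 5, 5]])
        res = txmod.differential_expression(expr, ["s0", "s1", "s2"],
                                            ["s3", "s4", "s5"])
        assert res.loc["g0", "pvalue"] < 0.01
        assert res.loc["g0", "direction"] == "up"
        assert res.loc["g0", "log2fc"] == pytest.approx(10.0)

    def test_identical_values_null(self):
        expr = self._expr([[5, 5, 5, 5]])
        res = txmod.differential_expression(expr, ["s0", "s1"], ["s2", "s3"])
        assert res.loc["g0", "log2fc"] == 0.0
        assert res.loc["g0", "pvalue"] == 1.0

    def test_overlapping_groups_rejected(self, random_expr):
        with pytest.raises(ValidationError, match="overlap"):
            txmod.differential_expression(random_expr, ["s0", "s1"],
                                          ["s1", "s2"])

    def test_null_pvalues_uniform(self):
        """On a null cohort (no condition effect) the engine's p-values are
        approximately uniform (KS not significant at alpha=0.01)."""
        from scipy import stats
        cfg = txmod.GeneratorConfig(seed=21, n_genes=600,
                                    proportion_shifts={}, induced_programs=[])
        counts, meta, _ = txmod.simulate_bulk_cohort(cfg)
        meta_idx = meta.set_index("sample_id")
        blood = [s for s in counts.samples
                 if meta_idx.loc[s, "compartment"] == "blood"]
        pos = [s for s in blood if meta_idx.loc[s, "condition"] == "HIVpos"]
        neg = [s for s in blood if meta_idx.loc[s, "condition"] == "HIVneg"]
        res = txmod.differential_expression(counts.subset_samples(blood),
                                            pos, neg)
        ks = stats.kstest(res["pvalue"], "uniform")
        assert ks.pvalue > 0.01

    def test_moderated_t_agrees_with_welch_on_strong_effects(self):
        expr = self._expr([[10, 11, 12, 9, 0, 1, 2, 1],
                           [4, 5, 6, 5, 5, 6, 4, 5]])
        a, b = ["s0", "s1", "s2", "s3"], ["s4", "s5", "s6", "s7"]
        welch = txmod.differential_expression(expr, a, b,
                                              method="welch_t_logcpm")
        mod = txmod.differential_expression(expr, a, b, method="moderated_t")
        assert mod.loc["g0", "pvalue"] < 0.05
        assert welch.loc["g0", "significant"] == mod.loc["g0", "significant"]


class TestMannWhitney:
    def test_exact_small_sample_p(self):
        """A={1,2,3} vs B={4,5,6}: U=0, exact two-sided p = 2*1/20 = 0.1."""
        assert txmod.mann_whitney_u([1, 2, 3], [4, 5, 6]) == pytest.approx(0.1)

    def test_identical_vectors_p_one(self):
        assert txmod.mann_whitney_u([2, 2, 2], [2, 2, 2]) == 1.0

    def test_large_groups_use_tie_corrected_normal(self):
        rng = np.random.default_rng(1)
        a = rng.integers(0, 5, 20)
        b = rng.integers(0, 5, 20)
        p = txmod.mann_whitney_u(a, b)
        assert 0.0 < p <= 1.0

    def test_module_test_stratified(self, small_metadata):
        scores = pd.DataFrame([[1.0, 2.0, 1.0, 2.0]], index=["m"],
                              columns=["s1", "s2", "s3", "s4"])
        with pytest.warns(UserWarning, match="missing"):
            out = txmod.mann_whitney_module_test(scores, small_metadata)
        assert set(out["stratum"]) == {"blood", "BAL"}
        assert out["pvalue"].isna().all()  # only 1 sample per group per stratum


class TestOverlapSummary:
    def test_pooled_convention_worked_example(self):
        a = [f"b{i}" for i in range(136)] + ["x", "y", "z"]
        b = [f"l{i}" for i in range(10)] + ["x", "y", "z"]
        out = txmod.overlap_summary(a, b)
        assert out == {"nA": 139, "nB": 13, "n_shared": 3,
                       "pooled_total": 152, "percent_shared": 2}

    def test_disjoint_and_identical(self):
        assert txmod.overlap_summary(["a"], ["b"])["percent_shared"] == 0
        same = [f"g{i}" for i in range(10)]
        out = txmod.overlap_summary(same, same)
        assert out["n_shared"] == 10 and out["pooled_total"] == 20
        assert out["percent_shared"] == 50

    def test_symmetry_and_empty(self):
        a, b = ["a", "b", "c"], ["b", "d"]
        fwd, rev = txmod.overlap_summary(a, b), txmod.overlap_summary(b, a)
        assert fwd["n_shared"] == rev["n_shared"]
        assert fwd["pooled_total"] == rev["pooled_total"]
        assert txmod.overlap_summary([], [])["percent_shared"] == 0


class TestOraEnrichment:
    def test_fully_contained_set_exact_tail(self):
        universe = [f"g{i}" for i in range(100)]
        hits = universe[:10]
        module = txmod.GeneModule("hit_set", universe[:10])
        out = txmod.ora_enrichment(hits, universe, [module])
        # P(overlap >= 10) = C(10,10)*C(90,0)/C(100,10), by direct counting
        expected = 1.0 / math.comb(100, 10) * math.comb(90, 0)
        assert out.loc[0, "pvalue"] == pytest.approx(expected, rel=1e-6)

    def test_disjoint_set_skipped_with_warning(self):
        universe = ["a", "b"]
        with pytest.warns(UserWarning, match="disjoint"):
            out = txmod.ora_enrichment(["a"], universe,
                                       [txmod.GeneModule("x", ["zzz"])])
        assert len(out) == 0

    def test_empty_universe_rejected(self):
        with pytest.raises(EmptyResultError):
            txmod.ora_enrichment([], [], [txmod.GeneModule("x", ["a"])])

    def test_null_calibration(self):
        """Random hit draws give roughly uniform p: fraction below 0.05 within
        [0.02, 0.08] over 1000 draws."""
        rng = np.random.default_rng(7)
        universe = [f"g{i}" for i in range(1000)]
        module = txmod.GeneModule("m", universe[:100])
        below = 0
        for _ in range(1000):
            hits = list(rng.choice(universe, 50, replace=False))
            out = txmod.ora_enrichment(hits, universe, [module])
            below += out.loc[0, "pvalue"] < 0.05
        assert 0.02 <= below / 1000 <= 0.08


class TestPCA:
    def test_separated_clouds_split_on_pc1(self):
        rng = np.random.default_rng(0)
        left = rng.normal(0, 0.1, size=(30, 6))
        right = rng.normal(4, 0.1, size=(30, 6))
        values = np.hstack([left, right])
        expr = txmod.ExpressionMatrix([f"g{i}" for i in range(30)],
                                      [f"s{j}" for j in range(12)], values)
        coords, var = txmod.pca_embedding(expr)
        pc1 = coords["PC1"].to_numpy()
        assert (pc1[:6].max() < pc1[6:].min()) or (pc1[6:].max() < pc1[:6].min())
        assert var.sum() <= 100.0 + 1e-9

    def test_duplicated_sample_identical_coordinates(self, random_expr):
        values = np.hstack([random_expr.values, random_expr.values[:, :1]])
        expr = txmod.ExpressionMatrix(random_expr.genes,
                                      random_expr.samples + ["dup"], values)
        coords, _ = txmod.pca_embedding(expr)
        assert np.allclose(coords.loc["dup"], coords.loc["s0"], atol=1e-8)

    def test_constant_matrix_zero_everything(self):
        expr = txmod.ExpressionMatrix(["a", "b"], ["s0", "s1", "s2"],
                                      np.full((2, 3), 3.0))
        coords, var = txmod.pca_embedding(expr)
        assert np.allclose(coords, 0.0) and np.allclose(var, 0.0)
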