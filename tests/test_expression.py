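import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from spiscan.expression_analysis import (
    ExpressionError,
    bh_adjust,
    call_venom_specific,
    ddct,
    flag_pseudogene,
    log2_profile,
    venom_specificity_test,
)
from spiscan.synthetic_data import generate_ct, generate_expression


def brute_force_bh(pvals):
    """Direct step-up definition: adj_i = min_{j: p_j >= p_i-rank} (m/rank_j) p_j."""
    m = len(pvals)
    order = np.argsort(pvals, kind="mergesort")
    adjusted = np.empty(m)
    running_min = 1.0
    for rank_from_top in range(m, 0, -1):
        idx = order[rank_from_top - 1]
        running_min = min(running_min, pvals[idx] * m / rank_from_top)
        adjusted[idx] = running_min
    return adjusted


class TestLog2Profile:
    def test_transform_values(self):
        mat = pd.DataFrame({"s1": [0.0, 7.0, 1023.0]}, index=["g1", "g2", "g3"])
        out = log2_profile(mat, pseudocount=1.0)
        assert list(out["s1"]) == pytest.approx([0.0, 3.0, 10.0])

    def test_negative_fpkm_rejected(self):
        mat = pd.DataFrame({"s1": [-1.0]}, index=["g1"])
        with pytest.raises(ExpressionError, match="negative"):
            log2_profile(mat)

    def test_nonpositive_pseudocount_rejected(self):
        mat = pd.DataFrame({"s1": [1.0]}, index=["g1"])
        with pytest.raises(ExpressionError, match="pseudocount"):
            log2_profile(mat, pseudocount=0.0)


class TestPseudogeneFlag:
    def test_flat_zero_gene_flagged(self):
        mat = pd.DataFrame({"s1": [0.0, 50.0], "s2": [0.0, 2.0]}, index=["g1", "g2"])
        assert flag_pseudogene(mat, "g1")
        assert not flag_pseudogene(mat, "g2")

    def test_boundary_at_exactly_one(self):
        mat = pd.DataFrame({"s1": [1.0], "s2": [1.0]}, index=["g1"])
        assert flag_pseudogene(mat, "g1")


class TestVenomSpecificityTest:
    def test_equal_expression_null_centered(self):
        assert venom_specificity_test(5.0, 5.0) >= 0.5

    def test_both_zero_no_evidence(self):
        assert venom_specificity_test(0.0, 0.0) == 1.0

    def test_matches_independent_binomial_tail(self):
        p = venom_specificity_test(100.0, 10.0, library_scale=10.0)
        expected = float(stats.binom.sf(999, 1100, 0.5))
        assert p == pytest.approx(expected, rel=1e-12)


class TestBH:
    def test_hand_computed_step_up(self):
        assert bh_adjust([0.01, 0.02, 0.03]) == pytest.approx([0.03, 0.03, 0.03])

    def test_single_p_identity(self):
        assert bh_adjust([0.5]) == [0.5]

    def test_sorted_input_gives_nondecreasing_adjusted(self):
        rng = np.random.default_rng(5)
        p = np.sort(rng.uniform(size=40))
        adj = bh_adjust(p)
        assert all(a <= b + 1e-12 for a, b in zip(adj, adj[1:]))

    def test_out_of_range_rejected(self):
        with pytest.raises(ExpressionError):
            bh_adjust([0.5, 1.5])

    @settings(deadline=None, max_examples=50)
    @given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1, max_size=100))
    def test_matches_brute_force_definition(self, pvals):
        assert bh_adjust(pvals) == pytest.approx(brute_force_bh(np.array(pvals)))


class TestVenomCalls:
    def test_planted_passers_called_exactly(self):
        mat, truth = generate_expression(seed=11)
        calls = call_venom_specific(mat, "venom_gland", "carcass")
        passed = {c.gene_id for c in calls if c.passed}
        assert passed == set(truth[truth.passes].gene_id)

    def test_vg_gate(self):
        mat = pd.DataFrame(
            {"venom_gland": [9.0], "carcass": [0.1]}, index=["g1"]
        )
        calls = call_venom_specific(mat, "venom_gland", "carcass")
        assert not calls[0].passed  # FPKM_VG <= 10

    def test_ratio_gate(self):
        mat = pd.DataFrame(
            {"venom_gland": [15.0], "carcass": [10.0]}, index=["g1"]
        )
        calls = call_venom_specific(mat, "venom_gland", "carcass")
        assert not calls[0].passed
        assert calls[0].log2_ratio < 1

    def test_missing_sample_is_error(self):
        mat = pd.DataFrame({"venom_gland": [1.0]}, index=["g1"])
        with pytest.raises(ExpressionError, match="carcass"):
            call_venom_specific(mat, "venom_gland", "carcass")

    def test_pass_set_invariant_to_gene_order(self):
        mat, truth = generate_expression(seed=13)
        calls = call_venom_specific(mat, "venom_gland", "carcass")
        shuffled = mat.sample(frac=1.0, random_state=0)
        calls2 = call_venom_specific(shuffled, "venom_gland", "carcass")
        assert {c.gene_id for c in calls if c.passed} == {
            c.gene_id for c in calls2 if c.passed
        }


class TestDdct:
    def _table(self, cts):
        rows = []
        for gene, samples in cts.items():
            for sample, reps in samples.items():
                for i, ct in enumerate(reps, start=1):
                    rows.append({"gene": gene, "sample": sample, "replicate": i, "ct": ct})
        return pd.DataFrame(rows)

    def test_flat_cts_give_fold_one(self):
        table = self._table(
            {"t": {"a": [20, 20], "b": [20, 20]}, "r": {"a": [15, 15], "b": [15, 15]}}
        )
        folds = ddct(table, "t", "r", "a")
        assert folds["a"] == 1.0 and folds["b"] == 1.0

    def test_one_cycle_lower_doubles_fold(self):
        table = self._table({"t": {"a": [20], "b": [19]}, "r": {"a": [15], "b": [15]}})
        assert ddct(table, "t", "r", "a")["b"] == pytest.approx(2.0)

    def test_ddct_plus_two_quarters_fold(self):
        table = self._table({"t": {"a": [20], "b": [22]}, "r": {"a": [15], "b": [15]}})
        assert ddct(table, "t", "r", "a")["b"] == pytest.approx(0.25)

    def test_global_ct_shift_leaves_folds_unchanged(self):
        table = self._table({"t": {"a": [20], "b": [18]}, "r": {"a": [15], "b": [15]}})
        shifted = table.copy()
        shifted["ct"] = shifted["ct"] + 3.0
        pd.testing.assert_series_equal(
            ddct(table, "t", "r", "a"), ddct(shifted, "t", "r", "a")
        )

    def test_missing_reference_is_error(self):
        table = self._table({"t": {"a": [20], "b": [18]}, "r": {"a": [15]}})
        with pytest.raises(ExpressionError, match="missing reference"):
            ddct(table, "t", "r", "a")

    def test_noiseless_generator_folds_recovered(self):
        table, truth = generate_ct(seed=3, noise_sd=0.0)
        for gene in truth.gene.unique():
            folds = ddct(table, gene, "Pp18S", "carcass")
            expected = truth[truth.gene == gene].set_index("sample").true_fold
            assert folds.loc[expected.index].to_numpy() == pytest.approx(
                expected.to_numpy(), rel=1e-9
            )
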