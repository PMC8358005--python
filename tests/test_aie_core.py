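"""Unit and property tests for the core AIE statistics.

Every statistical primitive is checked against an independent oracle:
exact binomial against full pmf enumeration, BH against a naive step-up
double loop, and the two-proportion z against statsmodels.
"""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from recipase import aie_core
from recipase.aie_core import (
    CAT_DECREASING,
    CAT_INCREASING,
    CAT_NONE,
    aggregate_by_subgroup,
    bh_fdr,
    call_differential_aie,
    call_subgroup_aie,
    exact_binomial_test,
    filter_sites,
    gene_level_aie,
    two_proportion_test,
)
from recipase.errors import UserInputError


# ---------------------------------------------------------------------------
# oracles
# ---------------------------------------------------------------------------

def binomial_minlike_oracle(k: int, n: int) -> float:
    """Two-sided exact binomial p at p0=0.5 by full pmf enumeration:
    sum of all outcome probabilities no more likely than the observed one."""
    pmf = [math.comb(n, i) for i in range(n + 1)]  # / 2^n, exact integers
    observed = pmf[k]
    total = sum(w for w in pmf if w <= observed)
    return total / 2**n


def bh_oracle(p):
    """Naive BH step-up by the textbook definition (double loop)."""
    p = list(p)
    m = len(p)
    order = sorted(range(m), key=lambda i: p[i])
    q = [0.0] * m
    for rank_pos in range(m):
        i = order[rank_pos]
        best = min(
            p[order[j]] * m / (j + 1) for j in range(rank_pos, m)
        )
        q[i] = min(1.0, best)
    return q


# ---------------------------------------------------------------------------
# exact binomial
# ---------------------------------------------------------------------------

class TestExactBinomial:
    def test_symmetric_is_one(self):
        assert exact_binomial_test(10, 10) == 1.0

    def test_fifteen_five(self):
        # enumeration: sum C(20,k)/2^20 over the two tails = 43400/1048576
        assert exact_binomial_test(15, 5) == pytest.approx(43400 / 1048576, rel=1e-12)

    def test_extreme(self):
        assert exact_binomial_test(20, 0) == pytest.approx(2 * 2**-20, rel=1e-12)

    def test_matches_enumeration_all_totals_to_30(self):
        for n in range(1, 31):
            for k in range(n + 1):
                expected = binomial_minlike_oracle(k, n)
                got = exact_binomial_test(k, n - k)
                assert got == pytest.approx(expected, rel=1e-9), (k, n)

    def test_matches_scipy_binomtest(self):
        for k, n in [(3, 40), (60, 100), (250, 513), (0, 7)]:
            expected = stats.binomtest(k, n, 0.5).pvalue
            assert exact_binomial_test(k, n - k) == pytest.approx(expected, rel=1e-9)

    def test_vectorized(self):
        p = exact_binomial_test(np.array([10, 15]), np.array([10, 5]))
        assert p[0] == 1.0
        assert p[1] == pytest.approx(43400 / 1048576)

    def test_zero_total_errors(self):
        with pytest.raises(UserInputError):
            exact_binomial_test(0, 0)


# ---------------------------------------------------------------------------
# BH FDR
# ---------------------------------------------------------------------------

class TestBhFdr:
    def test_single(self):
        assert bh_fdr([0.03]) == pytest.approx([0.03])

    def test_step_up_enumeration(self):
        q = bh_fdr([0.01, 0.02, 0.03, 0.04])
        assert q == pytest.approx([0.04, 0.04, 0.04, 0.04])

    def test_cap_at_one(self):
        assert bh_fdr([1.0, 1.0]) == pytest.approx([1.0, 1.0])

    def test_order_preserved(self):
        p = [0.04, 0.01, 0.5]
        q = bh_fdr(p)
        q_sorted_input = bh_fdr(sorted(p))
        assert sorted(q) == pytest.approx(list(q_sorted_input))
        # the q for p=0.01 sits at index 1
        assert q[1] == min(q)

    def test_against_brute_force_1000_vectors(self, rng):
        for _ in range(1000):
            m = int(rng.integers(1, 40))
            p = rng.uniform(1e-8, 1.0, m)
            np.testing.assert_allclose(bh_fdr(p), bh_oracle(p), rtol=1e-12)

    def test_rejects_out_of_range(self):
        with pytest.raises(UserInputError):
            bh_fdr([0.0, 0.5])
        with pytest.raises(UserInputError):
            bh_fdr([1.5])


# ---------------------------------------------------------------------------
# two-proportion test
# ---------------------------------------------------------------------------

class TestTwoProportion:
    def test_equal_proportions(self):
        z, p = two_proportion_test(50, 100, 50, 100)
        assert z == 0.0
        assert p == 1.0

    def test_eighty_vs_fifty(self):
        z, p = two_proportion_test(80, 100, 50, 100)
        expected_z = 0.3 / math.sqrt(0.65 * 0.35 * (1 / 100 + 1 / 100))
        assert z == pytest.approx(expected_z, rel=1e-12)
        assert p == pytest.approx(2 * stats.norm.sf(expected_z), rel=1e-12)
        assert p == pytest.approx(8.7e-6, rel=0.02)

    def test_extreme(self):
        _, p = two_proportion_test(100, 100, 0, 100)
        assert p < 1e-15

    def test_against_statsmodels(self, rng):
        from statsmodels.stats.proportion import proportions_ztest

        for _ in range(50):
            na, nb = rng.integers(5, 500, 2)
            ra = rng.integers(0, na + 1)
            rb = rng.integers(0, nb + 1)
            z, p = two_proportion_test(int(ra), int(na), int(rb), int(nb))
            z_sm, p_sm = proportions_ztest([ra, rb], [na, nb])
            if np.isnan(z_sm):  # pooled p-hat of 0 or 1: degenerate table
                assert p == 1.0
            else:
                assert z == pytest.approx(z_sm, rel=1e-9)
                assert p == pytest.approx(p_sm, rel=1e-9, abs=1e-300)

    def test_continuity_correction_is_more_conservative(self):
        _, p_plain = two_proportion_test(60, 100, 50, 100)
        _, p_cc = two_proportion_test(60, 100, 50, 100, continuity_correction=True)
        assert p_cc > p_plain

    def test_zero_total_errors(self):
        with pytest.raises(UserInputError):
            two_proportion_test(0, 0, 5, 10)


# ---------------------------------------------------------------------------
# aggregation and filtering
# ---------------------------------------------------------------------------

def _records(rows):
    return pd.DataFrame(
        rows, columns=["snp_id", "tissue", "subgroup", "ref_depth", "alt_depth"]
    )


class TestAggregate:
    def test_sums(self):
        rec = _records(
            [("s1", "t", "A", 10, 5), ("s1", "t", "A", 20, 15), ("s1", "t", "B", 1, 1)]
        )
        agg = aggregate_by_subgroup(rec)
        a = agg[agg["subgroup"] == "A"].iloc[0]
        assert (a["ref_depth_sum"], a["alt_depth_sum"]) == (30, 20)
        assert a["ref_frac"] == pytest.approx(0.6)

    def test_single_sample(self):
        agg = aggregate_by_subgroup(_records([("s1", "t", "A", 7, 3)]))
        assert agg.iloc[0]["ref_depth_sum"] == 7

    def test_missing_subgroup_emits_no_row(self):
        agg = aggregate_by_subgroup(_records([("s1", "t", "A", 7, 3)]))
        assert (agg["subgroup"] == "B").sum() == 0

    def test_mixed_tissues_error(self):
        rec = _records([("s1", "t1", "A", 1, 1), ("s1", "t2", "A", 1, 1)])
        with pytest.raises(UserInputError):
            aggregate_by_subgroup(rec)


class TestFilterSites:
    def test_boundary_kept(self):
        assert filter_sites(18, 2, 30, 30) is True

    def test_allele_minimum(self):
        assert filter_sites(19, 1, 30, 30) is False

    def test_total_minimum(self):
        assert filter_sites(10, 9, 30, 30) is False

    @settings(max_examples=200, deadline=None)
    @given(
        counts=st.tuples(*[st.integers(0, 60)] * 4),
        extra=st.tuples(*[st.integers(0, 20)] * 4),
    )
    def test_monotone_adding_reads(self, counts, extra):
        before = filter_sites(*counts)
        after = filter_sites(*(c + e for c, e in zip(counts, extra)))
        if before:
            assert after


# ---------------------------------------------------------------------------
# calling
# ---------------------------------------------------------------------------

def _agg(rows):
    df = pd.DataFrame(
        rows, columns=["snp_id", "tissue", "subgroup", "ref_depth_sum", "alt_depth_sum"]
    )
    total = df["ref_depth_sum"] + df["alt_depth_sum"]
    df["ref_frac"] = df["ref_depth_sum"] / total
    return df


class TestCallSubgroupAie:
    def test_balanced_not_called(self):
        calls = call_subgroup_aie(_agg([("s1", "t", "A", 50, 50)]))
        assert not calls.iloc[0]["is_aie"]

    def test_imbalanced_called(self):
        calls = call_subgroup_aie(_agg([("s1", "t", "A", 90, 10)]))
        assert calls.iloc[0]["is_aie"]
        assert calls.iloc[0]["p_binomial"] < 1e-10

    def test_fdr_within_family(self):
        rows = [(f"s{i}", "t", "A", 55, 45) for i in range(20)] + [
            ("hit", "t", "A", 95, 5)
        ]
        calls = call_subgroup_aie(_agg(rows))
        hit = calls[calls["snp_id"] == "hit"].iloc[0]
        assert hit["q_fdr"] == pytest.approx(hit["p_binomial"] * 21, rel=1e-9)

    def test_filter_applied(self):
        calls = call_subgroup_aie(_agg([("s1", "t", "A", 19, 0)]))
        assert calls.empty


class TestCallDifferentialAie:
    def test_increasing(self):
        agg = _agg([("s1", "t", "A", 80, 20), ("s1", "t", "B", 50, 50)])
        res = call_differential_aie(agg)
        row = res.iloc[0]
        assert row["category"] == CAT_INCREASING
        assert row["delta"] == pytest.approx(0.3)
        assert row["q_fdr"] < 0.05

    def test_small_delta_is_none(self):
        agg = _agg([("s1", "t", "A", 5200, 4800), ("s1", "t", "B", 4800, 5200)])
        res = call_differential_aie(agg)
        # highly significant but |delta| = 0.04 <= 0.1
        assert res.iloc[0]["p_value"] < 1e-6
        assert res.iloc[0]["category"] == CAT_NONE

    def test_strong_imprinting(self):
        agg = _agg([("s1", "t", "A", 950, 50), ("s1", "t", "B", 100, 900)])
        res = call_differential_aie(agg)
        row = res.iloc[0]
        assert row["delta"] == pytest.approx(0.85)
        assert row["category"] == CAT_INCREASING
        assert bool(row["strong_imprinting"]) is True

    def test_requires_both_subgroups_pass_filter(self):
        agg = _agg([("s1", "t", "A", 80, 20), ("s1", "t", "B", 10, 5)])
        assert call_differential_aie(agg).empty

    def test_delta_antisymmetry(self, small_sim):
        _, counts, _ = small_sim
        agg = aggregate_by_subgroup(counts)
        swapped = agg.copy()
        swapped["subgroup"] = swapped["subgroup"].map({"A": "B", "B": "A"})
        res = call_differential_aie(agg).set_index("snp_id")
        res_sw = call_differential_aie(swapped).set_index("snp_id")
        assert set(res.index) == set(res_sw.index)
        np.testing.assert_allclose(
            res["delta"].to_numpy(), -res_sw.loc[res.index, "delta"].to_numpy(), atol=1e-12
        )
        flip = {CAT_INCREASING: CAT_DECREASING, CAT_DECREASING: CAT_INCREASING, CAT_NONE: CAT_NONE}
        assert (res["category"].map(flip) == res_sw.loc[res.index, "category"]).all()


class TestGeneLevelAie:
    def _diff(self, rows):
        return pd.DataFrame(
            rows,
            columns=["snp_id", "tissue", "delta", "q_fdr", "category"],
        ).assign(
            ref_frac_a=0.5, ref_frac_b=0.5, z_stat=0.0, p_value=0.5, strong_imprinting=False
        )

    def _assign(self, pairs):
        return pd.DataFrame(pairs, columns=["snp_id", "gene_id"]).assign(distance=0)

    def test_single_qualifying_snp(self):
        diff = self._diff([("s1", "t", -0.2, 0.01, CAT_DECREASING)])
        verdict = gene_level_aie(diff, self._assign([("s1", "g1")]))
        assert verdict.iloc[0]["category"] == CAT_DECREASING
        assert verdict.iloc[0]["best_snp_id"] == "s1"

    def test_min_q_wins(self):
        diff = self._diff(
            [
                ("s1", "t", -0.2, 0.01, CAT_DECREASING),
                ("s2", "t", 0.15, 0.001, CAT_INCREASING),
            ]
        )
        verdict = gene_level_aie(diff, self._assign([("s1", "g1"), ("s2", "g1")]))
        assert verdict.iloc[0]["category"] == CAT_INCREASING

    def test_abs_delta_tiebreak(self):
        diff = self._diff(
            [
                ("s1", "t", -0.3, 0.01, CAT_DECREASING),
                ("s2", "t", 0.15, 0.01, CAT_INCREASING),
            ]
        )
        verdict = gene_level_aie(diff, self._assign([("s1", "g1"), ("s2", "g1")]))
        assert verdict.iloc[0]["category"] == CAT_DECREASING

    def test_all_none_stays_none(self):
        diff = self._diff([("s1", "t", 0.05, 0.9, CAT_NONE)])
        verdict = gene_level_aie(diff, self._assign([("s1", "g1")]))
        assert verdict.iloc[0]["category"] == CAT_NONE


# ---------------------------------------------------------------------------
# simulation-based error control / recovery (small versions; the full-size
# versions live in test_acceptance.py)
# ---------------------------------------------------------------------------

def test_null_false_positive_control_small():
    from recipase import synthetic_data as sd

    config = sd.SimulationConfig(
        n_genes=150,
        snps_per_gene_mean=3.0,
        seed=7,
        frac_imprinted_paternal=0.0,
        frac_imprinted_maternal=0.0,
        frac_cis_effect=0.0,
    )
    counts, _ = sd.simulate_allele_counts(config)
    res = call_differential_aie(aggregate_by_subgroup(counts))
    assert len(res) > 200
    frac_called = (res["category"] != CAT_NONE).mean()
    assert frac_called <= 0.06
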