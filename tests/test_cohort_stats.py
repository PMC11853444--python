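"""Paired VAF construction, rank tests with enumeration oracles, survival times."""

import itertools

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats as sps

from cfmrd.cohort_stats import (
    build_paired_vafs,
    kruskal_wallis,
    median_range,
    survival_times,
    wilcoxon_matched_pairs,
    wilcoxon_signed_rank,
)
from cfmrd.errors import DataError, NotEvaluable
from cfmrd.variant_io import PRE, SubjectRecord, VariantCall


def _call(comp, gene, vaf, sid="002", day=PRE, key=None):
    return VariantCall(sid, day, comp, gene, key or gene, vaf)


class TestPairedVafs:
    def test_matched_pairs_no_zero_fill(self):
        bm = [_call("BM", "TP53", 48.34), _call("BM", "HNF1A", 24.54)]
        pl = [_call("plasma", "TP53", 63.57), _call("plasma", "HNF1A", 28.71)]
        pairs = build_paired_vafs(bm, pl)
        assert len(pairs) == 2
        assert all(p.vaf_bm > 0 and p.vaf_plasma > 0 for p in pairs)

    def test_missing_compartment_zero_filled(self):
        bm = [_call("BM", "BCOR", 13.85, sid="003"), _call("BM", "KMT2D", 8.8, sid="003")]
        pairs = build_paired_vafs(bm, [])
        assert len(pairs) == 2
        assert all(p.vaf_plasma == 0.0 for p in pairs)

    def test_both_empty(self):
        assert build_paired_vafs([], []) == []

    def test_duplicate_key_within_compartment_rejected(self):
        bm = [_call("BM", "TP53", 5.0), _call("BM", "TP53", 6.0)]
        with pytest.raises(DataError, match="duplicate"):
            build_paired_vafs(bm, [])

    def test_swapping_compartments_transposes_pairs(self):
        bm = [_call("BM", "TP53", 5.0), _call("BM", "WT1", 2.0)]
        pl = [_call("plasma", "TP53", 7.0)]
        fwd = build_paired_vafs(bm, pl)
        bm2 = [_call("BM", c.gene, c.vaf, key=c.variant_key) for c in pl]
        pl2 = [_call("plasma", c.gene, c.vaf, key=c.variant_key) for c in bm]
        rev = build_paired_vafs(bm2, pl2)
        assert {(p.gene, p.vaf_bm, p.vaf_plasma) for p in fwd} == {
            (p.gene, p.vaf_plasma, p.vaf_bm) for p in rev
        }


def _enumeration_p(diffs):
    """Brute-force two-sided exact p over all 2^n sign assignments."""
    d = np.asarray(diffs, float)
    d = d[d != 0]
    n = len(d)
    ranks = sps.rankdata(np.abs(d))
    w_obs = min(ranks[d > 0].sum(), ranks[d < 0].sum())
    total = ranks.sum()
    count = 0
    for signs in itertools.product((0, 1), repeat=n):
        w_plus = sum(r for r, s in zip(ranks, signs) if s)
        if w_plus <= w_obs or w_plus >= total - w_obs:
            count += 1
    return count / 2**n


class TestWilcoxon:
    def test_all_zero_differences_not_evaluable(self):
        with pytest.raises(NotEvaluable):
            wilcoxon_signed_rank([1, 2, 3], [1, 2, 3])

    def test_toy_doubling_pairs_match_enumeration(self):
        x, y = [1, 2, 3, 4, 5], [2, 4, 6, 8, 10]
        res = wilcoxon_signed_rank(x, y)
        assert res.method == "exact"
        assert res.statistic == 0.0  # every plasma value exceeds its pair
        assert res.p_value == pytest.approx(_enumeration_p(np.subtract(x, y)))
        assert res.p_value == pytest.approx(2 / 32)

    def test_column_swap_symmetry(self):
        rng = np.random.default_rng(2)
        x, y = rng.normal(size=8), rng.normal(size=8)
        a, b = wilcoxon_signed_rank(x, y), wilcoxon_signed_rank(y, x)
        assert a.statistic == b.statistic and a.p_value == pytest.approx(b.p_value)

    @given(
        diffs=st.lists(
            st.integers(-20, 20).filter(lambda v: v != 0), min_size=3, max_size=10
        )
    )
    def test_exact_p_equals_sign_enumeration(self, diffs):
        """The DP-based exact distribution agrees with enumerating all 2^n
        sign assignments, including tied absolute differences."""
        res = wilcoxon_signed_rank(diffs, [0] * len(diffs))
        assert res.method == "exact"
        assert res.p_value == pytest.approx(_enumeration_p(diffs), abs=1e-12)

    def test_matches_scipy_exact_without_ties(self):
        rng = np.random.default_rng(7)
        for _ in range(10):
            d = rng.normal(size=12)  # continuous draws: no ties, no zeros
            ours = wilcoxon_signed_rank(d, np.zeros_like(d))
            ref = sps.wilcoxon(d, zero_method="wilcox", method="exact")
            assert ours.p_value == pytest.approx(ref.pvalue, abs=1e-12)

    def test_large_n_uses_normal_approximation(self):
        rng = np.random.default_rng(9)
        d = rng.normal(0.3, 1.0, size=60)
        res = wilcoxon_signed_rank(d, np.zeros_like(d))
        assert res.method == "normal"
        ref = sps.wilcoxon(d, zero_method="wilcox", correction=True, method="approx")
        assert res.p_value == pytest.approx(ref.pvalue)

    def test_paired_record_interface(self):
        bm = [_call("BM", g, v) for g, v in [("A", 5), ("B", 3), ("C", 8), ("D", 2), ("E", 9)]]
        pl = [_call("plasma", g, v) for g, v in [("A", 1), ("B", 2), ("C", 3), ("D", 1), ("E", 4)]]
        res = wilcoxon_matched_pairs(build_paired_vafs(bm, pl))
        assert res.n_used == 5 and res.p_value <= 0.1


class TestKruskalWallis:
    def test_identical_groups_give_zero_h(self):
        res = kruskal_wallis([[3, 3, 3], [3, 3]])
        assert res.statistic == 0.0 and res.p_value == 1.0

    def test_matches_rank_sum_arithmetic(self):
        groups = [[1, 2, 3], [4, 5, 6]]
        res = kruskal_wallis(groups)
        # direct rank formula without ties: H = 12/(N(N+1)) * sum n_i (rbar_i - rbar)^2
        h = 12 / (6 * 7) * (3 * (2 - 3.5) ** 2 + 3 * (5 - 3.5) ** 2)
        assert res.statistic == pytest.approx(h)
        assert res.df == 1

    @given(
        a=st.lists(st.integers(0, 30), min_size=2, max_size=8),
        b=st.lists(st.integers(0, 30), min_size=2, max_size=8),
    )
    def test_invariant_under_monotone_transform(self, a, b):
        base = kruskal_wallis([a, b])
        transformed = kruskal_wallis([[3 * v**3 + 7 for v in a], [3 * v**3 + 7 for v in b]])
        assert transformed.statistic == pytest.approx(base.statistic, abs=1e-9)

    def test_fixture_plasma_detects_more_pretransplant_mutations(self, paper):
        """Direction of effect only: pre-transplant cfDNA carries more
        detectable mutations (and lower VAFs) than marrow in this cohort."""
        bm = [c for c in paper.variants if c.day == PRE and c.compartment == "BM"]
        pl = [c for c in paper.variants if c.day == PRE and c.compartment == "plasma"]
        counts_bm = [sum(c.subject_id == s.subject_id for c in bm) for s in paper.subjects]
        counts_pl = [sum(c.subject_id == s.subject_id for c in pl) for s in paper.subjects]
        assert sum(counts_pl) > sum(counts_bm)
        assert np.median([c.vaf for c in bm]) > np.median([c.vaf for c in pl])


class TestMedianAndSurvival:
    def test_relapse_days_median_and_range(self):
        assert median_range([170, 62, 168, 52, 167, 139]) == (153.0, 52, 170)

    @pytest.mark.parametrize(
        "values,expected",
        [([7], (7.0, 7, 7)), ([1, 2, 3, 4], (2.5, 1, 4))],
    )
    def test_median_small_cases(self, values, expected):
        assert median_range(values) == expected

    @given(values=st.lists(st.floats(-100, 100), min_size=1, max_size=20))
    def test_median_permutation_invariant(self, values):
        assert median_range(values) == median_range(list(reversed(values)))

    def test_empty_not_evaluable(self):
        with pytest.raises(NotEvaluable):
            median_range([])

    def test_relapse_then_death(self):
        s = SubjectRecord("010", relapse_day=52, death_day=125, last_followup_day=125)
        t = survival_times(s)
        assert (t.rfs_days, t.event_rfs, t.os_days, t.event_os) == (52, True, 125, True)

    def test_alive_without_relapse_censored(self):
        t = survival_times(SubjectRecord("X", last_followup_day=365))
        assert (t.rfs_days, t.event_rfs, t.os_days, t.event_os) == (365, False, 365, False)

    def test_death_without_relapse(self):
        t = survival_times(SubjectRecord("001", death_day=59, last_followup_day=59))
        assert t.rfs_days == t.os_days == 59
        assert t.event_rfs and t.event_os

    def test_relapse_after_death_is_data_error(self):
        s = SubjectRecord("X", relapse_day=200, death_day=100, last_followup_day=100)
        with pytest.raises(DataError):
            survival_times(s)
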