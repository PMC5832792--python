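"""Sharing classification, CNV/integration matching and the
independent-origin Poisson test."""

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy import stats

from hchc_clonality import (
    CnvSegment,
    IntegrationSite,
    classify_sharing,
    common_cnvs,
    independent_origin_test,
    origin_test_mc_oracle,
    shared_integrations,
)

from conftest import make_pair


def k(i):  # distinct variant keys
    return ("1", 100 + i, "C", "T")


class TestClassifySharing:
    def test_set_arithmetic_example(self):
        pair = make_pair([k(1), k(2), k(3)], [k(2), k(3), k(4)])
        s = classify_sharing(pair)
        assert (s.n_ubiquitous, s.n_private_a, s.n_private_b) == (2, 1, 1)
        assert s.private_fraction == 0.5
        assert sorted(s.labels.values()).count("ubiquitous") == 2

    def test_min_alt_threshold_gates_presence(self):
        pair = make_pair([k(1)], [k(1)], alt_count=2)  # below min_alt=3
        s = classify_sharing(pair)
        assert (s.n_ubiquitous, s.n_private_a, s.n_private_b) == (0, 0, 0)
        s2 = classify_sharing(pair, min_alt=2)
        assert s2.n_ubiquitous == 1

    def test_effect_filter_defaults_to_nonsynonymous(self):
        pair = make_pair([k(1)], [k(1)], effect="silent")
        assert classify_sharing(pair).n_ubiquitous == 0
        assert classify_sharing(pair, effect_filter=None).n_ubiquitous == 1

    def test_empty_components_give_zero_summary_not_error(self):
        pair = make_pair([], [])
        s = classify_sharing(pair)
        assert (s.n_ubiquitous, s.n_private_a, s.n_private_b) == (0, 0, 0)
        assert s.private_fraction == 0.0

    @given(
        ia=st.sets(st.integers(0, 40), max_size=25),
        ib=st.sets(st.integers(0, 40), max_size=25),
    )
    def test_partition_and_symmetry_properties(self, ia, ib):
        pair = make_pair([k(i) for i in ia], [k(i) for i in ib])
        s = classify_sharing(pair)
        # labels partition the key union exactly
        assert s.n_ubiquitous + s.n_private_a + s.n_private_b == len(ia | ib)
        assert len(s.labels) == len(ia | ib)
        # swapping components swaps the private counts
        swapped = make_pair([k(i) for i in ib], [k(i) for i in ia])
        s2 = classify_sharing(swapped)
        assert (s2.n_private_a, s2.n_private_b) == (s.n_private_b, s.n_private_a)
        assert s2.n_ubiquitous == s.n_ubiquitous
        assert s2.private_fraction == pytest.approx(s.private_fraction)


def seg(sample, chrom, start, end, state="gain", cn=3):
    if state == "loss":
        cn = 1
    return CnvSegment(sample_id=sample, chrom=chrom, start=start, end=end, state=state, total_cn=cn)


class TestCommonCnvs:
    def test_identical_intervals_match(self):
        s = common_cnvs([seg("A", "1", 0, 1000)], [seg("B", "1", 0, 1000)])
        assert s.n_common == 1 and s.n_private_a == 0 and s.n_private_b == 0

    def test_one_bp_difference_fails_the_strict_rule(self):
        s = common_cnvs([seg("A", "1", 0, 1000)], [seg("B", "1", 0, 999)])
        assert s.n_common == 0 and s.n_private_a == 1 and s.n_private_b == 1

    def test_direction_must_agree(self):
        s = common_cnvs([seg("A", "1", 0, 1000, "gain")], [seg("B", "1", 0, 1000, "loss")])
        assert s.n_common == 0

    def test_relaxed_reciprocal_overlap(self):
        s = common_cnvs(
            [seg("A", "1", 0, 1000)], [seg("B", "1", 0, 900)], min_reciprocal_overlap=0.8
        )
        assert s.n_common == 1

    def test_each_segment_used_at_most_once(self):
        a = [seg("A", "1", 0, 1000)]
        b = [seg("B", "1", 0, 1000), seg("B", "1", 2000, 3000)]
        s = common_cnvs(a, b)
        assert s.n_common == 1 and s.n_private_b == 1

    def test_overlapping_segments_within_sample_error(self):
        with pytest.raises(ValueError, match="overlapping CNV segments"):
            common_cnvs([seg("A", "1", 0, 1000), seg("A", "1", 500, 1500)], [])


class TestSharedIntegrations:
    def test_identical_site_matches(self):
        a = [IntegrationSite("A", "15", 4000)]
        b = [IntegrationSite("B", "15", 4000)]
        assert len(shared_integrations(a, b)) == 1

    def test_tolerance_boundary(self):
        a = [IntegrationSite("A", "1", 1000)]
        assert len(shared_integrations(a, [IntegrationSite("B", "1", 1500)], 500)) == 1
        assert len(shared_integrations(a, [IntegrationSite("B", "1", 1600)], 500)) == 0

    def test_greedy_nearest_one_to_one(self):
        a = [IntegrationSite("A", "1", 1000), IntegrationSite("A", "1", 1200)]
        b = [IntegrationSite("B", "1", 1010)]
        matches = shared_integrations(a, b)
        assert len(matches) == 1 and matches[0][0].pos == 1000

    def test_single_shared_site_cohort_pattern(self):
        # one shared site on chrom 15, none elsewhere
        a = [IntegrationSite("A", "15", 4_000_000), IntegrationSite("A", "3", 99)]
        b = [IntegrationSite("B", "15", 4_000_120), IntegrationSite("B", "7", 1234)]
        matches = shared_integrations(a, b)
        assert len(matches) == 1 and matches[0][0].chrom == "15"


class TestIndependentOriginTest:
    def test_zero_observed_is_certain_and_supports_independence(self):
        r = independent_origin_test(200, 200, 0, 30_000_000)
        assert r.p_value == 1.0
        assert r.verdict_support == "supports_independent"
        assert r.expected_shared == pytest.approx(200 * 200 / 3e7)

    def test_cohort_minimum_ubiquitous_count_is_astronomically_unlikely(self):
        """29 shared mutations (the smallest ubiquitous count in a real
        two-component cohort) against lambda ~ 0.0013."""
        r = independent_origin_test(200, 200, 29, 30_000_000)
        assert r.p_value < 1e-60
        assert r.verdict_support == "supports_monoclonal"

    def test_impossible_overlap_errors(self):
        with pytest.raises(ValueError, match="impossible overlap"):
            independent_origin_test(10, 5, 6, 1000)

    def test_monotone_in_observed_shared(self):
        ps = [
            independent_origin_test(300, 300, obs, 100_000).p_value for obs in range(0, 8)
        ]
        assert all(p1 >= p2 for p1, p2 in zip(ps, ps[1:]))

    def test_matches_poisson_tail(self):
        r = independent_origin_test(1000, 1000, 3, 1_000_000)
        assert r.p_value == pytest.approx(float(stats.poisson.sf(2, 1.0)))

    @pytest.mark.parametrize(
        "n_a,n_b,L,obs",
        [(1000, 1000, 10_000_000, 1), (1000, 1000, 1_000_000, 3), (1000, 1000, 200_000, 10)],
    )
    def test_agrees_with_monte_carlo_collision_oracle(self, n_a, n_b, L, obs):
        """lambda in {0.1, 1, 5}: analytic tail within factor 2 of simulation."""
        p = independent_origin_test(n_a, n_b, obs, L).p_value
        p_mc = origin_test_mc_oracle(n_a, n_b, obs, L, n_draws=20_000, seed=17)
        assert p_mc > 0
        assert 0.5 < p / p_mc < 2.0
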