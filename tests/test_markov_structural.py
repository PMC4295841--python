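import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import binom

from multisyn.markov_structural import (
    StructuralParams,
    SynapseDistribution,
    build_transition_matrix,
    classify_case,
    continuous_fixed_points,
    delta_ln_p,
    deletion_prob,
    equilibrium_distribution,
    first_step_distribution,
    fixed_point_diagram,
    pcf_pd_curves,
    pdel_profile,
    stationary_from_matrix,
)
from multisyn.neuron_core import FeedbackSpec, SystemPoint, activity_profile
from multisyn.rate_rules import RuleSpec


def enumeration_matrix(P, pdel_by_S, p_build):
    """Independent oracle: enumerate every per-site outcome path.

    From state l, each of the l occupied sites is deleted or not, and each of
    the P - l initially vacant sites gains a synapse or not; all 2^P paths
    are enumerated with their product probabilities.
    """
    M = np.zeros((P + 1, P + 1))
    for l in range(P + 1):
        pd = pdel_by_S[l]
        for dels in itertools.product([0, 1], repeat=l):
            p_d = np.prod([pd if d else 1 - pd for d in dels]) if l else 1.0
            for builds in itertools.product([0, 1], repeat=P - l):
                p_b = np.prod([p_build if b else 1 - p_build for b in builds]) if P - l else 1.0
                k = l - sum(dels) + sum(builds)
                M[k, l] += p_d * p_b
    return M


class TestDeletionProb:
    def test_zero_weight_is_power_of_build_probability(self):
        sp = StructuralParams(p_build=0.2, rho=0.5, a=1.3, P=4)
        assert deletion_prob(sp, 0.0) == pytest.approx(0.2**0.5, rel=1e-14)

    def test_monotone_decreasing(self):
        sp = StructuralParams(p_build=0.2, rho=0.5, a=1.3, P=4)
        assert deletion_prob(sp, 1.0) < deletion_prob(sp, 0.5) < deletion_prob(sp, 0.0)

    def test_weight_insensitive_when_a_zero(self):
        sp = StructuralParams(p_build=0.2, rho=0.5, a=0.0, P=4)
        assert deletion_prob(sp, 3.0) == deletion_prob(sp, 0.0)

    def test_alternative_exponent(self):
        sp = StructuralParams(p_build=0.2, rho=0.5, a=1.0, P=4, q=2.0)
        assert deletion_prob(sp, 2.0) == pytest.approx(0.2**0.5 * math.exp(-4.0), rel=1e-14)

    def test_rejects_negative_weight(self):
        sp = StructuralParams(p_build=0.2, rho=0.5, a=1.0, P=4)
        with pytest.raises(ValueError):
            deletion_prob(sp, -0.1)

    def test_rate_scale_clips_at_one(self):
        sp = StructuralParams(p_build=0.2, rho=0.5, a=0.0, P=4, rate_scale=100.0)
        assert deletion_prob(sp, 0.0) == 1.0
        assert sp.p_build_eff == 1.0


class TestTransitionMatrix:
    def test_P1_enumeration(self):
        sp = StructuralParams(p_build=0.3, rho=1.0, a=0.5, P=1)
        pdel = np.array([0.4, 0.25])
        tm = build_transition_matrix(sp, pdel)
        oracle = enumeration_matrix(1, pdel, 0.3)
        np.testing.assert_allclose(tm.M, oracle, atol=1e-14)

    @pytest.mark.parametrize("P", [2, 3])
    def test_enumeration_oracle(self, P, rng):
        sp = StructuralParams(p_build=float(rng.uniform(0.05, 0.6)), rho=1.0, a=0.5, P=P)
        pdel = rng.uniform(0.05, 0.9, size=P + 1)
        tm = build_transition_matrix(sp, pdel)
        oracle = enumeration_matrix(P, pdel, sp.p_build)
        np.testing.assert_allclose(tm.M, oracle, atol=1e-13)

    def test_vanishing_build_probability_leaves_no_mass_above(self):
        sp = StructuralParams(p_build=1e-15, rho=1.0, a=0.0, P=4)
        pdel = np.full(5, 0.3)
        tm = build_transition_matrix(sp, pdel)
        for l in range(5):
            assert tm.M[l + 1:, l].sum() < 1e-13

    def test_monte_carlo_one_step(self, rng):
        # simulation oracle: 1e6 direct draws of (removals, builds) from state l
        P = 3
        sp = StructuralParams(p_build=0.2, rho=1.0, a=0.5, P=P)
        pdel = np.array([0.5, 0.35, 0.2, 0.1])
        tm = build_transition_matrix(sp, pdel)
        n = 1_000_000
        for l in (0, 2, 3):
            d = rng.binomial(l, pdel[l], size=n) if l else np.zeros(n, dtype=int)
            b = rng.binomial(P - l, sp.p_build, size=n) if P - l else np.zeros(n, dtype=int)
            k = l - d + b
            freq = np.bincount(k, minlength=P + 1) / n
            se = np.sqrt(tm.M[:, l] * (1 - tm.M[:, l]) / n)
            assert np.all(np.abs(freq - tm.M[:, l]) < 3 * se + 1e-4)

    def test_columns_stochastic(self, paper_sp, paper_pdel):
        tm = build_transition_matrix(paper_sp, paper_pdel)
        np.testing.assert_allclose(tm.M.sum(axis=0), 1.0, atol=1e-12)
        assert np.all(tm.M > 0)  # strictly positive chain

    def test_dimension_mismatch(self, paper_sp):
        with pytest.raises(ValueError):
            build_transition_matrix(paper_sp, np.full(3, 0.5))


class TestStationary:
    def test_symmetric_two_state_uniform(self):
        sp = StructuralParams(p_build=0.3, rho=1.0, a=0.0, P=1)
        tm = build_transition_matrix(sp, np.array([0.3, 0.3]))
        stat = stationary_from_matrix(tm)
        np.testing.assert_allclose(stat.p, [0.5, 0.5], atol=1e-12)

    def test_fixed_point_residual(self, paper_sp, paper_pdel):
        tm = build_transition_matrix(paper_sp, paper_pdel)
        stat = stationary_from_matrix(tm)
        assert np.max(np.abs(tm.M @ stat.p - stat.p)) < 1e-10

    def test_long_simulation_histogram(self, rng):
        # 1e6-step chain sampled directly from the matrix columns
        sp = StructuralParams(p_build=0.15, rho=0.6, a=0.8, P=4)
        pdel = deletion_prob(sp, np.array([0.0, 0.4, 0.8, 1.2, 1.6]))
        tm = build_transition_matrix(sp, pdel)
        stat = stationary_from_matrix(tm)
        counts = np.zeros(5)
        S = 0
        cum = np.cumsum(tm.M, axis=0)
        us = rng.random(200_000)
        for u in us:
            S = int(np.searchsorted(cum[:, S], u))
            counts[S] += 1
        emp = SynapseDistribution(p=counts / counts.sum())
        assert emp.tv_distance(stat) < 0.01


class TestFirstStep:
    def test_constant_pdel_equals_binomial(self):
        # pdel == p_build -> Binomial(P, 1/2); P = 2 gives (1/4, 1/2, 1/4)
        sp = StructuralParams(p_build=0.3, rho=1.0, a=0.0, P=2)
        dist = first_step_distribution(sp, np.full(3, 0.3))
        np.testing.assert_allclose(dist.p, [0.25, 0.5, 0.25], atol=1e-14)

    def test_P1_ratio_two(self):
        sp = StructuralParams(p_build=0.4, rho=1.0, a=0.0, P=1)
        dist = first_step_distribution(sp, np.array([0.2, 0.2]))
        np.testing.assert_allclose(dist.p, [1 / 3, 2 / 3], atol=1e-14)

    @pytest.mark.parametrize("P", range(1, 21))
    def test_weight_independent_closed_form(self, P):
        sp = StructuralParams(p_build=0.12, rho=0.8, a=0.0, P=P)
        pdel = np.full(P + 1, deletion_prob(sp, 0.0))
        dist = first_step_distribution(sp, pdel)
        expected = binom.pmf(np.arange(P + 1), P, sp.p_build / (sp.p_build + pdel[0]))
        np.testing.assert_allclose(dist.p, expected, rtol=1e-12, atol=1e-300)

    def test_detailed_balance_identity(self, paper_sp, paper_pdel):
        dist = first_step_distribution(paper_sp, paper_pdel)
        P = paper_sp.P
        for S in range(1, P + 1):
            lhs = dist.log_p[S - 1] + math.log((P - S + 1) * paper_sp.p_build)
            rhs = dist.log_p[S] + math.log(S * paper_pdel[S])
            assert lhs == pytest.approx(rhs, abs=1e-12)

    @given(
        P=st.integers(min_value=1, max_value=15),
        seed=st.integers(min_value=0, max_value=2**31),
    )
    @settings(max_examples=60, deadline=None)
    def test_detailed_balance_property(self, P, seed):
        r = np.random.default_rng(seed)
        sp = StructuralParams(p_build=float(r.uniform(1e-7, 0.9)), rho=1.0, a=0.0, P=P)
        pdel = r.uniform(1e-6, 1.0, size=P + 1)
        dist = first_step_distribution(sp, pdel)
        for S in range(1, P + 1):
            lhs = dist.log_p[S - 1] + math.log((P - S + 1) * sp.p_build)
            rhs = dist.log_p[S] + math.log(S * pdel[S])
            assert lhs == pytest.approx(rhs, abs=1e-10)

    def test_matches_matrix_at_working_point(self, paper_sp, paper_pdel):
        first = first_step_distribution(paper_sp, paper_pdel)
        stat = stationary_from_matrix(build_transition_matrix(paper_sp, paper_pdel))
        assert first.tv_distance(stat) < 0.05

    def test_matrix_agreement_across_parameter_neighbourhood(self, io, paper_rule):
        # birth-death approximation vs exact chain on a 20-point random sweep
        # around the published parameter set
        rng = np.random.default_rng(21)
        for _ in range(20):
            sp = StructuralParams.from_log_build(
                float(rng.uniform(-17.0, -15.0)),
                rho=float(rng.uniform(0.1, 0.15)),
                a=float(rng.uniform(1.8, 2.2)),
                P=12,
            )
            pt = SystemPoint.from_baseline(
                v_j=float(rng.uniform(0.6, 0.72)),
                v_i_S0=float(rng.uniform(0.25, 0.35)),
            )
            prof = activity_profile(sp.P, pt, paper_rule, io)
            pdel = pdel_profile(sp, prof)
            first = first_step_distribution(sp, pdel)
            stat = stationary_from_matrix(build_transition_matrix(sp, pdel))
            assert first.tv_distance(stat) < 0.05

    def test_extreme_underflow_handled(self):
        # entries spanning hundreds of orders of magnitude stay normalized
        sp = StructuralParams(p_build=math.exp(-16), rho=2.0, a=0.0, P=20)
        dist = first_step_distribution(sp, np.full(21, deletion_prob(sp, 0.0)))
        assert abs(dist.p.sum() - 1.0) < 1e-12


class TestDeltaLnP:
    def test_consistency_with_first_step(self, paper_sp, paper_pdel):
        delta = delta_ln_p(paper_sp, paper_pdel)
        dist = first_step_distribution(paper_sp, paper_pdel)
        np.testing.assert_allclose(np.diff(dist.log_p), delta, atol=1e-12)

    def test_combinatorial_sign_flip(self):
        # constant pdel = p_build: delta = ln((P-S+1)/S), positive below the
        # midpoint and negative above it
        P = 7
        sp = StructuralParams(p_build=0.3, rho=1.0, a=0.0, P=P)
        delta = delta_ln_p(sp, np.full(P + 1, 0.3))
        S = np.arange(1, P + 1)
        assert np.all((delta > 0) == (S < (P + 1) / 2))

    def test_working_point_sign_pattern(self, paper_sp, paper_pdel):
        delta = delta_ln_p(paper_sp, paper_pdel)
        assert delta[0] < 0  # deletion wins at one synapse
        assert np.any(delta[1:] > 0)  # growth region
        assert delta[-1] < 0  # combinatorics win near P


class TestClassifyCase:
    @pytest.mark.parametrize(
        "delta,case,maxima",
        [
            ([1.0, 1.0, 1.0], 1, (3,)),
            ([-1.0, -1.0, -1.0], 2, (0,)),
            ([1.0, 1.0, -1.0], 3, None),
            ([-1.0, 1.0, 1.0], 4, (0, 3)),
            ([1.0, -1.0, 1.0], 5, None),
            ([-1.0, 1.0, -1.0], 6, None),
        ],
    )
    def test_table_patterns(self, delta, case, maxima):
        res = classify_case(np.array(delta))
        assert res.case == case
        if maxima is not None:
            assert res.maxima == maxima

    def test_case6_max_at_second_crossing(self):
        res = classify_case(np.array([-2.0, 1.0, 0.5, -1.0, -1.0]))
        assert res.case == 6
        assert res.maxima == (0, 3)

    def test_tie_counts_as_crossing(self):
        res = classify_case(np.array([-1.0, 0.0, 1.0, -1.0]))
        assert res.case == 6

    def test_degenerate_all_zero(self):
        res = classify_case(np.zeros(4))
        assert res.degenerate

    def test_extrema_match_distribution_on_random_profiles(self, rng):
        # internal consistency on 1000 random deletion vectors: the classified
        # maxima must be the local maxima (boundaries included) of the
        # reconstructed distribution
        P = 9
        for _ in range(1000):
            sp = StructuralParams(p_build=float(rng.uniform(0.01, 0.9)), rho=1.0, a=0.0, P=P)
            pdel = rng.uniform(0.01, 1.0, size=P + 1)
            delta = delta_ln_p(sp, pdel)
            if np.any(delta == 0.0):
                continue
            res = classify_case(delta)
            if res.case not in (1, 2, 3, 4, 5, 6):
                continue
            p = first_step_distribution(sp, pdel).log_p
            local_max = [
                S for S in range(P + 1)
                if (S == 0 or p[S] > p[S - 1]) and (S == P or p[S] > p[S + 1])
            ]
            assert list(res.maxima) == local_max


class TestPcfPd:
    def test_pcf_increasing(self, paper_sp, paper_profile, paper_rule):
        fb = FeedbackSpec.feedforward(0.656)
        p_cf, _ = pcf_pd_curves(paper_sp, paper_profile, paper_rule, fb)
        v = np.linspace(paper_profile.v_i[1], paper_profile.v_i[-1] - 1e-9, 50)
        assert np.all(np.diff(p_cf(v)) > 0)

    def test_intersections_match_delta_crossings(self, paper_sp, paper_profile, paper_rule, paper_pdel):
        fb = FeedbackSpec.feedforward(0.656)
        p_cf, p_d = pcf_pd_curves(paper_sp, paper_profile, paper_rule, fb)
        delta = delta_ln_p(paper_sp, paper_pdel)
        # delta[S-1] = p_d - p_cf evaluated at the discrete state S
        for S in range(1, paper_sp.P + 1):
            v = paper_profile.v_i[S]
            assert p_d(v) - p_cf(v) == pytest.approx(delta[S - 1], abs=1e-9)

    def test_constant_weight_rule_single_intersection(self, io):
        # constant w* -> constant p_d -> at most one crossing (cases 1-4)
        sp = StructuralParams(p_build=0.001, rho=1.2, a=1.0, P=8)
        rule = RuleSpec(kind="hebb_hard", w_max=1.2)
        pt = SystemPoint.from_baseline(v_j=0.5, v_i_S0=0.3)
        dist = equilibrium_distribution(sp, rule, io, pt)
        delta = np.diff(dist.log_p)
        res = classify_case(delta)
        assert res.case in (1, 2, 3, 4)


class TestContinuousFixedPoints:
    def test_low_stimulation_single_attractor_at_zero(self, paper_sp, paper_rule, io):
        pt = SystemPoint.from_baseline(v_j=0.2, v_i_S0=0.05)
        branches = continuous_fixed_points(paper_sp, paper_rule, io, pt)
        stable = [b for b in branches if b.stable]
        assert len(stable) == 1
        assert stable[0].S < 0.5

    def test_working_point_bistable(self, paper_sp, paper_rule, io, working_point):
        branches = continuous_fixed_points(paper_sp, paper_rule, io, working_point)
        stable = [b for b in branches if b.stable]
        unstable = [b for b in branches if not b.stable]
        assert len(stable) == 2
        assert len(unstable) == 1
        assert stable[0].S < unstable[0].S < stable[1].S
        assert 3 <= stable[1].S <= 8  # upper attractor at the observed peak

    def test_high_stimulation_upper_attractor_only(self, paper_sp, paper_rule, io):
        pt = SystemPoint.from_baseline(v_j=0.656, v_i_S0=0.9)
        branches = continuous_fixed_points(paper_sp, paper_rule, io, pt)
        stable = [b for b in branches if b.stable]
        assert len(stable) == 1
        assert stable[0].S > 2

    def test_stability_labels_alternate(self, paper_sp, paper_rule, io, working_point):
        branches = continuous_fixed_points(paper_sp, paper_rule, io, working_point)
        labels = [b.stable for b in branches]
        assert all(a != b for a, b in zip(labels, labels[1:]))

    def test_merged_flag(self, paper_sp, paper_rule, io):
        # near the lower bifurcation the two lowest fixed points approach
        # each other closer than one discrete state
        diag = fixed_point_diagram(paper_sp, paper_rule, io, None,
                                   np.linspace(0.1, 0.5, 17), varied="post",
                                   fixed_value=0.656)
        merged_seen = any(
            any(b.merged for b in branches) for branches in diag.branches
        )
        assert merged_seen

    def test_diagram_bistable_band(self, paper_sp, paper_rule, io):
        diag = fixed_point_diagram(paper_sp, paper_rule, io, None,
                                   np.linspace(0.05, 0.95, 19), varied="post",
                                   fixed_value=0.656)
        mask = diag.bistable_mask()
        assert mask.any()
        # band is contiguous and bounded by monostable regions on both sides
        first, last = np.flatnonzero(mask)[[0, -1]]
        assert first > 0 and last < len(mask) - 1


class TestPeakAttractorCorrespondence:
    def test_distribution_peaks_near_stable_points(
        self, paper_sp, paper_rule, io, working_point, paper_pdel
    ):
        dist = first_step_distribution(paper_sp, paper_pdel)
        res = classify_case(delta_ln_p(paper_sp, paper_pdel))
        branches = continuous_fixed_points(paper_sp, paper_rule, io, working_point)
        stable_S = sorted(b.S for b in branches if b.stable)
        assert len(stable_S) == len(res.maxima)
        for peak, fixpt in zip(sorted(res.maxima), stable_S):
            assert abs(peak - fixpt) <= 1.0
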