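"""Regulatory kernels: binding, histone chain, methylation, expression."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.optimize import brentq
from scipy.stats import binom

from epidrift.regulation import (
    RegulationParams,
    denovo_rate,
    expression_fixed_point,
    histone_stationary_distribution,
    hmt_binding_probability,
    occupancy_from_sums,
    promoter_occupancy,
    replicate_methylation,
    step_expression,
    step_histones,
    unmethylated_fraction,
)
from epidrift.genome import Gene, Interaction


class TestUnmethylatedFraction:
    def test_all_unmethylated_is_one(self):
        assert unmethylated_fraction(np.zeros(6, dtype=bool)) == 1.0

    def test_half_methylated_is_half(self):
        assert unmethylated_fraction(np.array([1, 1, 1, 0, 0, 0], bool)) == 0.5

    def test_zero_cpgs_convention(self):
        assert unmethylated_fraction(np.zeros(0, dtype=bool)) == 0.0

    def test_matches_count_oracle(self, rng):
        for _ in range(20):
            v = rng.random(rng.integers(1, 30)) < 0.5
            assert unmethylated_fraction(v) == (v.size - v.sum()) / v.size


class TestHmtBinding:
    def test_logistic_at_zero_argument(self):
        p = RegulationParams(eps_0=0.0, eps_bs=1.0, eps_hm=1.0)
        assert hmt_binding_probability(0, 8, 0.0, p) == pytest.approx(0.5)

    def test_closed_form_value(self):
        # logistic(-2 + 1*1 + 4*0.5) = logistic(1) ~ 0.7311, computed
        # independently from the exponential form
        p = RegulationParams(eps_0=2.0, eps_bs=1.0, eps_hm=0.5)
        expected = 1.0 / (1.0 + math.exp(2.0 - 1.0 - 4 * 0.5))
        assert hmt_binding_probability(4, 8, 1.0, p) == pytest.approx(expected)
        assert expected == pytest.approx(0.73105857, abs=1e-6)

    def test_saturation_limit(self):
        p = RegulationParams(eps_0=2.0, eps_bs=1.0, eps_hm=50.0)
        assert hmt_binding_probability(8, 8, 1.0, p) == pytest.approx(1.0)

    def test_no_nucleosomes_no_recruitment(self, params):
        assert hmt_binding_probability(0, 0, 1.0, params) == 0.0

    @given(
        n_hm=st.integers(0, 7),
        w=st.floats(0.0, 1.0 - 1e-9),
        eps_0=st.floats(0.0, 10.0),
        eps_bs=st.floats(0.1, 4.0),
        eps_hm=st.floats(0.1, 2.0),
    )
    @settings(deadline=None, max_examples=80, derandomize=True)
    def test_monotone_in_marks_and_binding_sites(self, n_hm, w, eps_0, eps_bs, eps_hm):
        p = RegulationParams(eps_0=eps_0, eps_bs=eps_bs, eps_hm=eps_hm)
        base = hmt_binding_probability(n_hm, 8, w, p)
        assert 0.0 <= base <= 1.0
        assert hmt_binding_probability(n_hm + 1, 8, w, p) > base
        assert hmt_binding_probability(n_hm, 8, min(w + 1e-3, 1.0), p) > base


class TestStepHistones:
    def test_pure_death_chain_decay(self, rng):
        p = RegulationParams(k_m=0.0, k_d=0.05)
        n = np.full(4000, 8)
        for _ in range(10):
            n = step_histones(n, np.full(4000, 8), 0.0, p, rng)
        expected = 8 * (1 - 0.05) ** 10
        assert np.mean(n) == pytest.approx(expected, rel=0.05)

    def test_pure_birth_step_is_binomial(self, rng):
        p = RegulationParams(k_m=0.4, k_d=0.0)
        draws = np.array(
            [step_histones(0, 6, 1.0, p, rng) for _ in range(4000)]
        )
        ref = binom(6, 0.4)
        assert np.mean(draws) == pytest.approx(ref.mean(), rel=0.05)
        assert np.var(draws) == pytest.approx(ref.var(), rel=0.15)

    def test_counts_stay_in_bounds(self, params, rng):
        n = 4
        for _ in range(500):
            n = step_histones(n, 8, 0.9, params, rng)
            assert 0 <= n <= 8

    def test_overscaled_rate_rejected(self, rng):
        p = RegulationParams(k_m=1.0, k_d=0.05, dt=1.0)
        with pytest.raises(ValueError):
            step_histones(0, 8, 1.5, p, rng)  # k_m * theta * dt > 1


class TestHistoneStationaryDistribution:
    def test_no_feedback_reduces_to_binomial(self):
        # eps_hm = 0: constant-rate chain, detailed balance gives
        # Binomial(N_H, k_m Theta / (k_m Theta + k_d))
        p = RegulationParams(eps_0=2.0, eps_bs=1.0, eps_hm=0.0, k_m=0.4, k_d=0.1)
        theta = 1.0 / (1.0 + math.exp(2.0 - 1.0))
        pi, bimodal = histone_stationary_distribution(6, 1.0, p)
        q = 0.4 * theta / (0.4 * theta + 0.1)
        np.testing.assert_allclose(pi, binom(6, q).pmf(np.arange(7)), atol=1e-12)
        assert not bimodal

    def test_default_energies_bistable_only_above_six_nucleosomes(self, params):
        # the class boundary C3 < 1 <= C2 <= 6 < C1 in chromatin terms
        _, bi8 = histone_stationary_distribution(8, 1.0, params)
        assert bi8
        for n_h in (2, 4, 6):
            _, bi = histone_stationary_distribution(n_h, 1.0, params)
            assert not bi

    def test_methylated_dna_locks_the_silenced_state(self, params):
        # at the stationary CpG methylation level the low mode dominates
        pi, _ = histone_stationary_distribution(8, 0.4, params)
        assert pi[:3].sum() > 0.9

    def test_simulation_matches_master_equation(self, params, rng):
        # chains sampled from the exact stationary law must stay on it
        n_h = 4
        pi, _ = histone_stationary_distribution(n_h, 1.0, params)
        chains = rng.choice(n_h + 1, p=pi, size=400)
        n_h_arr = np.full(400, n_h)
        counts = np.zeros(n_h + 1)
        for t in range(1500):
            theta = hmt_binding_probability(chains, n_h_arr, 1.0, params)
            chains = step_histones(chains, n_h_arr, theta, params, rng)
            if t >= 250:
                counts += np.bincount(chains, minlength=n_h + 1)
        tv = 0.5 * np.abs(counts / counts.sum() - pi).sum()
        assert tv < 0.02

    def test_relative_fluctuations_larger_for_c2_than_c1(self, params):
        # stem-cell-marker (C2) chromatin flickers strongly relative to its
        # level; C1 genes sit firmly in the high mode
        def cv(n_h):
            pi, _ = histone_stationary_distribution(n_h, 1.0, params)
            x = np.arange(n_h + 1) / n_h
            m = float(np.sum(pi * x))
            return math.sqrt(float(np.sum(pi * (x - m) ** 2))) / m

        assert cv(4) > 3 * cv(8)


class TestDenovoRate:
    def test_fully_unmodified_gene_uses_base_constant(self, params):
        assert denovo_rate(0, 8, params) == params.d_novo0 == 0.3

    def test_full_modification_protects(self):
        p = RegulationParams(eps_methyl=200.0)
        assert denovo_rate(8, 8, p) == pytest.approx(0.0, abs=1e-12)

    def test_closed_form_half_modified(self):
        p = RegulationParams(d_novo0=0.3, eps_methyl=6.0)
        assert denovo_rate(4, 8, p) == pytest.approx(0.3 * math.exp(-3.0))
        assert denovo_rate(4, 8, p) == pytest.approx(0.01494, abs=1e-5)

    def test_nucleosome_free_gene_uses_base_constant(self, params):
        assert denovo_rate(0, 0, params) == params.d_novo0


class TestReplicateMethylation:
    def test_perfect_inheritance(self, rng):
        p = RegulationParams(d_main=1.0, d_novo0=0.0)
        v = rng.random(50) < 0.4
        out = replicate_methylation(v, 0.0, p, rng)
        np.testing.assert_array_equal(out, v)

    def test_de_novo_gains_are_binomial(self, rng):
        p = RegulationParams(d_main=0.8, d_novo0=0.3)
        gains = [
            replicate_methylation(np.zeros(10, bool), 0.3, p, rng).sum()
            for _ in range(3000)
        ]
        ref = binom(10, 0.3)
        assert np.mean(gains) == pytest.approx(ref.mean(), rel=0.05)
        assert np.var(gains) == pytest.approx(ref.var(), rel=0.15)

    def test_stationary_level_matches_two_state_fixed_point(self, rng):
        # p* = D_novo / (1 - D_main + D_novo) for the per-CpG Markov chain
        p = RegulationParams(d_main=0.8, d_novo0=0.3)
        d_novo = 0.3
        v = np.zeros(5000, dtype=bool)
        for _ in range(60):  # relaxation time ~ 1/(1 - d_main + d_novo) = 2
            v = replicate_methylation(v, d_novo, p, rng)
        level = []
        for _ in range(40):
            v = replicate_methylation(v, d_novo, p, rng)
            level.append(v.mean())
        expected = d_novo / (1 - 0.8 + d_novo)
        assert np.mean(level) == pytest.approx(expected, rel=0.02)

    def test_methylation_monotone_in_d_novo(self, rng):
        p = RegulationParams(d_main=0.9)
        levels = []
        for d_novo in (0.05, 0.15, 0.3):
            v = np.zeros(4000, dtype=bool)
            for _ in range(80):
                v = replicate_methylation(v, d_novo, p, rng)
            levels.append(v.mean())
        assert levels[0] < levels[1] < levels[2]


class TestExpression:
    def test_paper_maximum_promoter_activity(self):
        # theta_pro = Theta = 1 and delta = 1 per unit time: e* = P_max = 1000
        p = RegulationParams(delta=1.0, dt=0.1)
        assert expression_fixed_point(1.0, 1.0, p) == pytest.approx(1000.0)

    def test_silenced_gene_decays_geometrically(self, params):
        e = 100.0
        for k in range(1, 6):
            e = step_expression(e, 0.5, 0.0, params)
            assert e == pytest.approx(100.0 * (1 - params.delta * params.dt) ** k)

    def test_euler_error_shrinks_linearly_with_dt(self):
        # analytic solution: e(t) = e* + (e0 - e*) exp(-delta t)
        drive, delta, t_end, e0 = 0.6, 0.5, 4.0, 10.0
        e_star = 1000.0 * drive / delta
        exact = e_star + (e0 - e_star) * math.exp(-delta * t_end)
        errs = []
        for dt in (0.02, 0.01):
            p = RegulationParams(delta=delta, dt=dt)
            e = e0
            for _ in range(int(t_end / dt)):
                e = step_expression(e, drive, 1.0, p)
            errs.append(abs(e - exact))
        assert errs[1] < errs[0]
        assert errs[0] / errs[1] == pytest.approx(2.0, rel=0.25)

    def test_unstable_step_rejected(self):
        with pytest.raises(ValueError):
            RegulationParams(delta=1.2, dt=1.0)


class TestPromoterOccupancy:
    def test_basal_without_interactions(self, params):
        gene = Gene(id=0, start=0, length=100)
        theta = promoter_occupancy(gene, np.zeros(3), params)
        assert theta == pytest.approx(params.q_p / (1 + params.q_p))

    def test_activator_and_repressor_saturation(self, params):
        assert occupancy_from_sums(1e9, 0.0, params) == pytest.approx(1.0)
        assert occupancy_from_sums(0.0, 1e9, params) == pytest.approx(0.0, abs=1e-8)

    @given(a=st.floats(0, 100), r=st.floats(0, 100))
    @settings(deadline=None, max_examples=60, derandomize=True)
    def test_monotone_and_bounded(self, a, r):
        p = RegulationParams()
        theta = occupancy_from_sums(a, r, p)
        assert 0.0 < theta < 1.0
        assert occupancy_from_sums(a + 1.0, r, p) > theta
        assert occupancy_from_sums(a, r + 1.0, p) < theta

    def test_two_gene_fixed_point_matches_root_finder(self, params):
        # gene 1 activated by gene 0 (weight 2); gene 0 basal.  The coupled
        # steady state of the expression system is checked against an
        # independent scalar root-finder on the fixed-point equation.
        g0 = Gene(id=0, start=0, length=100)
        g1 = Gene(
            id=1,
            start=100,
            length=100,
            interactions=[Interaction(regulator=0, sign="activating", weight=2)],
        )
        theta_chrom = 0.9
        e0 = expression_fixed_point(
            params.q_p / (1 + params.q_p), theta_chrom, params
        )

        def residual(e1):
            theta_pro = promoter_occupancy(g1, np.array([e0, e1]), params)
            return expression_fixed_point(theta_pro, theta_chrom, params) - e1

        root = brentq(residual, 0.0, params.p_max / params.delta)
        # iterate the map as the implementation does
        e1 = 0.0
        for _ in range(2000):
            theta_pro = promoter_occupancy(g1, np.array([e0, e1]), params)
            e1 = expression_fixed_point(theta_pro, theta_chrom, params)
        assert e1 == pytest.approx(root, rel=1e-8)
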