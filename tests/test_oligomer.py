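"""Dual-color labeling model: exact oracles, limits, and inference."""

import itertools

import numpy as np
import pytest

from curtainkit import simgen
from curtainkit.oligomer import (
    ClusterSizeModel,
    ColorCounts,
    LabelModel,
    color_probabilities,
    estimate_gamma,
    gamma_sensitivity,
    loglik,
    mixture_probabilities,
    mle_cluster_size,
    trinomial_pmf,
)


def brute_force_probs(n, label):
    """Independent oracle: enumerate every (c, m) outcome of a size-n cluster."""
    pc, pm = label.pc, label.pm
    q = 1 - pc - pm
    from math import comb

    p_c = p_m = p_d = p_none = 0.0
    for c in range(n + 1):
        for m in range(n - c + 1):
            f = (
                comb(n, c) * comb(n - c, m)
                * pc**c * pm**m * q ** (n - c - m)
            )
            if c == 0 and m == 0:
                p_none += f
            elif m == 0:
                p_c += f
            elif c == 0:
                p_m += f
            else:
                p_d += f
    alpha = 1 - p_none
    return p_c / alpha, p_m / alpha, p_d / alpha, alpha


class TestTrinomial:
    def test_hand_value(self):
        # f(1,1;2, pc=pm=0.5) = 2 * 0.5 * 0.5 = 0.5
        assert trinomial_pmf(1, 1, 2, LabelModel(1.0, 1.0)) == pytest.approx(0.5)

    @pytest.mark.parametrize("n", [1, 2, 5, 10])
    @pytest.mark.parametrize("kappa,gamma", [(1.0, 1.0), (0.8, 1.3), (0.5, 2.0)])
    def test_normalization(self, n, kappa, gamma):
        label = LabelModel(kappa, gamma)
        tot = sum(
            trinomial_pmf(c, m, n, label)
            for c in range(n + 1)
            for m in range(n - c + 1)
        )
        assert tot == pytest.approx(1.0, abs=1e-12)

    def test_full_labeling_leaves_nothing_unlabeled(self):
        for n in (1, 3, 7):
            assert trinomial_pmf(0, 0, n, LabelModel(1.0, 1.3)) == 0.0

    def test_invalid_draw_rejected(self):
        with pytest.raises(ValueError):
            trinomial_pmf(2, 2, 3, LabelModel())


class TestColorProbabilities:
    def test_single_unit_cannot_be_dual(self):
        p = color_probabilities(1, LabelModel(1.0, 1.0))
        assert (p.p_cyan_only, p.p_magenta_only, p.p_dual) == pytest.approx(
            (0.5, 0.5, 0.0)
        )

    def test_dimer_enumeration(self):
        # four equally likely label pairs: CC, CM, MC, MM
        p = color_probabilities(2, LabelModel(1.0, 1.0))
        assert p.as_array() == pytest.approx([0.25, 0.25, 0.5])

    def test_extreme_asymmetry_suppresses_magenta(self):
        p = color_probabilities(3, LabelModel(1.0, 1e6))
        assert p.p_magenta_only < 1e-15

    @pytest.mark.parametrize("n", range(1, 11))
    @pytest.mark.parametrize("kappa,gamma", [(1.0, 1.0), (1.0, 1.3), (0.7, 1.3),
                                             (0.4, 0.8)])
    def test_matches_brute_force_enumeration(self, n, kappa, gamma):
        label = LabelModel(kappa, gamma)
        p = color_probabilities(n, label)
        oc, om, od, oa = brute_force_probs(n, label)
        assert p.p_cyan_only == pytest.approx(oc, abs=1e-12)
        assert p.p_magenta_only == pytest.approx(om, abs=1e-12)
        assert p.p_dual == pytest.approx(od, abs=1e-12)
        assert p.alpha == pytest.approx(oa, abs=1e-12)

    def test_probabilities_sum_to_one_on_grid(self):
        for n, kappa, gamma in itertools.product(
            (1, 4, 25), (0.3, 0.9, 1.0), (0.5, 1.0, 2.5)
        ):
            assert color_probabilities(n, LabelModel(kappa, gamma)).as_array().sum() \
                == pytest.approx(1.0, abs=1e-12)

    def test_dual_monotone_in_size_and_efficiency(self):
        for gamma in (0.8, 1.0, 1.3):
            duals = [color_probabilities(n, LabelModel(1.0, gamma)).p_dual
                     for n in range(1, 11)]
            assert np.all(np.diff(duals) >= -1e-12)
            duals_k = [color_probabilities(4, LabelModel(k, gamma)).p_dual
                       for k in (0.2, 0.4, 0.6, 0.8, 1.0)]
            assert np.all(np.diff(duals_k) >= -1e-12)


class TestMixture:
    def test_fixed_kind_reduces_to_single_size(self):
        label = LabelModel(1.0, 1.3)
        mix = mixture_probabilities(ClusterSizeModel("fixed", 3.0), label)
        single = color_probabilities(3, label)
        assert mix.as_array() == pytest.approx(single.as_array(), abs=1e-14)

    def test_small_mu_concentrates_on_monomers(self):
        p = mixture_probabilities(
            ClusterSizeModel("truncated_poisson", 1e-6), LabelModel(1.0, 1.0)
        )
        assert p.p_dual < 1e-5

    def test_truncated_poisson_against_brute_force_sum(self):
        # oracle: explicit sum over N of phi(N) * enumerated category probs
        label = LabelModel(1.0, 1.0)
        mu = 2.0
        from math import exp, factorial

        norm = 1 - exp(-mu)
        oc = om = od = 0.0
        for n in range(1, 60):
            w = mu**n * exp(-mu) / (factorial(n) * norm)
            c, m, d, _ = brute_force_probs(n, label)
            oc += w * c
            om += w * m
            od += w * d
        p = mixture_probabilities(ClusterSizeModel("truncated_poisson", mu), label)
        assert p.p_dual == pytest.approx(od, abs=1e-10)
        assert p.p_cyan_only == pytest.approx(oc, abs=1e-10)

    def test_matches_monte_carlo_simulation(self):
        # generator and analytic mixture must agree within 3 binomial SE
        rng = np.random.default_rng(11)
        for _ in range(6):
            kappa = rng.uniform(0.4, 1.0)
            gamma = rng.uniform(0.6, 2.0)
            mu = rng.uniform(0.5, 5.0)
            label = LabelModel(kappa, gamma)
            sm = ClusterSizeModel("truncated_poisson", mu)
            n = 100_000
            counts = simgen.sim_label_counts(n, sm, label, seed=int(rng.integers(2**30)))
            p = mixture_probabilities(sm, label)
            for obs, exp in zip(counts.as_array(), p.as_array()):
                se = np.sqrt(exp * (1 - exp) * counts.total)
                assert abs(obs - exp * counts.total) < 3 * se + 1e-9


class TestLoglik:
    def test_zero_counts_give_zero(self):
        assert loglik(ColorCounts(0, 0, 0),
                      ClusterSizeModel("fixed", 2.0), LabelModel()) == 0.0

    def test_counts_at_predicted_proportions_maximize(self):
        label = LabelModel(1.0, 1.0)
        sm = ClusterSizeModel("fixed", 2.0)
        # counts exactly proportional to (0.25, 0.25, 0.5)
        counts = ColorCounts(250, 250, 500)
        ll_match = loglik(counts, sm, label)
        for other_n in (1, 3, 4, 5):
            assert loglik(counts, ClusterSizeModel("fixed", float(other_n)), label) \
                < ll_match

    def test_scaling_counts_preserves_argmax(self):
        label = LabelModel(1.0, 1.3)
        c1 = ColorCounts(48, 37, 56)
        c2 = ColorCounts(96, 74, 112)
        f1 = mle_cluster_size(c1, "truncated_poisson", label)
        f2 = mle_cluster_size(c2, "truncated_poisson", label)
        assert f1.mu_hat == pytest.approx(f2.mu_hat, rel=1e-4)


class TestMLE:
    def test_solution_binding_counts_give_dimer(self):
        # 141 solution binding events, 56 dual; single-color split 1.3:1
        counts = ColorCounts.from_total_and_dual(141, 56, gamma=1.3)
        fit = mle_cluster_size(counts, "fixed", LabelModel(1.0, 1.3))
        assert fit.mean_size == pytest.approx(2.0)
        assert not fit.boundary

    def test_truncated_poisson_parameter_recovery(self):
        counts = simgen.sim_label_counts(
            5000, ClusterSizeModel("truncated_poisson", 2.5),
            LabelModel(1.0, 1.3), seed=5,
        )
        fit = mle_cluster_size(counts, "truncated_poisson", LabelModel(1.0, 1.3))
        assert 2.3 <= fit.mu_hat <= 2.7

    def test_all_dual_hits_boundary_and_is_flagged(self):
        with pytest.warns(UserWarning, match="boundary"):
            fit = mle_cluster_size(ColorCounts(0, 0, 100), "truncated_poisson")
        assert fit.boundary

    def test_too_few_events_rejected(self):
        with pytest.raises(ValueError):
            mle_cluster_size(ColorCounts(2, 2, 2), "fixed")

    def test_lower_kappa_never_lowers_size_estimate(self):
        # unlabeled complexes hide oligomer size: kappa < 1 inflates mu_hat,
        # so the kappa=1 estimate is a lower limit
        counts = ColorCounts.from_total_and_dual(141, 56, gamma=1.3)
        sizes = [
            mle_cluster_size(counts, "truncated_poisson", LabelModel(k, 1.3)).mu_hat
            for k in (1.0, 0.8, 0.6, 0.4)
        ]
        assert np.all(np.diff(sizes) >= -1e-6)


class TestGamma:
    def test_symmetric_counts_give_unity(self):
        g = estimate_gamma(ColorCounts(50, 50, 40),
                           ClusterSizeModel("truncated_poisson", 2.0))
        assert g == pytest.approx(1.0, abs=1e-6)

    def test_recovery_from_simulated_counts(self):
        counts = simgen.sim_label_counts(
            5000, ClusterSizeModel("truncated_poisson", 2.0),
            LabelModel(1.0, 1.3), seed=9,
        )
        g = estimate_gamma(counts, ClusterSizeModel("truncated_poisson", 2.0))
        assert g == pytest.approx(1.3, abs=0.15)

    def test_ratio_and_mle_modes_agree(self):
        counts = simgen.sim_label_counts(
            20000, ClusterSizeModel("truncated_poisson", 2.0),
            LabelModel(1.0, 1.3), seed=21,
        )
        sm = ClusterSizeModel("truncated_poisson", 2.0)
        g_ratio = estimate_gamma(counts, sm, method="ratio")
        g_mle = estimate_gamma(counts, sm, method="mle")
        assert g_mle == pytest.approx(g_ratio, rel=0.05)

    def test_sensitivity_is_weak_near_measured_asymmetry(self):
        counts = ColorCounts.from_total_and_dual(141, 56, gamma=1.3)
        tab = gamma_sensitivity(counts, "truncated_poisson",
                                np.linspace(1.2, 1.4, 5))
        assert tab["mean_size"].max() - tab["mean_size"].min() < 0.5
        fixed = gamma_sensitivity(counts, "fixed", np.array([1.0, 1.3]))
        assert fixed["mu_hat"].nunique() == 1

    def test_empty_gamma_range_rejected(self):
        with pytest.raises(ValueError):
            gamma_sensitivity(ColorCounts(10, 10, 10), "fixed", np.array([]))
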