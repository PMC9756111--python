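"""Generators: determinism, moment identities, ground-truth plumbing."""

import numpy as np
import pytest

from curtainkit import simgen
from curtainkit.oligomer import ClusterSizeModel, LabelModel
from curtainkit.survival import SurvivalModel


class TestDeterminism:
    def test_every_generator_is_pure_in_seed(self):
        m = SurvivalModel(0.5, 10, 1000)
        a = simgen.sim_lifetimes(50, m, 100, seed=3)
        b = simgen.sim_lifetimes(50, m, 100, seed=3)
        assert np.array_equal(a.durations, b.durations)

        t1 = simgen.sim_diffusion_track(0.1, 50, 0.1, 0.02, seed=3)
        t2 = simgen.sim_diffusion_track(0.1, 50, 0.1, 0.02, seed=3)
        assert np.array_equal(t1.positions, t2.positions)

        b1 = simgen.sim_bleach_trace(4, 100, 0.2, 60, noise_sd=10, seed=3)
        b2 = simgen.sim_bleach_trace(4, 100, 0.2, 60, noise_sd=10, seed=3)
        assert np.array_equal(b1.F, b2.F)

        c1 = simgen.sim_label_counts(500, ClusterSizeModel("truncated_poisson", 2),
                                     LabelModel(), seed=3)
        c2 = simgen.sim_label_counts(500, ClusterSizeModel("truncated_poisson", 2),
                                     LabelModel(), seed=3)
        assert c1 == c2

        cfg = simgen.SimConfig(seed=3)
        k1 = simgen.sim_kymogram([(1, 2)], [], cfg, 10, 50)
        k2 = simgen.sim_kymogram([(1, 2)], [], cfg, 10, 50)
        assert np.array_equal(k1.data, k2.data)

    def test_streams_are_independent_of_each_other(self):
        # drawing from one generator must not perturb another's stream
        t1 = simgen.sim_diffusion_track(0.1, 50, 0.1, 0.0, seed=5)
        simgen.sim_lifetimes(1000, SurvivalModel(0.5, 1, 10), 5, seed=5)
        t2 = simgen.sim_diffusion_track(0.1, 50, 0.1, 0.0, seed=5)
        assert np.array_equal(t1.positions, t2.positions)


class TestLifetimes:
    def test_single_exponential_mean(self):
        data = simgen.sim_lifetimes(
            100_000, SurvivalModel(0.0, 10.0, 10.0), 1e9, seed=0
        )
        assert data.durations.mean() == pytest.approx(10.0, rel=0.02)
        assert not data.censored.any()

    def test_censored_fraction_matches_mixture_survival(self):
        # S(100) = 0.5 e^-0.1 + 0.5 e^-10 ~ 0.4524
        n = 100_000
        data = simgen.sim_lifetimes(
            n, SurvivalModel(0.5, 10.0, 1000.0), 100.0, seed=1
        )
        expect = 0.5 * np.exp(-0.1) + 0.5 * np.exp(-10)
        se = np.sqrt(expect * (1 - expect) / n)
        assert abs(data.censored.mean() - expect) < 3 * se

    def test_parameter_validation(self):
        with pytest.raises(ValueError):
            simgen.sim_lifetimes(0, SurvivalModel(0.5, 1, 2), 10)
        with pytest.raises(ValueError):
            simgen.sim_lifetimes(5, SurvivalModel(0.5, 1, 2), -1)


class TestDiffusion:
    def test_frozen_particle_constant_trace(self):
        t = simgen.sim_diffusion_track(0.0, 20, 0.1, 0.0, seed=2, x0=3.0)
        assert np.all(t.positions == 3.0)

    def test_increment_variance_moment_identity(self):
        D, dt, sig = 0.1, 0.1, 0.02
        t = simgen.sim_diffusion_track(D, 100_000, dt, sig, seed=3)
        dx = np.diff(t.positions)
        assert dx.var() == pytest.approx(2 * D * dt + 2 * sig**2, rel=0.02)

    def test_lag1_covariance_is_minus_noise_variance(self):
        sig = 0.05
        t = simgen.sim_diffusion_track(0.05, 200_000, 0.1, sig, seed=4)
        dx = np.diff(t.positions)
        cov = np.mean(dx[:-1] * dx[1:])
        assert cov == pytest.approx(-sig**2, rel=0.1)

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            simgen.sim_diffusion_track(0.1, 1, 0.1)


class TestBleach:
    def test_noiseless_staircase_monotone_to_zero(self):
        tr = simgen.sim_bleach_trace(4, 100.0, 1.0, 400, noise_sd=0.0, seed=5)
        levels = np.unique(tr.F)
        assert set(levels).issubset({0.0, 100.0, 200.0, 300.0, 400.0})
        assert np.all(np.diff(tr.F) <= 0)
        assert tr.F[0] == 400.0 and tr.F[-1] == 0.0

    def test_initial_amplitude_mean(self):
        f0 = [
            simgen.sim_bleach_trace(3, 100.0, 0.1, 30, noise_sd=20.0, seed=s).F[0]
            for s in range(300)
        ]
        assert np.mean(f0) == pytest.approx(300.0, abs=3 * 20 / np.sqrt(300))

    def test_bleach_time_geometric(self):
        r, dt = 0.5, 0.1
        frames = []
        for s in range(2000):
            _, truth = simgen.sim_bleach_trace(1, 100.0, r, 400, seed=s,
                                               return_truth=True)
            frames.append(truth["bleach_frames"][0])
        frames = np.array(frames)
        frames = frames[frames >= 0]
        # geometric with success prob 1-exp(-r dt): mean = 1/p - 1 (0-based)
        p = 1 - np.exp(-r * dt)
        assert frames.mean() == pytest.approx(1 / p - 1, rel=0.05)

    def test_blinking_produces_recoveries(self):
        tr = simgen.sim_bleach_trace(3, 100.0, 0.01, 500, noise_sd=0.0,
                                     blink_off_rate=0.5, blink_on_rate=2.0,
                                     seed=6)
        assert np.any(np.diff(tr.F) > 0)


class TestLabelCounts:
    def test_monomers_never_dual(self):
        c = simgen.sim_label_counts(
            10_000, ClusterSizeModel("fixed", 1.0), LabelModel(1.0, 1.0), seed=7
        )
        assert c.n_dual == 0

    def test_dimer_dual_fraction_half(self):
        c = simgen.sim_label_counts(
            100_000, ClusterSizeModel("fixed", 2.0), LabelModel(1.0, 1.0), seed=8
        )
        frac = c.n_dual / c.total
        assert frac == pytest.approx(0.5, abs=3 * 0.5 / np.sqrt(c.total))

    def test_huge_clusters_always_dual(self):
        c = simgen.sim_label_counts(
            5000, ClusterSizeModel("truncated_poisson", 40.0),
            LabelModel(1.0, 1.0), seed=9,
        )
        assert c.n_dual / c.total > 0.999

    def test_unlabeled_clusters_discarded(self):
        c, truth = simgen.sim_label_counts(
            5000, ClusterSizeModel("fixed", 1.0), LabelModel(0.5, 1.0), seed=10,
            return_truth=True,
        )
        assert c.total == truth["detected"].sum()
        assert c.total < 5000


class TestKymogram:
    def test_empty_scene_pure_noise(self):
        cfg = simgen.SimConfig(seed=11, noise_sd=2.0)
        k = simgen.sim_kymogram([], [], cfg, 50, 100)
        assert abs(k.data.mean()) < 0.05
        assert k.data.std() == pytest.approx(2.0, rel=0.05)

    def test_static_punctum_refit_matches_truth(self):
        from curtainkit.tracking import localize_punctum

        cfg = simgen.SimConfig(seed=12, noise_sd=1.0, pixel_size=0.1)
        k = simgen.sim_kymogram([], [(0, 4.55, 50.0)], cfg, 20, 100)
        loc = localize_punctum(k.data[0, 0])
        assert loc.valid
        assert loc.center[0] * cfg.pixel_size == pytest.approx(4.55, abs=0.05)

    def test_tract_width_matches_geometry(self):
        cfg = simgen.SimConfig(seed=13, noise_sd=0.1, pixel_size=0.1,
                               psf_sigma=0.15)
        k = simgen.sim_kymogram([(3.0, 5.0)], [], cfg, 10, 100,
                                tract_amplitude=10.0)
        profile = k.data[0].mean(axis=0)
        bright = np.sum(profile > 5.0)  # half-maximum width
        assert bright == pytest.approx(20, abs=3)

    def test_out_of_field_clipped_with_warning(self):
        cfg = simgen.SimConfig(seed=14)
        with pytest.warns(UserWarning, match="field of view"):
            simgen.sim_kymogram([(-1.0, 2.0)], [], cfg, 5, 50)

    def test_ground_truth_rides_along(self):
        cfg = simgen.SimConfig(seed=15)
        k = simgen.sim_kymogram([(1.0, 2.0)], [(1, 3.0, 10.0)], cfg, 5, 60)
        assert len(k.truth["tracts"]) == 1
        assert k.truth["puncta"][0]["channel"] == 1


class TestForceProtocol:
    def test_force_series_steps(self):
        proto = simgen.ForceProtocol(((1.0, 65.0), (1.0, 5.0)))
        F = proto.force_series(30, 0.1)
        assert set(F) == {65.0, 5.0}
        assert F[0] == 65.0 and F[-1] == 5.0

    def test_bad_duration_rejected(self):
        with pytest.raises(ValueError):
            simgen.ForceProtocol(((0.0, 65.0),))

    def test_wlc_trace_has_two_plateaus(self):
        proto = simgen.ForceProtocol(((2.0, 65.0), (2.0, 5.0)))
        F = proto.force_series(40, 0.1)
        trace = simgen.sim_wlc_extension(np.full(40, 3.0), F, noise_sd=0.0)
        xi = trace.frame["xi"]
        assert xi[F == 65.0].std() < 1e-12
        assert xi[F == 65.0].mean() > xi[F == 5.0].mean() * 1.05
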