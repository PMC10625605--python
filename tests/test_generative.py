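"""Generative models: tuning, likelihood decoding, exact posteriors."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from neurosampler import generative as g
from neurosampler._ring import wrap


class TestLogTuning:
    def test_zero_at_preferred_and_half_width(self, tuning):
        h = tuning.log_tuning(tuning.theta[20])
        assert h[20] == pytest.approx(0.0)
        h2 = tuning.log_tuning(tuning.theta[20] + tuning.a)
        assert h2[20] == pytest.approx(-0.5)
        assert np.all(h <= 0) and np.all(h2 <= 0)

    def test_wrapped_distance_across_boundary(self):
        # s = 179 deg and theta_j = -179 deg are 2 degrees apart on the ring
        tun = g.TuningModel(n_e=360, a=40.0)
        j = int(np.argmin(np.abs(tun.theta - (-179.0))))
        h = tun.log_tuning(179.0)
        assert h[j] == pytest.approx(-(2.0**2) / (2 * 40.0**2))  # -0.00125

    def test_rejects_nonfinite_stimulus(self, tuning):
        with pytest.raises(ValueError):
            tuning.log_tuning(np.nan)

    @given(st.floats(-360, 360), st.floats(-180, 180))
    def test_translation_equivariance(self, delta, s):
        tun = g.TuningModel(n_e=36, a=40.0)
        k = 5  # shift by an integer number of grid spacings
        shifted = tun.log_tuning(wrap(s + k * tun.spacing))
        assert np.allclose(np.roll(tun.log_tuning(s), k), shifted, atol=1e-9)


class TestFeedforward:
    def test_decoded_precision_is_count_over_a_squared(self, world, rng):
        for _ in range(20):
            inp = g.sample_feedforward(world, rng.uniform(-180, 180), rng)
            assert inp.Lambda_f == inp.n_f / world.tuning.a**2
            assert inp.n_f == inp.counts.sum()
            assert -180 < inp.mu_f <= 180

    def test_expected_total_count_matches_gaussian_integral(self, world, rng):
        # E[n_f] ~ U_f*sqrt(2*pi)*a/spacing for a << L
        n = np.mean([
            g.sample_feedforward(world, 0.0, rng).n_f for _ in range(300)
        ])
        expect = world.U_f * np.sqrt(2 * np.pi) * world.tuning.a / world.tuning.spacing
        assert n == pytest.approx(expect, rel=0.05)

    def test_peak_rate_at_preferred_stimulus(self, world):
        rates = world.U_f * np.exp(world.tuning.log_tuning(world.tuning.theta[10]))
        assert rates[10] == pytest.approx(world.U_f)

    def test_decode_single_count_and_symmetry(self, tuning):
        counts = np.zeros(tuning.n_e)
        j = int(np.argmin(np.abs(tuning.theta - 30.0)))
        counts[j] = 1
        inp = g.decode_likelihood(counts, tuning)
        assert inp.mu_f == pytest.approx(tuning.theta[j])
        assert inp.Lambda_f == pytest.approx(1 / tuning.a**2)

        counts = np.zeros(tuning.n_e)
        counts[np.argmin(np.abs(tuning.theta - 10.0))] = 3
        counts[np.argmin(np.abs(tuning.theta + 10.0))] = 3
        assert abs(g.decode_likelihood(counts, tuning).mu_f) < 1e-9

    def test_decode_mean_unbiased_monte_carlo(self, world, rng):
        mus = [g.sample_feedforward(world, 40.0, rng).mu_f for _ in range(500)]
        se = np.std(mus) / np.sqrt(len(mus))
        assert abs(np.mean(mus) - 40.0) < 3 * se

    def test_empty_input_flagged(self, tuning):
        inp = g.decode_likelihood(np.zeros(tuning.n_e), tuning)
        assert inp.empty and inp.Lambda_f == 0.0
        with pytest.raises(g.EmptyInputError):
            g.posterior_hierarchical(inp, 0.1)

    def test_decoding_equivariance_under_rotation(self, fixed_input, tuning):
        k = 17
        rolled = g.decode_likelihood(np.roll(fixed_input.counts, k), tuning)
        assert wrap(rolled.mu_f - fixed_input.mu_f) == pytest.approx(
            k * tuning.spacing, abs=1e-6
        )
        assert rolled.Lambda_f == fixed_input.Lambda_f


class TestSampleWorld:
    def test_strong_prior_locks_stimulus_to_parameter(self, tuning, rng):
        w = g.HierarchicalWorld(Lambda_s=1e9, U_f=5.0, tuning=tuning)
        s, z, _ = g.sample_world(w, rng)
        assert abs(wrap(s - z)) < 1e-3

    def test_conditional_variance_matches_prior(self, tuning, rng):
        w = g.HierarchicalWorld(Lambda_s=0.05, U_f=5.0, tuning=tuning)
        d = np.array([wrap(t[0] - t[1]) for t in (g.sample_world(w, rng) for _ in range(10000))])
        assert np.var(d) == pytest.approx(1 / w.Lambda_s, rel=0.1)

    def test_marginal_of_stimulus_is_uniform(self, tuning, rng):
        from scipy import stats

        w = g.HierarchicalWorld(Lambda_s=0.05, U_f=5.0, tuning=tuning)
        s = np.array([g.sample_world(w, rng)[0] for _ in range(4000)])
        p = stats.kstest(s, stats.uniform(loc=-180, scale=360).cdf).pvalue
        assert p > 0.01

    def test_parallel_difference_variance(self, tuning, rng):
        w = g.ParallelWorld(Lambda_s=0.1, U_f=5.0, tuning=tuning)
        diffs = []
        for _ in range(8000):
            (s1, s2), _ = g.sample_world(w, rng)
            diffs.append(wrap(s1 - s2))
        assert np.var(diffs) == pytest.approx(1 / w.Lambda_s, rel=0.1)


class TestPosteriors:
    def test_hierarchical_precision_matrix(self, fixed_input):
        post = g.posterior_hierarchical(fixed_input, 0.05)
        Lf = fixed_input.Lambda_f
        assert np.allclose(post.K_p, [[Lf + 0.05, -0.05], [-0.05, 0.05]])
        assert post.mu_p[0] == post.mu_p[1] == fixed_input.mu_f
        # marginal variance of s is 1/Lambda_f for any Lambda_s > 0
        assert post.cov()[0, 0] == pytest.approx(1 / Lf)
        assert np.linalg.det(post.K_p) == pytest.approx(Lf * 0.05)

    def test_strong_prior_correlates_latents(self, fixed_input):
        post = g.posterior_hierarchical(fixed_input, 1e6)
        C = post.cov()
        assert C[0, 1] / np.sqrt(C[0, 0] * C[1, 1]) > 0.999

    def test_degenerate_prior_flagged(self, fixed_input):
        post = g.posterior_hierarchical(fixed_input, 0.0)
        assert post.degenerate
        with pytest.raises(np.linalg.LinAlgError):
            post.cov()

    def test_parallel_additivity_and_limits(self, tuning, rng):
        w = g.ParallelWorld(Lambda_s=0.1, U_f=5.0, tuning=tuning)
        i1 = g.sample_feedforward(w, -10.0, rng)
        i2 = g.sample_feedforward(w, 10.0, rng)
        post = g.posterior_parallel((i1, i2), w.Lambda_s)
        # precision additivity: K_p - prior = likelihood precision
        assert np.allclose(
            post.K_p - w.prior_precision, np.diag([i1.Lambda_f, i2.Lambda_f])
        )
        # no coupling: means are the likelihood means
        p0 = g.posterior_parallel((i1, i2), 0.0)
        assert np.allclose(p0.mu_p, [i1.mu_f, i2.mu_f], atol=1e-9)
        assert p0.cov()[0, 1] == pytest.approx(0.0)
        # infinitely strong coupling with equal precision: symmetric fusion
        i2b = g.FeedforwardInput(
            counts=i1.counts, tuning=tuning, mu_f=i2.mu_f,
            Lambda_f=i1.Lambda_f, n_f=i1.n_f,
        )
        pf = g.posterior_parallel((i1, i2b), 1e7)
        fused = (i1.mu_f + i2b.mu_f) / 2
        assert np.allclose(pf.mu_p, [fused, fused], atol=1e-3)

    def test_posterior_translation_equivariance(self, fixed_input, tuning):
        k = 23
        rolled = g.decode_likelihood(np.roll(fixed_input.counts, k), tuning)
        p0 = g.posterior_hierarchical(fixed_input, 0.05)
        p1 = g.posterior_hierarchical(rolled, 0.05)
        assert np.allclose(p1.K_p, p0.K_p)
        assert np.allclose(
            wrap(p1.mu_p - p0.mu_p), k * tuning.spacing * np.ones(2), atol=1e-6
        )


class TestGridOracle:
    """Dense-grid Bayes oracle: normalize the exact generative density."""

    def _grid_loglik(self, inp, grid):
        H = np.array([inp.tuning.log_tuning(s) for s in grid])  # (G, N)
        return H @ inp.counts

    def test_hierarchical_posterior_vs_grid(self, fixed_input):
        Ls = 0.05
        grid = np.arange(-180.0, 180.0, 0.1)
        ll = self._grid_loglik(fixed_input, grid)
        ps = np.exp(ll - ll.max())
        ps /= ps.sum()
        mean_s = np.sum(ps * grid)
        var_s = np.sum(ps * (grid - mean_s) ** 2)
        # z marginal: convolve p(s) with N(0, 1/Lambda_s)
        kern_x = np.arange(-600, 601) * 0.1  # odd length, centered at zero
        kern = np.exp(-0.5 * Ls * kern_x**2)
        pz = np.convolve(ps, kern / kern.sum(), mode="same")
        mean_z = np.sum(pz * grid) / pz.sum()
        var_z = np.sum(pz * (grid - mean_z) ** 2) / pz.sum()

        post = g.posterior_hierarchical(fixed_input, Ls)
        C = post.cov()
        sd_s, sd_z = np.sqrt(C[0, 0]), np.sqrt(C[1, 1])
        assert abs(mean_s - post.mu_p[0]) < 0.01 * sd_s
        assert abs(mean_z - post.mu_p[1]) < 0.01 * sd_z
        assert var_s == pytest.approx(C[0, 0], rel=0.01)
        assert var_z == pytest.approx(C[1, 1], rel=0.01)

    def test_parallel_posterior_vs_grid(self, tuning, rng):
        w = g.ParallelWorld(Lambda_s=0.1, U_f=5.0, tuning=tuning)
        i1 = g.sample_feedforward(w, -10.0, rng)
        i2 = g.sample_feedforward(w, 10.0, rng)
        post = g.posterior_parallel((i1, i2), w.Lambda_s)
        g1 = np.arange(i1.mu_f - 25, i1.mu_f + 25, 0.1)
        g2 = np.arange(i2.mu_f - 25, i2.mu_f + 25, 0.1)
        l1 = self._grid_loglik(i1, g1)
        l2 = self._grid_loglik(i2, g2)
        joint = (
            l1[:, None] + l2[None, :]
            - 0.5 * w.Lambda_s * (g1[:, None] - g2[None, :]) ** 2
        )
        P = np.exp(joint - joint.max())
        P /= P.sum()
        m1 = np.sum(P.sum(axis=1) * g1)
        m2 = np.sum(P.sum(axis=0) * g2)
        v1 = np.sum(P.sum(axis=1) * (g1 - m1) ** 2)
        v2 = np.sum(P.sum(axis=0) * (g2 - m2) ** 2)
        C = post.cov()
        assert abs(m1 - post.mu_p[0]) < 0.01 * np.sqrt(C[0, 0])
        assert abs(m2 - post.mu_p[1]) < 0.01 * np.sqrt(C[1, 1])
        assert v1 == pytest.approx(C[0, 0], rel=0.01)
        assert v2 == pytest.approx(C[1, 1], rel=0.01)


class TestIO:
    def test_csv_roundtrip(self, fixed_input, tmp_path):
        path = tmp_path / "input.csv"
        fixed_input.to_csv(path)
        back = g.FeedforwardInput.from_csv(path)
        assert np.array_equal(back.counts, fixed_input.counts)
        assert back.mu_f == pytest.approx(fixed_input.mu_f)
        assert back.Lambda_f == fixed_input.Lambda_f

    def test_world_config_roundtrip(self, tmp_path):
        cfg = tmp_path / "world.yaml"
        cfg.write_text(
            "N_E: 90\na_deg: 40\nL_deg: 360\nU_f: 4.0\nLambda_s: 0.02\nseed: 7\n"
        )
        world, seed = g.load_world(cfg)
        assert world.tuning.n_e == 90 and world.U_f == 4.0 and seed == 7
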