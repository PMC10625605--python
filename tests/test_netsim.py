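"""Spiking-network simulators: connectivity, weight laws, sampling behavior."""

import numpy as np
import pytest

from neurosampler import generative as g
from neurosampler import gibbs as gb
from neurosampler import netsim, readout
from neurosampler._ring import wrap


class TestWeightLaws:
    @pytest.mark.parametrize(
        "Ls,Lf,expected",
        [(0.0, 0.2, 0.0), (0.2, 0.2, 0.5), (1e9, 0.2, 1.0), (0.1, 0.3, 0.25)],
    )
    def test_optimal_weight_values(self, Ls, Lf, expected):
        assert netsim.optimal_weight(Ls, Lf) == pytest.approx(expected, abs=1e-6)

    def test_cross_network_weight_same_law(self):
        assert netsim.cross_network_weight(0.1, 0.3) == netsim.optimal_weight(0.1, 0.3)
        assert netsim.cross_network_weight(0.0, 0.3) == 0.0
        assert netsim.cross_network_weight(0.2, 0.2) == 0.5

    def test_zero_likelihood_rejected(self):
        with pytest.raises(ValueError):
            netsim.optimal_weight(0.1, 0.0)


class TestConnectivity:
    def test_ring_weights_sum_and_symmetry(self):
        cfg = netsim.NetworkConfig(w_E=0.3)
        J = netsim.build_ring_connectivity(cfg)
        # each neuron's summed E->E strength is N_E * w_EE (ring normalization)
        assert np.allclose(J["EE"].sum(axis=1), cfg.N_E * cfg.w_E, rtol=1e-3)
        assert np.allclose(J["EE"], J["EE"].T)
        # rows are symmetric about the diagonal neuron (even Gaussian)
        N = cfg.N_E
        for j in (0, 41, 115):
            for k in (1, 7, 60):
                assert J["EE"][j, (j + k) % N] == pytest.approx(
                    J["EE"][j, (j - k) % N], rel=1e-9
                )
        assert np.all(J["EI"] == cfg.w_I) and np.all(J["IE"] == cfg.w_E)

    def test_zero_weight_zero_matrix(self):
        cfg = netsim.NetworkConfig(w_E=0.0)
        assert not netsim.build_ring_connectivity(cfg)["EE"].any()


class TestEOnly:
    def test_empty_input_silent_network(self, tuning, rng):
        inp = g.decode_likelihood(np.zeros(tuning.n_e), tuning)
        trace = netsim.simulate_e_only(inp, 0.5, 200, rng)
        assert not trace.counts_E.any() and not trace.u_rec_E.any()

    def test_no_recurrence_samples_normalized_likelihood(self, fixed_input, rng):
        chain = netsim.run_sampler(fixed_input, 0.0, 20000, rng)
        fit = gb.fit_distribution(chain)
        se = gb.chain_mean_se(chain)
        assert abs(wrap(fit.mean[0] - fixed_input.mu_f)) < 3 * se[0]
        sd = np.sqrt(fit.cov[0, 0])
        assert sd == pytest.approx(fixed_input.Lambda_f**-0.5, rel=0.05)

    def test_instability_guard(self, fixed_input, rng):
        with pytest.raises(netsim.UnstableSimulationError):
            netsim.run_sampler(fixed_input, 1.3, 6000, rng)

    def test_rotation_equivariance_of_sampling(self, fixed_input, tuning, rng):
        k = 30
        rolled = g.decode_likelihood(np.roll(fixed_input.counts, k), tuning)
        c0 = netsim.run_sampler(fixed_input, 0.3, 15000, rng)
        c1 = netsim.run_sampler(rolled, 0.3, 15000, rng)
        f0, f1 = gb.fit_distribution(c0), gb.fit_distribution(c1)
        se = np.hypot(gb.chain_mean_se(c0), gb.chain_mean_se(c1))
        shift = wrap(f1.mean - f0.mean) - k * tuning.spacing
        assert np.all(np.abs(shift) < 3 * se)
        assert np.all(np.abs(f1.cov / f0.cov - 1.0) < 0.15)

    def test_spike_generation_fano_is_one(self, fixed_input, rng):
        # with w_E = 0 the rate is fixed, so per-step counts are pure Poisson
        trace = netsim.simulate_e_only(fixed_input, 0.0, 4000, rng)
        from neurosampler.analysis import fano_factor

        fano, mean_fano = fano_factor(trace.counts_E)
        n_active = np.sum(~np.isnan(fano))
        se = np.sqrt(2.0 / trace.counts_E.shape[0] / n_active)
        assert abs(mean_fano - 1.0) < 3 * se

    def test_recurrent_precision_readout_matches_prior(self, world, fixed_input, rng):
        # at w*, the summed recurrent input encodes Lambda_s: a^-2 sum u^r ~ Lambda_s
        w_star = netsim.optimal_weight(world.Lambda_s, fixed_input.Lambda_f)
        chain = netsim.run_sampler(fixed_input, w_star, 30000, rng)
        Ls_readout = chain.meta["mean_sum_ur"] / world.tuning.a**2
        assert Ls_readout == pytest.approx(world.Lambda_s, rel=0.10)

    def test_gibbs_alternation_pairing(self, fixed_input, rng):
        # z~_t is conditioned on the previous spikes: corr(z_t, s_{t-1})
        # exceeds corr(z_t, s_t) contribution beyond the shared chain value
        chain = netsim.run_sampler(fixed_input, 0.4, 20000, rng)
        s, z = chain.post_burn_in().T
        ok = ~np.isnan(s) & ~np.isnan(z)
        s, z = s[ok], z[ok]
        r_prev = np.corrcoef(z[1:], s[:-1])[0, 1]
        r_next = np.corrcoef(z[:-1], s[1:])[0, 1]
        assert r_prev > r_next


class TestEIRing:
    def test_zero_input_silent(self):
        cfg = netsim.NetworkConfig(w_E=0.05, T_ms=500.0)
        rng = np.random.default_rng(0)
        trace = netsim.simulate_ei(np.zeros(cfg.N_E), cfg, rng)
        assert trace.counts_E.sum() == 0 and trace.counts_I.sum() == 0

    def test_feedforward_regime_precision_tracks_likelihood(self):
        cfg = netsim.NetworkConfig(w_E=0.05)
        rng = np.random.default_rng(1)
        prec, lik = [], []
        for u in (0.025, 0.05, 0.1):
            ff = netsim.feedforward_rates(cfg.input_tuning, 0.0, u)
            trace = netsim.simulate_ei(ff, cfg, rng, T_ms=6000.0, w_EE=0.0)
            fit = gb.fit_distribution(readout.chain_from_trace(trace))
            prec.append(1.0 / fit.cov[0, 0])
            _, Lf = readout.decode_window_likelihood(trace)
            lik.append(float(np.nanmean(Lf)))
        assert prec[0] < prec[1] < prec[2]  # precision grows with input rate
        ratio = np.array(prec) / np.array(lik)
        assert np.all(ratio > 0.15) and np.all(ratio < 1.2)

    def test_fixed_rate_spiking_fano_is_one(self):
        # clamp the feedforward drive and remove all coupling: spike counts
        # are then pure Poisson, Fano factor 1 (refractoriness disabled)
        cfg = netsim.NetworkConfig(w_E=0.0, recurrent_noise=False)
        rng = np.random.default_rng(2)
        ff = netsim.feedforward_rates(cfg.input_tuning, 0.0, 0.05)
        trace = netsim.simulate_ei(ff, cfg, rng, T_ms=6000.0, w_EE=0.0,
                                   refractory=False, deterministic_input=True)
        from neurosampler.analysis import fano_factor

        counts = trace.counts_E[20:]
        active = counts[:, counts.mean(axis=0) > 0.2]
        _, mean_fano = fano_factor(active)
        se = np.sqrt(2.0 / active.shape[0] / active.shape[1])
        assert abs(mean_fano - 1.0) < 3 * se + 0.02

    def test_input_stream_doubles_window_variability(self):
        # with a Poisson input stream, window counts are doubly stochastic:
        # Fano rises towards 2 (input realization + spike generation)
        cfg = netsim.NetworkConfig(w_E=0.05, recurrent_noise=False)
        rng = np.random.default_rng(2)
        ff = netsim.feedforward_rates(cfg.input_tuning, 0.0, 0.05)
        trace = netsim.simulate_ei(ff, cfg, rng, T_ms=6000.0, w_EE=0.0,
                                   refractory=False)
        from neurosampler.analysis import fano_factor

        counts = trace.counts_E[20:]
        _, mean_fano = fano_factor(counts[:, counts.mean(axis=0) > 0.2])
        assert 1.3 < mean_fano < 2.5

    def test_hierarchical_ei_bump_is_input_positioned(self):
        cfg = netsim.NetworkConfig(w_E=0.04)
        rng = np.random.default_rng(3)
        ff = netsim.feedforward_rates(cfg.input_tuning, 35.0, 0.06)
        trace = netsim.simulate_ei(ff, cfg, rng, T_ms=4000.0)
        fit = gb.fit_distribution(readout.chain_from_trace(trace))
        assert abs(wrap(fit.mean[0] - 35.0)) < 5.0


class TestCoupled:
    def _run(self, w_mn, T_ms=4000.0, seed=0):
        cfg = netsim.NetworkConfig(w_E=0.05, w_mn=w_mn)
        rng = np.random.default_rng(seed)
        ffs = [netsim.feedforward_rates(cfg.input_tuning, m, 0.05)
               for m in (-10.0, 10.0)]
        t1, t2 = netsim.simulate_coupled(ffs, cfg, rng, T_ms=T_ms)
        c1 = readout.chain_from_trace(t1)
        c2 = readout.chain_from_trace(t2)
        return gb.fit_distribution(c1), gb.fit_distribution(c2), c1, c2

    def test_uncoupled_networks_sample_own_likelihoods(self):
        f1, f2, c1, c2 = self._run(0.0, T_ms=8000.0)
        assert abs(wrap(f1.mean[0] + 10.0)) < 3.0
        assert abs(wrap(f2.mean[0] - 10.0)) < 3.0
        n = min(len(c1.post_burn_in()), len(c2.post_burn_in()))
        a, b = c1.post_burn_in()[:n, 0], c2.post_burn_in()[:n, 0]
        ok = ~np.isnan(a) & ~np.isnan(b)
        assert abs(np.corrcoef(a[ok], b[ok])[0, 1]) < 0.15

    def test_coupling_pulls_sample_means_together(self):
        gaps = []
        for w_mn in (0.0, 0.08, 0.15):
            f1, f2, *_ = self._run(w_mn)
            gaps.append(abs(wrap(f2.mean[0] - f1.mean[0])))
        assert gaps[0] > gaps[1] > gaps[2]
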