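import numpy as np
import pytest

from mrilnet.params import SimParams
from mrilnet.raster import SpikeRaster
from mrilnet.dynamics import (NetworkState, WeightState, poisson_spikes,
                              synaptic_filter, dendritic_potential,
                              attenuated_potential, response_function,
                              adapt_response_params, update_running_moments,
                              somatic_step, init_weights)


class TestPoissonSpikes:
    def test_count_statistics_match_poisson_mean(self):
        # 10 Hz for 100 s -> mean 1000 spikes; check over several seeds
        rates = np.full((100_000, 1), 0.01)
        counts = [len(poisson_spikes(rates, 1.0, seed)) for seed in range(20)]
        assert abs(np.mean(counts) - 1000) < 3 * np.sqrt(1000)

    def test_zero_rate_gives_empty_raster(self):
        r = poisson_spikes(np.zeros((1000, 5)), 1.0, 0)
        assert len(r) == 0

    def test_rate_dt_product_above_one_rejected(self):
        with pytest.raises(ValueError):
            poisson_spikes(np.full((10, 1), 0.01), 200.0, 0)

    def test_negative_rate_rejected(self):
        with pytest.raises(ValueError):
            poisson_spikes(np.full((10, 1), -0.1), 1.0, 0)

    def test_reproducible_given_seed(self):
        rates = np.full((5000, 3), 0.02)
        a = poisson_spikes(rates, 1.0, 7)
        b = poisson_spikes(rates, 1.0, 7)
        assert np.array_equal(a.neuron, b.neuron)
        assert np.array_equal(a.time, b.time)


class TestSynapticFilter:
    def test_single_spike_matches_closed_form(self):
        # one spike at t=0: I(t) = exp(-t/tau_syn)/(tau*tau_syn)
        p = SimParams(n_in=1, n_out=1, dt=1.0)
        raster = SpikeRaster([0], [0.0], 1, 200.0)
        I, _ = synaptic_filter(raster, p)
        t = np.arange(200) * p.dt
        expected = np.exp(-t / p.tau_syn) / (p.tau_mem * p.tau_syn)
        assert np.max(np.abs(I[:, 0] - expected)) < 1e-3
        # the area under I is 1/tau (trapezoid over the sampled trace)
        assert np.trapezoid(I[:, 0], dx=p.dt) == pytest.approx(
            1 / p.tau_mem, rel=2e-2)

    def test_no_spikes_gives_zero_traces(self):
        p = SimParams(n_in=2, n_out=1)
        raster = SpikeRaster([], [], 2, 100.0)
        I, e = synaptic_filter(raster, p)
        assert not I.any() and not e.any()

    def test_linearity_under_spike_doubling(self):
        p = SimParams(n_in=1, n_out=1)
        r1 = SpikeRaster([0, 0, 0], [3.0, 17.0, 40.0], 1, 100.0)
        bins = r1.to_bins(1.0) * 2
        r2 = SpikeRaster.from_bins(bins, 1.0)
        I1, e1 = synaptic_filter(r1, p)
        I2, e2 = synaptic_filter(r2, p)
        assert np.allclose(I2, 2 * I1, atol=1e-10)
        assert np.allclose(e2, 2 * e1, atol=1e-10)

    def test_superposition_of_rasters(self):
        p = SimParams(n_in=3, n_out=1)
        rng = np.random.default_rng(0)
        b1 = (rng.random((500, 3)) < 0.02).astype(np.uint8)
        b2 = (rng.random((500, 3)) < 0.02).astype(np.uint8)
        f = lambda b: synaptic_filter(SpikeRaster.from_bins(b, 1.0), p)
        I12, e12 = f(b1 + b2)
        I1, e1 = f(b1)
        I2, e2 = f(b2)
        assert np.allclose(I12, I1 + I2, atol=1e-10)
        assert np.allclose(e12, e1 + e2, atol=1e-10)


class TestDendriticPotential:
    def test_identity_weight_picks_single_entry(self):
        w = np.eye(3)
        e = np.array([0.0, 2.0, 0.0])
        assert dendritic_potential(w, e).tolist() == [0.0, 2.0, 0.0]

    def test_zero_weights_give_zero(self):
        assert not dendritic_potential(np.zeros((2, 4)), np.ones(4)).any()

    def test_matches_naive_double_loop(self, rng):
        w = rng.normal(size=(4, 7))
        e = rng.random(7)
        naive = np.array([sum(w[i, j] * e[j] for j in range(7))
                          for i in range(4)])
        assert np.allclose(dendritic_potential(w, e), naive, atol=1e-12)

    def test_shape_mismatch_raises(self):
        with pytest.raises(ValueError):
            dendritic_potential(np.zeros((2, 3)), np.ones(4))


class TestAttenuation:
    def test_printed_constants_give_0913(self):
        p = SimParams(n_in=1, n_out=1)  # g_d=0.7, tau=15
        assert p.alpha == pytest.approx(0.7 / (0.7 + 1 / 15), abs=1e-12)
        assert p.alpha == pytest.approx(0.9130, abs=5e-5)

    def test_zero_vector_maps_to_zero(self, params):
        assert not attenuated_potential(np.zeros(3), params).any()

    @pytest.mark.parametrize("g_d,tau", [(0.1, 5.0), (0.7, 15.0), (3.0, 50.0)])
    def test_attenuation_below_one(self, g_d, tau):
        p = SimParams(n_in=1, n_out=1, g_d=g_d, tau_mem=tau)
        assert 0 < p.alpha < 1


class TestResponseFunction:
    def test_midpoint_is_half_max(self):
        assert response_function(1.0, 5.0, 1.0, 0.05) == pytest.approx(0.025)

    def test_saturation_limits(self):
        assert response_function(-100.0, 5.0, 0.0, 0.05) == pytest.approx(0.0, abs=1e-12)
        assert response_function(100.0, 5.0, 0.0, 0.05) == pytest.approx(0.05)

    def test_standardized_baseline_value(self):
        # phi(mu)/phi0 = 1/(1+exp(beta0*theta0)) at the running mean
        p = SimParams(n_in=1, n_out=1)
        val = response_function(0.0, p.beta0, p.theta0, p.phi0) / p.phi0
        assert val == pytest.approx(1 / (1 + np.exp(p.beta0 * p.theta0)))

    def test_monotone_and_bounded(self, rng):
        x = np.sort(rng.normal(size=200))
        y = response_function(x, 5.0, 0.3, 0.05)
        assert np.all(np.diff(y) > 0)
        assert np.all((y > 0) & (y < 0.05))

    def test_nonpositive_beta_rejected(self):
        with pytest.raises(ValueError):
            response_function(0.0, -1.0, 0.0, 0.05)


class TestAdaptiveParams:
    def test_identity_regime(self, params):
        st = NetworkState.zeros(params)
        beta, theta = adapt_response_params(st, params)
        assert np.allclose(beta, params.beta0)
        assert np.allclose(theta, params.theta0)

    def test_direct_substitution(self):
        p = SimParams(n_in=1, n_out=1, beta0=5.0, theta0=1.0)
        st = NetworkState.zeros(p)
        st.mu = np.array([3.0])
        st.m2 = st.mu**2 + 4.0  # sigma = 2
        beta, theta = adapt_response_params(st, p)
        assert beta[0] == pytest.approx(2.5)
        assert theta[0] == pytest.approx(5.0)

    def test_equals_fixed_sigmoid_of_standardized_potential(self, rng):
        p = SimParams(n_in=1, n_out=4, t0=500.0)
        st = NetworkState.zeros(p)
        st.mu = rng.normal(size=4)
        st.m2 = st.mu**2 + rng.uniform(0.5, 2.0, size=4)**2
        sigma = st.sigma(p)
        u = rng.normal(size=4)
        beta, theta = adapt_response_params(st, p)
        direct = response_function(u, beta, theta, p.phi0)
        via_std = response_function((u - st.mu) / sigma, p.beta0, p.theta0,
                                    p.phi0)
        assert np.allclose(direct, via_std, atol=1e-12)

    def test_sigma_clamped_at_floor(self, params):
        st = NetworkState.zeros(params)
        st.m2 = st.mu**2  # zero variance
        beta, _ = adapt_response_params(st, params)
        assert np.all(beta == params.beta0 / params.sigma_floor)


class TestRunningMoments:
    def test_constant_input_collapses_to_floor_variance(self, params):
        st = NetworkState.zeros(params)
        u = np.full(params.n_out, 3.0)
        for _ in range(int(50 * params.t0 / params.dt)):
            st.mu, st.m2, _ = update_running_moments(st, u, params)
        sigma = st.sigma(params)
        assert np.allclose(st.mu, 3.0, atol=1e-3)
        assert np.allclose(sigma, params.sigma_floor)

    def test_recovers_gaussian_moments(self, rng):
        p = SimParams(n_in=1, n_out=1, t0=200.0)
        st = NetworkState.zeros(p)
        for _ in range(int(100 * p.t0 / p.dt)):
            u = rng.normal(2.0, 3.0, size=1)
            st.mu, st.m2, _ = update_running_moments(st, u, p)
        assert st.mu[0] == pytest.approx(2.0, abs=0.5)
        assert st.sigma(p)[0] == pytest.approx(3.0, rel=0.1)

    def test_scaling_homogeneity(self, rng):
        p = SimParams(n_in=1, n_out=1, t0=100.0)
        stream = rng.normal(1.0, 2.0, size=5000)
        out = []
        for k in (1.0, 3.0):
            st = NetworkState.zeros(p)
            for u in stream * k:
                st.mu, st.m2, _ = update_running_moments(
                    st, np.array([u]), p)
            out.append(st.sigma(p)[0])
        assert out[1] == pytest.approx(3 * out[0], rel=1e-6)


class TestSomaticStep:
    def test_relaxes_to_attenuated_dendritic_potential(self, params):
        st = NetworkState.zeros(params)
        st.v = np.array([1.0, -0.5, 2.0])
        w = WeightState(w=np.zeros((3, 20)), G=np.zeros((3, 3)), gmax=1.0)
        for _ in range(int(20 * params.tau_mem / params.dt)):
            st.u = somatic_step(st, w, params)
        assert np.allclose(st.u, params.alpha * st.v, rtol=1e-3)

    def test_exponential_decay_rate(self):
        p = SimParams(n_in=1, n_out=1, dt=0.01)
        st = NetworkState.zeros(p)
        st.u = np.array([1.0])
        w = WeightState(w=np.zeros((1, 1)), G=np.zeros((1, 1)), gmax=1.0)
        n = int(10 / p.dt)  # 10 ms
        for _ in range(n):
            st.u = somatic_step(st, w, p)
        rate = 1 / p.tau_mem + p.g_d
        assert st.u[0] == pytest.approx(np.exp(-rate * 10), rel=5e-2)

    def test_inhibition_never_increases_potential(self, params, rng):
        st = NetworkState.zeros(params)
        st.u = rng.normal(size=3)
        st.v = rng.normal(size=3)
        free = WeightState(w=np.zeros((3, 20)), G=np.zeros((3, 3)), gmax=1.0)
        G = rng.uniform(0.0, 1.0, size=(3, 3))
        np.fill_diagonal(G, 0.0)
        inhibited = WeightState(w=np.zeros((3, 20)), G=G, gmax=1.0)
        assert np.all(somatic_step(st, inhibited, params)
                      <= somatic_step(st, free, params))


def test_init_weights_scale_and_bounds(params, rng):
    p = SimParams(n_in=2000, n_out=10)
    ws = init_weights(p, gmax=0.3, rng=rng)
    assert ws.w.std() == pytest.approx(1 / np.sqrt(2000), rel=0.1)
    assert np.all(np.diag(ws.G) == 0)
    assert np.all((ws.G >= 0) & (ws.G <= 0.3))


def test_dt_stability_guard():
    with pytest.raises(ValueError):
        SimParams(n_in=1, n_out=1, dt=2.0, tau_syn=5.0)
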