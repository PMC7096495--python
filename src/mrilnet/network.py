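"""The competitive two-compartment network as a scikit-learn estimator.

:class:`MRILNetwork` is an unsupervised transformer: ``fit`` runs the
online weight updates (the regularized information-loss rule on the
feedforward weights and, optionally, symmetric anti-Hebbian plasticity on
the lateral inhibitory weights) while streaming the stimulus through the
network; ``transform`` freezes the learned weights and returns the somatic
firing-rate traces — the low-dimensional representation in which chunks,
communities, orientations or sources appear as assembly activations.

It accepts a :class:`~mrilnet.stimuli.StimulusProgram`, a
:class:`~mrilnet.raster.SpikeRaster`, or a plain (n_time_ms, n_in) array of
rates in events/ms.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from .params import LearningParams, SimParams, StdpParams, gmax_for
from .raster import SpikeRaster
from .stimuli import StimulusProgram
from .dynamics import WeightState, init_weights
from .engine import SimResult, run_network
from .evaluation import smooth_responses, soma_dendrite_correlation
from .learning import kl_poisson

__all__ = ["MRILNetwork"]


class MRILNetwork(BaseEstimator, TransformerMixin):
    """Competitive network of two-compartment neurons.

    Parameters
    ----------
    n_out : int
        Number of output neurons.
    tau_mem, g_d, tau_syn, e0, phi0, beta0, theta0, t0, dt, sigma_floor :
        Neuron/dynamics constants, see :class:`~mrilnet.params.SimParams`.
    eta, gamma : float
        Learning rate and L2 regularization of the feedforward update.
    g_noise : float
        Strength of the learning-noise variant; active when
        ``noise_enabled=True``.
    istdp : bool
        Learn the lateral inhibition by spike-timing plasticity.
    istdp_mode : {'anti_hebbian', 'conventional'}
    cp, cd, tau_p, tau_d : float
        Plasticity-kernel constants.
    gmax_coef : float
        Lateral weights are bounded by ``gmax_coef / sqrt(n_out)``.
    record_every : int
        Trace subsampling (in integration steps) during ``fit``.
    random_state : int or numpy Generator
        Seeds weight init, input-spike sampling, output-spike thinning and
        learning noise.

    Attributes
    ----------
    w_ : (n_out, n_in) ndarray — learned feedforward weights.
    G_ : (n_out, n_out) ndarray — learned lateral inhibition.
    mu_, sigma_ : (n_out,) ndarray — final adaptation state.
    n_in_ : int
    history_ : dict with the training soma–dendrite correlation curve.
    """

    def __init__(self, n_out=10, tau_mem=15.0, g_d=0.7, tau_syn=5.0,
                 e0=25.0, phi0=0.05, beta0=5.0, theta0=1.0, t0=5_000.0,
                 dt=1.0, sigma_floor=0.01,
                 eta=1e-5, gamma=0.5, g_noise=0.6, noise_enabled=False,
                 istdp=True, istdp_mode="anti_hebbian",
                 cp=0.00525, cd=0.0105, tau_p=40.0, tau_d=20.0,
                 gmax_coef=1.0, record_every=10, random_state=None):
        self.n_out = n_out
        self.tau_mem = tau_mem
        self.g_d = g_d
        self.tau_syn = tau_syn
        self.e0 = e0
        self.phi0 = phi0
        self.beta0 = beta0
        self.theta0 = theta0
        self.t0 = t0
        self.dt = dt
        self.sigma_floor = sigma_floor
        self.eta = eta
        self.gamma = gamma
        self.g_noise = g_noise
        self.noise_enabled = noise_enabled
        self.istdp = istdp
        self.istdp_mode = istdp_mode
        self.cp = cp
        self.cd = cd
        self.tau_p = tau_p
        self.tau_d = tau_d
        self.gmax_coef = gmax_coef
        self.record_every = record_every
        self.random_state = random_state

    # ---- parameter plumbing ------------------------------------------

    def _sim_params(self, n_in: int) -> SimParams:
        return SimParams(
            n_in=n_in, n_out=self.n_out, tau_mem=self.tau_mem, g_d=self.g_d,
            tau_syn=self.tau_syn, e0=self.e0, phi0=self.phi0,
            beta0=self.beta0, theta0=self.theta0, t0=self.t0, dt=self.dt,
            sigma_floor=self.sigma_floor)

    def _learning_params(self) -> LearningParams:
        return LearningParams(eta=self.eta, gamma=self.gamma,
                              g_noise=self.g_noise,
                              noise_enabled=self.noise_enabled)

    def _stdp_params(self) -> StdpParams:
        return StdpParams(cp=self.cp, cd=self.cd, tau_p=self.tau_p,
                          tau_d=self.tau_d,
                          gmax=gmax_for(self.n_out, self.gmax_coef),
                          mode=self.istdp_mode)

    def _rng(self) -> np.random.Generator:
        if isinstance(self.random_state, np.random.Generator):
            return self.random_state
        return np.random.default_rng(self.random_state)

    def _as_bins(self, X, rng: np.random.Generator) -> np.ndarray:
        if isinstance(X, StimulusProgram):
            return X.spike_bins(self.dt, rng)
        if isinstance(X, SpikeRaster):
            return X.to_bins(self.dt)
        X = np.asarray(X)
        if X.dtype == np.uint8 or X.dtype == bool:
            return X.astype(np.uint8)
        rates = np.atleast_2d(X.astype(np.float64))
        if np.any(rates < 0):
            raise ValueError("rates must be nonnegative")
        if np.any(rates * self.dt > 1.0):
            raise ValueError("rate*dt exceeds 1; decrease dt")
        rep = int(round(1.0 / self.dt))
        if rep > 1:
            rates = np.repeat(rates, rep, axis=0)
        return (rng.random(rates.shape) < rates * self.dt).astype(np.uint8)

    # ---- estimator API -----------------------------------------------

    def fit(self, X, y=None):
        """Train the network on a stimulus (program, raster or rate array)."""
        rng = self._rng()
        bins = self._as_bins(X, rng)
        params = self._sim_params(bins.shape[1])
        sp = self._stdp_params()
        weights = init_weights(params, sp.gmax, rng)
        res = run_network(bins, weights, params, self._learning_params(),
                          sp if self.istdp else None, rng, learn=True,
                          record_every=self.record_every)
        self._finalize(res, params)
        return self

    def partial_fit(self, X, y=None):
        """Continue training from the current weights (first call = fit)."""
        if not hasattr(self, "w_"):
            return self.fit(X)
        rng = self._rng()
        bins = self._as_bins(X, rng)
        params = self._sim_params(self.n_in_)
        sp = self._stdp_params()
        weights = WeightState(w=self.w_, G=self.G_, gmax=sp.gmax)
        res = run_network(bins, weights, params, self._learning_params(),
                          sp if self.istdp else None, rng, learn=True,
                          record_every=self.record_every)
        self._finalize(res, params)
        return self

    def _finalize(self, res: SimResult, params: SimParams) -> None:
        self.w_ = res.w
        self.G_ = res.G
        self.mu_ = res.mu
        self.sigma_ = res.sigma
        self.n_in_ = params.n_in
        window = max(int(15_000 / (params.dt * res.record_every)), 2)
        # learning curve: correlation between the observable somatic output
        # (sampled spike counts, lightly smoothed) and the dendritic
        # prediction rate, every 15 s of training
        spikes = smooth_responses(res.out_spikes.astype(float), 5)
        corr = soma_dendrite_correlation(spikes, res.phi_dend, window)
        # windowed empirical learning objective: mean soma-dendrite KL
        kl = kl_poisson(np.maximum(res.phi_som, 1e-12),
                        np.maximum(res.phi_dend, 1e-12))
        n_w = corr.shape[0]
        cost = np.array([kl[w * window:(w + 1) * window].mean(axis=0)
                         for w in range(n_w)])
        self.history_ = {
            "soma_dendrite_corr": np.nanmean(corr, axis=1),
            "soma_dendrite_corr_per_neuron": corr,
            "cost_per_neuron": cost,
            "rate_corr": np.nanmean(
                soma_dendrite_correlation(res.phi_som, res.phi_dend, window),
                axis=1),
            "checkpoint_ms": (np.arange(n_w) + 1) * window
            * params.dt * res.record_every,
        }

    def simulate(self, X, *, learn: bool = False, record_every: int = 1,
                 rng: np.random.Generator | None = None) -> SimResult:
        """Run the fitted network and return full recorded traces."""
        check_is_fitted(self, "w_")
        rng = rng if rng is not None else self._rng()
        bins = self._as_bins(X, rng)
        if bins.shape[1] != self.n_in_:
            raise ValueError(f"input has {bins.shape[1]} neurons, "
                             f"fitted for {self.n_in_}")
        params = self._sim_params(self.n_in_)
        sp = self._stdp_params()
        weights = WeightState(w=self.w_, G=self.G_, gmax=sp.gmax)
        return run_network(bins, weights, params,
                           self._learning_params() if learn else None,
                           sp if (learn and self.istdp) else None,
                           rng, learn=learn, record_every=record_every)

    def transform(self, X, smooth_bins: int = 10) -> np.ndarray:
        """Somatic firing-rate traces (n_time, n_out) with frozen weights."""
        res = self.simulate(X, learn=False, record_every=1)
        return smooth_responses(res.phi_som, smooth_bins)
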