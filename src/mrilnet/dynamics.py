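"""Core dynamics of the two-compartment neuron model.

The output neurons each have a dendritic compartment whose potential is a
weighted sum of filtered presynaptic spikes, and a somatic compartment that
leakily integrates the dendritic potential (coupling conductance ``g_d``)
while receiving lateral inhibition from the other output neurons.  The
somatic transfer function is a sigmoid whose slope and threshold track
running estimates of the mean and s.d. of the somatic potential, so that the
standardised potential û = (u − μ)/σ always drives a fixed sigmoid — the
adaptation that keeps firing in a high-information regime and blocks the
trivial all-zero solution of the learning rule.

All functions here are plain-numpy, one step or one trace at a time; the
jitted time loop in :mod:`mrilnet.engine` composes the same arithmetic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .params import SimParams
from .raster import SpikeRaster

__all__ = [
    "NetworkState",
    "WeightState",
    "poisson_spikes",
    "synaptic_filter",
    "dendritic_potential",
    "attenuated_potential",
    "response_function",
    "adapt_response_params",
    "update_running_moments",
    "somatic_step",
    "sample_output_spikes",
    "init_weights",
]


@dataclass
class NetworkState:
    """Per-neuron dynamical variables at one instant.

    ``u``/``v``: somatic and dendritic potentials (n_out,);
    ``mu``/``m2``: running first and second moment of u (n_out,), with
    ``sigma`` derived as sqrt(max(m2 − mu², floor²));
    ``I``/``e``: synaptic current and PSP trace per input neuron (n_in,).
    """

    u: np.ndarray
    v: np.ndarray
    mu: np.ndarray
    m2: np.ndarray
    I: np.ndarray
    e: np.ndarray

    @classmethod
    def zeros(cls, params: SimParams) -> "NetworkState":
        n_out, n_in = params.n_out, params.n_in
        return cls(
            u=np.zeros(n_out),
            v=np.zeros(n_out),
            mu=np.zeros(n_out),
            m2=np.ones(n_out),  # sigma starts at 1
            I=np.zeros(n_in),
            e=np.zeros(n_in),
        )

    def sigma(self, params: SimParams) -> np.ndarray:
        var = self.m2 - self.mu**2
        return np.sqrt(np.maximum(var, params.sigma_floor**2))


@dataclass
class WeightState:
    """Feedforward matrix w (n_out × n_in) and lateral inhibition G.

    G is nonnegative with zero diagonal and entries clipped to [0, gmax].
    """

    w: np.ndarray
    G: np.ndarray
    gmax: float

    def __post_init__(self) -> None:
        self.w = np.atleast_2d(np.asarray(self.w, dtype=np.float64))
        self.G = np.atleast_2d(np.asarray(self.G, dtype=np.float64))
        n_out = self.w.shape[0]
        if self.G.shape != (n_out, n_out):
            raise ValueError("G must be (n_out, n_out)")
        if not np.all(np.isfinite(self.w)):
            raise ValueError("w must be finite")
        if np.any(self.G < 0) or np.any(self.G > self.gmax + 1e-12):
            raise ValueError("G entries must lie in [0, gmax]")
        if np.any(np.diag(self.G) != 0):
            raise ValueError("G must have a zero diagonal")


def init_weights(params: SimParams, gmax: float, rng: np.random.Generator) -> WeightState:
    """Gaussian feedforward init with s.d. 1/sqrt(n_in); G uniform at gmax/2."""
    w = rng.normal(0.0, 1.0 / np.sqrt(params.n_in), size=(params.n_out, params.n_in))
    G = np.full((params.n_out, params.n_out), gmax / 2.0)
    np.fill_diagonal(G, 0.0)
    return WeightState(w=w, G=G, gmax=gmax)


def poisson_spikes(rates: np.ndarray, dt: float, seed) -> SpikeRaster:
    """Sample an inhomogeneous Poisson raster from a rate schedule.

    Parameters
    ----------
    rates : (n_bins, n_neurons) array, events/ms
        Per-bin instantaneous rates; each bin fires independently with
        probability ``rate * dt``.
    dt : float, ms
    seed : int or numpy.random.Generator
    """
    rates = np.atleast_2d(np.asarray(rates, dtype=np.float64))
    if np.any(rates < 0):
        raise ValueError("rates must be nonnegative")
    if np.any(rates * dt > 1.0):
        raise ValueError("rate*dt exceeds 1 somewhere; decrease dt")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    bins = (rng.random(rates.shape) < rates * dt).astype(np.uint8)
    return SpikeRaster.from_bins(bins, dt)


def synaptic_filter(raster: SpikeRaster, params: SimParams):
    """Filter a spike raster into synaptic current I and PSP trace e.

    Implements τ_syn·İ = −I + X/τ and ė = −e/τ + e0·I, where each delta
    spike injects 1/(τ·τ_syn) into I (unit area 1/τ under ∫I dt).  I decays
    exactly (exponential update); e uses forward Euler on the drive term.

    Returns
    -------
    I, e : (n_bins, n_neurons) arrays sampled at the end of each bin.
    """
    dt = params.dt
    X = raster.to_bins(dt).astype(np.float64)
    n_bins, n = X.shape
    I = np.zeros((n_bins, n))
    e = np.zeros((n_bins, n))
    dec_I = np.exp(-dt / params.tau_syn)
    jump = 1.0 / (params.tau_mem * params.tau_syn)
    cur_I = np.zeros(n)
    cur_e = np.zeros(n)
    for k in range(n_bins):
        cur_I = cur_I * dec_I + X[k] * jump
        cur_e = cur_e + dt * (-cur_e / params.tau_mem + params.e0 * cur_I)
        I[k] = cur_I
        e[k] = cur_e
    return I, e


def dendritic_potential(w: np.ndarray, e: np.ndarray) -> np.ndarray:
    """Dendritic potential v_i = Σ_j w_ij e_j."""
    w = np.asarray(w, dtype=np.float64)
    e = np.asarray(e, dtype=np.float64)
    if w.ndim != 2 or e.shape[-1] != w.shape[1]:
        raise ValueError(f"shape mismatch: w {w.shape} vs e {e.shape}")
    return e @ w.T if e.ndim > 1 else w @ e


def attenuated_potential(v: np.ndarray, params: SimParams) -> np.ndarray:
    """v* = α·v with α = g_D/(g_D + 1/τ): the somatic steady state for given v."""
    return params.alpha * np.asarray(v, dtype=np.float64)


def response_function(x, beta, theta, phi0: float) -> np.ndarray:
    """Sigmoidal rate φ(x) = φ0 / (1 + exp(β(θ − x))), strictly in (0, φ0)."""
    if phi0 <= 0:
        raise ValueError("phi0 must be > 0")
    beta = np.asarray(beta, dtype=np.float64)
    if np.any(beta <= 0):
        raise ValueError("beta must be > 0")
    x = np.asarray(x, dtype=np.float64)
    return phi0 / (1.0 + np.exp(beta * (theta - x)))


def adapt_response_params(state: NetworkState, params: SimParams):
    """Per-neuron slope and threshold: β_i = β0/σ_i, θ_i = μ_i + σ_i·θ0.

    With these, φ^som(u) equals the fixed sigmoid applied to the
    standardised potential û = (u − μ)/σ.
    """
    sigma = state.sigma(params)
    beta = params.beta0 / sigma
    theta = state.mu + sigma * params.theta0
    return beta, theta


def update_running_moments(state: NetworkState, u_new: np.ndarray,
                           params: SimParams):
    """Exponential-moving-average update of (mu, m2) with time constant t0.

    Returns the new (mu, m2, sigma).  σ is clamped below at sigma_floor.
    """
    a = params.dt / params.t0
    mu = state.mu + a * (u_new - state.mu)
    m2 = state.m2 + a * (u_new**2 - state.m2)
    sigma = np.sqrt(np.maximum(m2 - mu**2, params.sigma_floor**2))
    return mu, m2, sigma


def somatic_step(state: NetworkState, weights: WeightState,
                 params: SimParams) -> np.ndarray:
    """One Euler step of the somatic potential.

    u̇_i = −u_i/τ + g_D(−u_i + v_i) − Σ_j G_ij φ^som(u_j)/φ0, with the
    lateral term computed from instantaneous rates (not spikes).
    """
    beta, theta = adapt_response_params(state, params)
    rates = response_function(state.u, beta, theta, params.phi0)
    inh = weights.G @ (rates / params.phi0)
    du = (-state.u / params.tau_mem
          + params.g_d * (-state.u + state.v)
          - inh)
    return state.u + params.dt * du


def sample_output_spikes(rates: np.ndarray, dt: float, seed) -> SpikeRaster:
    """Poisson spike trains from somatic rate traces (drives iSTDP only)."""
    return poisson_spikes(rates, dt, seed)
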