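"""The dendritic weight update: minimization of regularized information loss.

The rule treats the somatic and (attenuated) dendritic potentials as the
rates of two Poisson processes and descends the time-averaged KL divergence
between them, plus an L2 penalty.  Because the somatic rate is standardised
by the running-moment adaptation, the soma can never be perfectly predicted
by the raw dendritic sigmoid, which rules out the trivial fixed point w = 0.
The resulting update has BCM form — prediction error times presynaptic
trace — but with a *stable* crossing at φ^som = φ^dend.

A noise-augmented variant replaces the somatic rate with a clipped,
Gaussian-perturbed version; it rescues source separation when cross-talk
between mixed inputs is weak.
"""

from __future__ import annotations

import numpy as np

from .params import LearningParams, SimParams
from .dynamics import response_function

__all__ = [
    "psi",
    "kl_poisson",
    "phi_dend",
    "mril_step",
    "noisy_mril_step",
    "clip_linear",
    "consistency_cost",
]


def phi_dend(v_star, params: SimParams) -> np.ndarray:
    """Dendritic prediction rate: the fixed sigmoid φ̂ applied to v*."""
    return response_function(v_star, params.beta0, params.theta0, params.phi0)


def psi(v_star, params: SimParams) -> np.ndarray:
    """Logarithmic slope of the dendritic sigmoid, ψ(x) = d/dx log φ̂(x).

    Closed form: β0·(1 − φ̂(x)/φ0); positive and decreasing, with limits β0
    at −∞ and 0 at +∞.
    """
    return params.beta0 * (1.0 - phi_dend(v_star, params) / params.phi0)


def kl_poisson(phi_a, phi_b) -> np.ndarray:
    """KL divergence between Poisson processes with rates phi_a and phi_b.

    D = φ_a·log(φ_a/φ_b) + φ_b − φ_a, nonnegative, zero iff equal.
    """
    phi_a = np.asarray(phi_a, dtype=np.float64)
    phi_b = np.asarray(phi_b, dtype=np.float64)
    if np.any(phi_a <= 0) or np.any(phi_b <= 0):
        raise ValueError("rates must be strictly positive")
    return phi_a * np.log(phi_a / phi_b) + phi_b - phi_a


def clip_linear(x, phi0: float) -> np.ndarray:
    """Piecewise-linear clip of a rate to [0, phi0]."""
    if phi0 <= 0:
        raise ValueError("phi0 must be > 0")
    return np.clip(np.asarray(x, dtype=np.float64), 0.0, phi0)


def _mril_delta(w_row, v_star, phi_som_eff, e, lp: LearningParams,
                params: SimParams) -> np.ndarray:
    err = (phi_som_eff - phi_dend(v_star, params)) / params.phi0
    return lp.eta * params.dt * (
        psi(v_star, params) * err * np.asarray(e, dtype=np.float64)
        - lp.gamma * np.asarray(w_row, dtype=np.float64)
    )


def mril_step(w_row, v_star, u, mu, sigma, e, lp: LearningParams,
              params: SimParams) -> np.ndarray:
    """One online update of a neuron's feedforward weight row.

    Δw = η·dt·( ψ(v*)·[φ^som(u) − φ̂(v*)]/φ0 · e − γ·w ), where φ^som uses
    the adaptive slope/threshold implied by (μ, σ) and φ̂ the fixed ones.
    φ^som is treated as a constant of the gradient (no derivative through
    the adaptation).
    """
    sigma = max(float(sigma), params.sigma_floor)
    beta = params.beta0 / sigma
    theta = mu + sigma * params.theta0
    phi_som = response_function(u, beta, theta, params.phi0)
    return _mril_delta(w_row, v_star, phi_som, e, lp, params)


def noisy_mril_step(w_row, v_star, u, mu, sigma, e, lp: LearningParams,
                    params: SimParams, seed=None, xi=None) -> np.ndarray:
    """MRIL step with the somatic rate replaced by f(φ^som + φ0·g·ξ).

    ξ is standard normal (drawn from ``seed`` unless supplied explicitly);
    f clips to [0, φ0] so that noise-dominated (negative) teaching signals
    are eliminated rather than driving depression.
    """
    sigma = max(float(sigma), params.sigma_floor)
    beta = params.beta0 / sigma
    theta = mu + sigma * params.theta0
    phi_som = response_function(u, beta, theta, params.phi0)
    if xi is None:
        rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
        xi = rng.standard_normal(np.shape(phi_som) or ())
    phi_eff = clip_linear(phi_som + params.phi0 * lp.g_noise * xi, params.phi0)
    return _mril_delta(w_row, v_star, phi_eff, e, lp, params)


def consistency_cost(u_trace, v_star_trace, params: SimParams,
                     mu=None, sigma=None) -> float:
    """Time-averaged soma–dendrite KL divergence (the learning objective).

    ``u_trace``/``v_star_trace``: (n_time,) or (n_time, n_out) aligned
    traces.  ``mu``/``sigma`` give the adaptation state per neuron (defaults
    0 and 1, the identity regime).
    """
    u = np.atleast_2d(np.asarray(u_trace, dtype=np.float64).T).T
    v = np.atleast_2d(np.asarray(v_star_trace, dtype=np.float64).T).T
    if u.shape != v.shape:
        raise ValueError("u and v* traces must be aligned")
    mu = np.zeros(u.shape[1]) if mu is None else np.asarray(mu, dtype=np.float64)
    sigma = np.ones(u.shape[1]) if sigma is None else np.asarray(sigma, dtype=np.float64)
    sigma = np.maximum(sigma, params.sigma_floor)
    beta = params.beta0 / sigma
    theta = mu + sigma * params.theta0
    phi_som = response_function(u, beta, theta, params.phi0)
    return float(np.mean(kl_poisson(phi_som, phi_dend(v, params))))
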