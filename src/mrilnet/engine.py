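"""Fixed-step simulation loop for the competitive two-compartment network.

Two implementations of the same arithmetic live here:

* :func:`run_network` — a numba-compiled kernel used by the estimator; all
  inner products are explicit loops so the floating-point evaluation order
  is fixed by the code.
* :func:`simulate_reference` — a plain-numpy step-by-step loop composed of
  the public per-step operations, kept as an executable specification; a
  test pins the two paths together to near machine precision.

Randomness (input spikes, output-spike thinning, learning noise) is drawn
*outside* the loop from a single ``numpy.random.Generator``, so both paths
consume identical random streams and a run is reproducible from one seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit

from .params import LearningParams, SimParams, StdpParams
from .dynamics import NetworkState, WeightState

__all__ = ["run_network", "simulate_reference", "SimResult"]


@dataclass
class SimResult:
    """Recorded traces (every ``record_every`` steps) and final state."""

    u: np.ndarray          # (n_rec, n_out) somatic potential
    v_star: np.ndarray     # (n_rec, n_out) attenuated dendritic potential
    phi_som: np.ndarray    # (n_rec, n_out) somatic rate, events/ms
    phi_dend: np.ndarray   # (n_rec, n_out) dendritic prediction rate
    out_spikes: np.ndarray  # (n_rec, n_out) somatic spike count per interval
    w: np.ndarray
    G: np.ndarray
    mu: np.ndarray
    sigma: np.ndarray
    record_every: int
    dt: float

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.u.shape[0]) * self.record_every * self.dt


@njit(cache=True, fastmath=True)
def _kernel(X, uni, xi, w, G, I, e, u, mu, m2,
            dt, tau, g_d, tau_syn, e0, phi0, beta0, theta0, t0, floor,
            eta, gamma, g_noise, learn_w, noise_on,
            istdp_on, sign, cp, cd, tau_p, tau_d, gmax,
            record_every,
            rec_u, rec_v, rec_som, rec_dend, rec_spk):
    n_steps, n_in = X.shape
    n_out = w.shape[0]
    alpha = g_d / (g_d + 1.0 / tau)
    dec_i = np.exp(-dt / tau_syn)
    jump = 1.0 / (tau * tau_syn)
    fp = np.exp(-dt / tau_p)
    fd = np.exp(-dt / tau_d)
    a_mom = dt / t0

    rates = np.empty(n_out)
    phid = np.empty(n_out)
    v_star = np.empty(n_out)
    sigma = np.empty(n_out)
    for i in range(n_out):
        sig = np.sqrt(max(m2[i] - mu[i] * mu[i], floor * floor))
        sigma[i] = sig
        rates[i] = phi0 / (1.0 + np.exp((beta0 / sig) * (mu[i] + sig * theta0 - u[i])))
    ap = np.zeros(n_out)
    ad = np.zeros(n_out)
    spk = np.zeros(n_out, dtype=np.uint8)

    for t in range(n_steps):
        for j in range(n_in):
            I[j] = I[j] * dec_i + X[t, j] * jump
            e[j] = e[j] + dt * (-e[j] / tau + e0 * I[j])
        for i in range(n_out):
            acc = 0.0
            for j in range(n_in):
                acc += w[i, j] * e[j]
            v_star[i] = alpha * acc
            inh = 0.0
            for k in range(n_out):
                inh += G[i, k] * rates[k] / phi0
            u[i] = u[i] + dt * (-u[i] / tau + g_d * (-u[i] + acc) - inh)
        for i in range(n_out):
            mu[i] += a_mom * (u[i] - mu[i])
            m2[i] += a_mom * (u[i] * u[i] - m2[i])
            sig = np.sqrt(max(m2[i] - mu[i] * mu[i], floor * floor))
            sigma[i] = sig
            rates[i] = phi0 / (1.0 + np.exp((beta0 / sig) * (mu[i] + sig * theta0 - u[i])))
            phid[i] = phi0 / (1.0 + np.exp(beta0 * (theta0 - v_star[i])))
        if learn_w:
            for i in range(n_out):
                if noise_on:
                    eff = rates[i] + phi0 * g_noise * xi[t, i]
                    if eff < 0.0:
                        eff = 0.0
                    elif eff > phi0:
                        eff = phi0
                else:
                    eff = rates[i]
                err = (eff - phid[i]) / phi0
                gain = eta * dt * (beta0 * (1.0 - phid[i] / phi0)) * err
                dec = eta * dt * gamma
                for j in range(n_in):
                    w[i, j] += gain * e[j] - dec * w[i, j]
        if istdp_on:
            for i in range(n_out):
                ap[i] *= fp
                ad[i] *= fd
                spk[i] = 1 if uni[t, i] < rates[i] * dt else 0
            for i in range(n_out):
                if spk[i] == 1:
                    for j in range(n_out):
                        k0 = sign * (cp * ap[j] - cd * ad[j])
                        G[i, j] += k0
                        G[j, i] += k0
            for i in range(n_out):
                if spk[i] == 1:
                    for j in range(i + 1, n_out):
                        if spk[j] == 1:
                            k0 = sign * (cp - cd)
                            G[i, j] += k0
                            G[j, i] += k0
            for i in range(n_out):
                if spk[i] == 1:
                    ap[i] += 1.0
                    ad[i] += 1.0
                G[i, i] = 0.0
                for j in range(n_out):
                    if G[i, j] < 0.0:
                        G[i, j] = 0.0
                    elif G[i, j] > gmax:
                        G[i, j] = gmax
        else:
            for i in range(n_out):
                spk[i] = 1 if uni[t, i] < rates[i] * dt else 0
        r = t // record_every
        for i in range(n_out):
            rec_spk[r, i] += spk[i]
        if t % record_every == 0:
            for i in range(n_out):
                rec_u[r, i] = u[i]
                rec_v[r, i] = v_star[i]
                rec_som[r, i] = rates[i]
                rec_dend[r, i] = phid[i]
    return sigma


def run_network(X: np.ndarray, weights: WeightState, params: SimParams,
                lp: LearningParams | None, sp: StdpParams | None,
                rng: np.random.Generator, *, learn: bool = True,
                state: NetworkState | None = None,
                record_every: int = 1) -> SimResult:
    """Simulate the network over a binned input spike array.

    Parameters
    ----------
    X : (n_steps, n_in) uint8
        Binned input spikes (counts per dt-bin).
    weights : WeightState
        Initial weights; not modified in place.
    lp : LearningParams or None
        Feedforward plasticity; ``None`` or ``learn=False`` freezes w.
    sp : StdpParams or None
        Lateral plasticity; ``None`` freezes G.
    rng : numpy.random.Generator
        Source of output-spike thinning and learning noise.
    state : NetworkState, optional
        Initial dynamical state (defaults to rest with σ = 1).
    record_every : int
        Trace subsampling in steps.
    """
    X = np.ascontiguousarray(X, dtype=np.uint8)
    n_steps = X.shape[0]
    if X.shape[1] != params.n_in:
        raise ValueError(f"X has {X.shape[1]} columns, expected n_in={params.n_in}")
    w = np.array(weights.w, dtype=np.float64, copy=True)
    G = np.array(weights.G, dtype=np.float64, copy=True)
    st = state if state is not None else NetworkState.zeros(params)
    I = st.I.copy(); e = st.e.copy(); u = st.u.copy()
    mu = st.mu.copy(); m2 = st.m2.copy()

    uni = rng.random((n_steps, params.n_out))
    learn_w = bool(learn and lp is not None)
    noise_on = bool(learn_w and lp is not None and lp.noise_enabled)
    if noise_on:
        xi = rng.standard_normal((n_steps, params.n_out))
    else:
        xi = np.zeros((1, params.n_out))
    istdp_on = bool(learn and sp is not None)
    spd = sp if sp is not None else StdpParams(gmax=weights.gmax)

    n_rec = (n_steps + record_every - 1) // record_every
    rec_u = np.empty((n_rec, params.n_out))
    rec_v = np.empty((n_rec, params.n_out))
    rec_som = np.empty((n_rec, params.n_out))
    rec_dend = np.empty((n_rec, params.n_out))
    rec_spk = np.zeros((n_rec, params.n_out), dtype=np.int64)

    lpd = lp if lp is not None else LearningParams()
    sigma = _kernel(
        X, uni, xi, w, G, I, e, u, mu, m2,
        params.dt, params.tau_mem, params.g_d, params.tau_syn, params.e0,
        params.phi0, params.beta0, params.theta0, params.t0,
        params.sigma_floor,
        lpd.eta, lpd.gamma, lpd.g_noise, learn_w, noise_on,
        istdp_on, spd.sign, spd.cp, spd.cd, spd.tau_p, spd.tau_d,
        weights.gmax, record_every,
        rec_u, rec_v, rec_som, rec_dend, rec_spk)
    return SimResult(u=rec_u, v_star=rec_v, phi_som=rec_som,
                     phi_dend=rec_dend, out_spikes=rec_spk,
                     w=w, G=G, mu=mu, sigma=np.asarray(sigma),
                     record_every=record_every, dt=params.dt)


def simulate_reference(X: np.ndarray, weights: WeightState, params: SimParams,
                       lp: LearningParams | None, sp: StdpParams | None,
                       rng: np.random.Generator, *, learn: bool = True,
                       record_every: int = 1) -> SimResult:
    """Plain-numpy executable specification of :func:`run_network`.

    Identical update order and random-stream consumption; intended for
    short runs and the cross-implementation test.
    """
    X = np.asarray(X, dtype=np.float64)
    n_steps, n_in = X.shape
    n_out = params.n_out
    if n_in != params.n_in:
        raise ValueError("X width must equal n_in")
    w = np.array(weights.w, dtype=np.float64, copy=True)
    G = np.array(weights.G, dtype=np.float64, copy=True)
    st = NetworkState.zeros(params)
    I, e, u, mu, m2 = st.I, st.e, st.u, st.mu, st.m2

    uni = rng.random((n_steps, n_out))
    learn_w = bool(learn and lp is not None)
    noise_on = bool(learn_w and lp is not None and lp.noise_enabled)
    xi = rng.standard_normal((n_steps, n_out)) if noise_on else np.zeros((n_steps, n_out))
    istdp_on = bool(learn and sp is not None)
    spd = sp if sp is not None else StdpParams(gmax=weights.gmax)

    alpha = params.alpha
    dec_i = np.exp(-params.dt / params.tau_syn)
    jump = 1.0 / (params.tau_mem * params.tau_syn)
    fp = np.exp(-params.dt / spd.tau_p)
    fd = np.exp(-params.dt / spd.tau_d)
    a_mom = params.dt / params.t0
    dt, phi0, beta0, theta0 = params.dt, params.phi0, params.beta0, params.theta0

    def phi_som(u_, mu_, sig_):
        return phi0 / (1.0 + np.exp((beta0 / sig_) * (mu_ + sig_ * theta0 - u_)))

    sigma = np.sqrt(np.maximum(m2 - mu**2, params.sigma_floor**2))
    rates = phi_som(u, mu, sigma)
    ap = np.zeros(n_out); ad = np.zeros(n_out)

    n_rec = (n_steps + record_every - 1) // record_every
    rec_spk = np.zeros((n_rec, n_out), dtype=np.int64)
    recs = []
    for t in range(n_steps):
        I = I * dec_i + X[t] * jump
        e = e + dt * (-e / params.tau_mem + params.e0 * I)
        v = w @ e
        v_star = alpha * v
        inh = G @ (rates / phi0)
        u = u + dt * (-u / params.tau_mem + params.g_d * (-u + v) - inh)
        mu = mu + a_mom * (u - mu)
        m2 = m2 + a_mom * (u * u - m2)
        sigma = np.sqrt(np.maximum(m2 - mu**2, params.sigma_floor**2))
        rates = phi_som(u, mu, sigma)
        phid = phi0 / (1.0 + np.exp(beta0 * (theta0 - v_star)))
        if learn_w:
            eff = rates if not noise_on else np.clip(
                rates + phi0 * lp.g_noise * xi[t], 0.0, phi0)
            err = (eff - phid) / phi0
            w = w + lp.eta * dt * (
                np.outer(beta0 * (1.0 - phid / phi0) * err, e) - lp.gamma * w)
        spikes = (uni[t] < rates * dt).astype(np.uint8)
        if istdp_on:
            ap = ap * fp
            ad = ad * fd
            kvec = spd.sign * (spd.cp * ap - spd.cd * ad)
            for i in np.nonzero(spikes)[0]:
                G[i, :] += kvec
                G[:, i] += kvec
            who = np.nonzero(spikes)[0]
            for a_i in range(len(who)):
                for b_i in range(a_i + 1, len(who)):
                    i, j = who[a_i], who[b_i]
                    G[i, j] += spd.sign * (spd.cp - spd.cd)
                    G[j, i] += spd.sign * (spd.cp - spd.cd)
            ap = ap + spikes
            ad = ad + spikes
            np.fill_diagonal(G, 0.0)
            np.clip(G, 0.0, weights.gmax, out=G)
        rec_spk[t // record_every] += spikes
        if t % record_every == 0:
            recs.append((u.copy(), v_star.copy(), rates.copy(), phid.copy()))
    stack = lambda k: np.array([r[k] for r in recs])
    return SimResult(u=stack(0), v_star=stack(1), phi_som=stack(2),
                     phi_dend=stack(3), out_spikes=rec_spk,
                     w=w, G=G, mu=mu, sigma=sigma,
                     record_every=record_every, dt=dt)
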