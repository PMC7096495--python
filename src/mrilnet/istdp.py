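"""Plasticity of lateral inhibitory weights.

The kernel is symmetric in the pre/post spike-time difference and
anti-Hebbian: near-synchronous firing depresses the inhibitory weight
(Cp < Cd at Δt = 0), so neurons responding to the same temporal feature
disinhibit each other and condense into assemblies, while asynchronous
pairs keep (or regain) mutual inhibition.  The sign-reversed "conventional"
kernel, in which synchrony strengthens inhibition, is retained as a control.
"""

from __future__ import annotations

import numpy as np

from .params import StdpParams
from .raster import SpikeRaster

__all__ = ["istdp_kernel", "apply_istdp", "apply_istdp_bruteforce",
           "kernel_table"]


def kernel_table(sp: StdpParams, t_max: float = 200.0,
                 dt: float = 1.0) -> np.ndarray:
    """Two-column (Δt, ΔG) table of the pairing kernel, for plotting."""
    dts = np.arange(-t_max, t_max + dt / 2, dt)
    return np.column_stack([dts, istdp_kernel(dts, sp)])


def istdp_kernel(delta_t, sp: StdpParams) -> np.ndarray:
    """Weight change for one spike pair with timing difference delta_t (ms).

    Anti-Hebbian: ΔG = Cp·exp(−|Δt|/τp) − Cd·exp(−|Δt|/τd); the
    conventional mode negates it.  Symmetric in Δt by construction.
    """
    adt = np.abs(np.asarray(delta_t, dtype=np.float64))
    k = sp.cp * np.exp(-adt / sp.tau_p) - sp.cd * np.exp(-adt / sp.tau_d)
    return sp.sign * k


def _check(G: np.ndarray, pre: SpikeRaster, post: SpikeRaster) -> np.ndarray:
    G = np.array(G, dtype=np.float64, copy=True)
    n = G.shape[0]
    if G.shape != (n, n) or pre.n_neurons != n or post.n_neurons != n:
        raise ValueError("G and rasters must agree on the population size")
    return G


def apply_istdp(G, pre_raster: SpikeRaster, post_raster: SpikeRaster,
                sp: StdpParams) -> np.ndarray:
    """All-to-all pairing update of G from a pre and a post spike raster.

    ``G[i, j]`` is the inhibitory weight from neuron j onto neuron i and is
    updated by every (post spike of i, pre spike of j) pair under the
    symmetric kernel, using two exponential traces per neuron (pairs beyond
    7·max(τp, τd) contribute < 1e-3 of the kernel and are what the traces
    implicitly truncate to zero only at infinity — the trace sum is exact).
    The result is clipped to [0, gmax] with a zero diagonal.

    Here both rasters live on the same output population; in the network,
    ``pre`` and ``post`` are the same sampled somatic spike trains.
    """
    G = _check(G, pre_raster, post_raster)
    n = G.shape[0]
    # merge events into one time-ordered stream tagged pre(0)/post(1)
    times = np.concatenate([pre_raster.time, post_raster.time])
    cells = np.concatenate([pre_raster.neuron, post_raster.neuron])
    kinds = np.concatenate([np.zeros(len(pre_raster), dtype=np.int64),
                            np.ones(len(post_raster), dtype=np.int64)])
    order = np.argsort(times, kind="stable")
    times, cells, kinds = times[order], cells[order], kinds[order]

    # per-neuron traces of past pre and post spikes at two decay constants
    pre_p = np.zeros(n); pre_d = np.zeros(n)
    post_p = np.zeros(n); post_d = np.zeros(n)
    t_last = 0.0
    for t, c, kind in zip(times, cells, kinds):
        if t > t_last:
            fp = np.exp(-(t - t_last) / sp.tau_p)
            fd = np.exp(-(t - t_last) / sp.tau_d)
            pre_p *= fp; post_p *= fp
            pre_d *= fd; post_d *= fd
            t_last = t
        if kind == 1:  # post spike of neuron c: pair with past pre spikes
            G[c, :] += sp.sign * (sp.cp * pre_p - sp.cd * pre_d)
        else:          # pre spike of neuron c: pair with past post spikes
            G[:, c] += sp.sign * (sp.cp * post_p - sp.cd * post_d)
        if kind == 0:
            pre_p[c] += 1.0; pre_d[c] += 1.0
        else:
            post_p[c] += 1.0; post_d[c] += 1.0
    np.fill_diagonal(G, 0.0)
    np.clip(G, 0.0, sp.gmax, out=G)
    np.fill_diagonal(G, 0.0)
    return G


def apply_istdp_bruteforce(G, pre_raster: SpikeRaster,
                           post_raster: SpikeRaster,
                           sp: StdpParams) -> np.ndarray:
    """O(n_pairs) reference: explicit sum of the kernel over all spike pairs.

    Pairs at zero time difference are counted once, matching the
    trace-based path in which the later event of a tie (stable event order)
    sees the earlier one.  Intended for small rasters in tests.
    """
    G = _check(G, pre_raster, post_raster)
    for i, t_post in zip(post_raster.neuron, post_raster.time):
        for j, t_pre in zip(pre_raster.neuron, pre_raster.time):
            if i == j:
                continue
            G[i, j] += float(istdp_kernel(t_pre - t_post, sp))
    np.fill_diagonal(G, 0.0)
    np.clip(G, 0.0, sp.gmax, out=G)
    np.fill_diagonal(G, 0.0)
    return G
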