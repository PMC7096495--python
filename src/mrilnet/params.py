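"""Model parameter containers with validation.

All times are in milliseconds and all rates in events/ms (so 10 Hz = 0.01).
The constants mirror the two-compartment model: a dendritic compartment that
integrates filtered presynaptic spikes and a somatic compartment coupled to it
with conductance ``g_d``, whose sigmoidal transfer function is standardised by
running estimates of the somatic-potential mean and s.d.
"""

from __future__ import annotations

from dataclasses import dataclass, field


@dataclass
class SimParams:
    """Scalar constants of the neuron and network dynamics.

    Parameters
    ----------
    n_in, n_out : int
        Population sizes of the Poisson input layer and the two-compartment
        output layer.
    tau_mem : float
        Somatic/dendritic membrane (and PSP) time constant τ, ms.
    g_d : float
        Dendro-somatic coupling conductance g_D (dimensionless).
    tau_syn : float
        Synaptic-current time constant, ms.  5 ms by default; 50 ms switches
        the model to a slow (NMDA-like) regime used for overlapping chunks.
    e0 : float
        Unit PSP amplitude.
    phi0 : float
        Maximal firing rate of the sigmoidal response function, events/ms.
    beta0 : float
        Baseline sigmoid slope.
    theta0 : float
        Baseline sigmoid threshold in units of the standardised potential.
    t0 : float
        Averaging window (ms) of the running mean/variance of the somatic
        potential, realised as an exponential moving average.
    dt : float
        Integration step, ms.
    sigma_floor : float
        Lower clamp on the running s.d. (guards the 1/σ slope).
    """

    n_in: int = 500
    n_out: int = 10
    tau_mem: float = 15.0
    g_d: float = 0.7
    tau_syn: float = 5.0
    e0: float = 25.0
    phi0: float = 0.05
    beta0: float = 5.0
    theta0: float = 1.0
    t0: float = 5_000.0
    dt: float = 1.0
    sigma_floor: float = 0.01

    def __post_init__(self) -> None:
        for name in ("tau_mem", "tau_syn", "e0", "phi0", "beta0", "t0", "dt"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if self.sigma_floor <= 0:
            raise ValueError("sigma_floor must be strictly positive")
        if self.n_in < 1 or self.n_out < 1:
            raise ValueError("population sizes must be >= 1")
        if self.dt > min(self.tau_syn, self.tau_mem) / 5.0:
            raise ValueError(
                f"dt={self.dt} too coarse: must be <= min(tau_syn, tau_mem)/5 "
                f"= {min(self.tau_syn, self.tau_mem) / 5.0}"
            )

    @property
    def alpha(self) -> float:
        """Attenuation factor α = g_D/(g_D + g_L) with g_L = 1/τ."""
        return self.g_d / (self.g_d + 1.0 / self.tau_mem)


@dataclass
class LearningParams:
    """Hyperparameters of the regularized information-loss weight update.

    ``eta`` is the learning rate per ms, ``gamma`` the L2 weight-decay
    strength, ``g_noise`` the strength of the Gaussian rate noise injected
    into the somatic teaching signal (0.6 where the noisy variant is used),
    and ``noise_enabled`` switches that variant on.
    """

    eta: float = 1e-5
    gamma: float = 0.5
    g_noise: float = 0.6
    noise_enabled: bool = False

    def __post_init__(self) -> None:
        if self.eta <= 0:
            raise ValueError("eta must be > 0")
        if self.gamma < 0:
            raise ValueError("gamma must be >= 0")
        if self.g_noise < 0:
            raise ValueError("g_noise must be >= 0")


@dataclass
class StdpParams:
    """Constants of the symmetric plasticity kernel on lateral inhibition.

    The anti-Hebbian kernel ``Cp·exp(−|Δt|/τp) − Cd·exp(−|Δt|/τd)`` is
    negative near synchrony (depression dominates), so co-active neurons
    disinhibit each other; ``mode='conventional'`` negates the kernel, the
    control in which synchrony strengthens inhibition.
    """

    cp: float = 0.00525
    cd: float = 0.0105
    tau_p: float = 40.0
    tau_d: float = 20.0
    gmax: float = 1.0
    mode: str = "anti_hebbian"

    def __post_init__(self) -> None:
        for name in ("cp", "cd", "tau_p", "tau_d", "gmax"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if self.mode not in ("anti_hebbian", "conventional"):
            raise ValueError("mode must be 'anti_hebbian' or 'conventional'")

    @property
    def sign(self) -> float:
        return 1.0 if self.mode == "anti_hebbian" else -1.0


def gmax_for(n_out: int, coef: float = 1.0) -> float:
    """Upper bound on inhibitory weights, scaling as coef/sqrt(n_out)."""
    if n_out < 1:
        raise ValueError("n_out must be >= 1")
    return coef / n_out**0.5
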