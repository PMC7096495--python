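"""Experiment presets and the end-to-end runner.

Each preset reproduces one of the study conditions at desk scale: a
stimulus generator, network hyperparameters, a training duration and the
metrics evaluated on a held-out segment of the same stimulus stream.  All
randomness descends from a single master seed; outputs carry the resolved
configuration and its hash for provenance.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import stimuli
from .network import MRILNetwork
from .evaluation import (pc_variance, reference_correlation,
                         selectivity_assignment, smooth_responses,
                         separation_score, decode_sources, negentropy,
                         source_assignment)

__all__ = ["ExperimentPreset", "PRESETS", "get_preset", "run_experiment",
           "save_weights", "load_weights", "bss_program"]


@dataclass
class ExperimentPreset:
    """A runnable experiment: stimulus + network + durations + metrics."""

    name: str
    description: str
    stimulus: dict              # generator name + kwargs
    net: dict                   # MRILNetwork kwargs
    train_ms: float
    eval_ms: float
    metrics: tuple = ()

    def config(self) -> dict:
        return {"name": self.name, "stimulus": self.stimulus,
                "net": self.net, "train_ms": self.train_ms,
                "eval_ms": self.eval_ms}

    def with_overrides(self, **over) -> "ExperimentPreset":
        cfg = self.config()
        out = ExperimentPreset(self.name, self.description,
                               dict(self.stimulus), dict(self.net),
                               self.train_ms, self.eval_ms, self.metrics)
        for key, val in over.items():
            parts = key.split(".")
            if len(parts) == 1 and hasattr(out, parts[0]) and parts[0] in (
                    "train_ms", "eval_ms"):
                setattr(out, parts[0], float(val))
            elif parts[0] == "net" and len(parts) == 2:
                out.net[parts[1]] = val
            elif parts[0] == "stimulus" and len(parts) == 2:
                out.stimulus[parts[1]] = val
            else:
                raise KeyError(f"unknown config path: {key!r}")
        return out


def bss_program(seed, *, duration_s=160.0, correlation_mode="dependent",
                theta=None, n_in=500, max_rate=0.01, sample_rate=100.0):
    """Mixtures of two synthetic correlated sources encoded as input rates.

    Returns the stimulus program (labels = index of the momentarily
    dominant source, −1 when both are quiet) with the true source and
    mixture envelopes stashed in ``meta``.
    """
    s1, s2 = stimuli.synth_correlated_sources(
        duration_s=duration_s, sample_rate=sample_rate,
        correlation_mode=correlation_mode, seed=seed)
    m1, m2, cfg = stimuli.mix_sources(s1, s2, theta)
    prog = stimuli.amplitude_to_rate([m1, m2], n_in=n_in, fs=sample_rate,
                                     max_rate=max_rate)
    # per-ms dominant-source labels for assembly discovery
    n_bins = prog.labels.shape[0]
    t_bins = (np.arange(n_bins) + 0.5) / 1000.0
    t_sig = np.arange(len(s1)) / sample_rate
    e1 = np.interp(t_bins, t_sig, stimuli.envelope_of(s1, sample_rate))
    e2 = np.interp(t_bins, t_sig, stimuli.envelope_of(s2, sample_rate))
    lab = np.where(e1 >= e2, 0, 1)
    quiet = np.maximum(e1, e2) < 0.1 * max(e1.max(), e2.max())
    lab[quiet] = -1
    prog.labels = lab
    prog.meta.update({"kind": "bss", "crosstalk": cfg.crosstalk,
                      "theta": cfg.theta,
                      "sources_env": np.vstack([e1, e2]),
                      "mixtures_env": np.vstack(
                          [np.interp(t_bins, t_sig,
                                     stimuli.envelope_of(m, sample_rate))
                           for m in (m1, m2)])})
    return prog


_STIMULUS_FACTORIES = {
    "frozen_pattern": stimuli.frozen_pattern_stream,
    "chunk_chars": stimuli.chunk_char_stream,
    "community_walk": stimuli.community_walk_stream,
    "bar_images": stimuli.bar_image_stream,
    "bss": bss_program,
}


PRESETS: dict[str, ExperimentPreset] = {}


def _register(p: ExperimentPreset) -> None:
    PRESETS[p.name] = p


_register(ExperimentPreset(
    name="fig1_single_neuron",
    description="One two-compartment neuron learns one of three frozen "
                "spatiotemporal patterns embedded in irregular input.",
    stimulus={"kind": "frozen_pattern", "n_in": 500, "n_patterns": 3,
              "base_rate": 0.01, "occupancy": 0.5, "assembly_fraction": 1.0},
    net={"n_out": 1, "istdp": False, "eta": 3e-5, "gamma": 0.5},
    train_ms=360_000.0, eval_ms=60_000.0,
    metrics=("selectivity", "learning_curve")))

_register(ExperimentPreset(
    name="fig2_assemblies",
    description="Competitive network + inhibitory plasticity forms "
                "chunk-specific cell assemblies.",
    stimulus={"kind": "frozen_pattern", "n_in": 500, "n_patterns": 3,
              "base_rate": 0.01, "occupancy": 0.5, "assembly_fraction": 1.0},
    net={"n_out": 10, "istdp": True, "eta": 3e-5, "gamma": 0.5,
         "gmax_coef": 0.7},
    train_ms=360_000.0, eval_ms=60_000.0,
    metrics=("selectivity", "assembly_G", "reference_correlation",
             "learning_curve")))

_register(ExperimentPreset(
    name="fig3_detection",
    description="Detection of a minimal cell assembly: only a fraction of "
                "inputs participate in the recurring pattern.",
    stimulus={"kind": "frozen_pattern", "n_in": 500, "n_patterns": 1,
              "base_rate": 0.01, "occupancy": 0.5, "assembly_fraction": 0.10},
    net={"n_out": 5, "istdp": True, "eta": 1e-5, "gamma": 0.2,
         "gmax_coef": 0.7},
    train_ms=900_000.0, eval_ms=60_000.0,
    metrics=("pattern_correlation",)))

_register(ExperimentPreset(
    name="fig4_chunks",
    description="Chunking of a random character sequence built from three "
                "disjoint four-character chunks.",
    stimulus={"kind": "chunk_chars", "chunks": ["abcd", "efgh", "ijkl"],
              "n_in": 1000},
    net={"n_out": 10, "istdp": True, "eta": 3e-5, "gamma": 0.5,
         "gmax_coef": 0.7},
    train_ms=300_000.0, eval_ms=60_000.0,
    metrics=("selectivity", "reference_correlation", "pc_variance")))

_register(ExperimentPreset(
    name="fig4_overlap",
    description="Chunking of partially overlapping chunks; requires the "
                "slow (50 ms) synaptic time constant.",
    stimulus={"kind": "chunk_chars", "chunks": ["abcd", "befg", "ehij"],
              "n_in": 1000},
    net={"n_out": 10, "istdp": True, "eta": 3e-5, "gamma": 0.5,
         "gmax_coef": 0.7, "tau_syn": 50.0},
    train_ms=300_000.0, eval_ms=60_000.0,
    metrics=("selectivity", "reference_correlation", "pc_variance")))

_register(ExperimentPreset(
    name="fig5_community",
    description="Random walk on a 3-community graph; assemblies should "
                "track temporal communities despite uniform transitions.",
    stimulus={"kind": "community_walk", "n_in": 1000, "steps": 12000},
    net={"n_out": 10, "istdp": True, "eta": 3e-5, "gamma": 0.5,
         "gmax_coef": 0.7, "tau_syn": 50.0},
    train_ms=300_000.0, eval_ms=60_000.0,
    metrics=("selectivity", "reference_correlation")))

_register(ExperimentPreset(
    name="fig6_orientation",
    description="Orientation map from sequences of noisy oriented-bar "
                "images.",
    stimulus={"kind": "bar_images", "image_px": 16, "n_orientations": 8,
              "noise_level": 0.2, "n_images": 4000},
    net={"n_out": 20, "istdp": True, "eta": 3e-5, "gamma": 0.5,
         "gmax_coef": 0.7},
    train_ms=240_000.0, eval_ms=40_000.0,
    metrics=("selectivity",)))

_register(ExperimentPreset(
    name="fig7_bss",
    description="Blind separation of two correlated synthetic sources "
                "mixed with the fixed [[1, .5], [.5, 1]] matrix.",
    stimulus={"kind": "bss", "duration_s": 160.0,
              "correlation_mode": "dependent"},
    net={"n_out": 10, "istdp": True, "eta": 3e-5, "gamma": 0.5,
         "gmax_coef": 0.7},
    train_ms=100_000.0, eval_ms=60_000.0,
    metrics=("bss",)))

_register(ExperimentPreset(
    name="fig8_crosstalk",
    description="Separation quality vs cross-talk tan(theta), with the "
                "noise-augmented learning rule as rescue.",
    stimulus={"kind": "bss", "duration_s": 160.0, "theta": 0.3,
              "correlation_mode": "dependent"},
    net={"n_out": 10, "istdp": True, "eta": 3e-5, "gamma": 0.5,
         "gmax_coef": 0.7, "noise_enabled": False},
    train_ms=100_000.0, eval_ms=60_000.0,
    metrics=("bss",)))


def get_preset(name: str) -> ExperimentPreset:
    try:
        return PRESETS[name]
    except KeyError:
        raise KeyError(f"unknown preset {name!r}; available: "
                       f"{sorted(PRESETS)}") from None


def make_stimulus(preset: ExperimentPreset, seed: int):
    kwargs = dict(preset.stimulus)
    kind = kwargs.pop("kind")
    factory = _STIMULUS_FACTORIES[kind]
    total_ms = preset.train_ms + preset.eval_ms
    if kind == "frozen_pattern":
        kwargs.setdefault("duration_ms", total_ms)
    elif kind == "chunk_chars":
        kwargs.setdefault("duration_ms", total_ms)
    elif kind == "community_walk":
        kwargs.setdefault("steps", int(math.ceil(total_ms / 30.0)))
    elif kind == "bar_images":
        kwargs.setdefault("n_images", int(math.ceil(total_ms / 70.0)))
    elif kind == "bss":
        kwargs.setdefault("duration_s", total_ms / 1000.0)
    return factory(seed=seed, **kwargs)


# ---------------------------------------------------------------------------
# metric evaluation


def _metrics_for(preset: ExperimentPreset, net: MRILNetwork, test,
                 rng: np.random.Generator) -> dict[str, float]:
    out: dict[str, float] = {}
    res = net.simulate(test, record_every=1, rng=rng)
    r = smooth_responses(res.phi_som, 10)
    labels = test.labels
    want = set(preset.metrics)

    if want & {"selectivity", "reference_correlation", "assembly_G"}:
        assig = selectivity_assignment(r, labels)
        out["n_assemblies"] = float(len(set(assig) - {-1}))
        out["n_others"] = float(np.sum(assig == -1))
        for j, a in enumerate(assig):
            out[f"preferred_chunk_neuron{j}"] = float(a)
    if "reference_correlation" in want:
        best, _, _ = reference_correlation(r, labels, assig)
        for c, v in best.items():
            out[f"reference_correlation_chunk{c}"] = float(v)
    if "assembly_G" in want:
        same = (assig[:, None] == assig[None, :]) & (assig[:, None] != -1)
        np.fill_diagonal(same, False)
        off = ~same & ~np.eye(len(assig), dtype=bool)
        out["within_assembly_G"] = float(net.G_[same].mean()) if same.any() else float("nan")
        out["between_assembly_G"] = float(net.G_[off].mean())
    if "pc_variance" in want:
        fr = pc_variance(smooth_responses(res.phi_som, 50))
        out["pc_top3_percent"] = float(100.0 * fr[:3].sum())
    if "pattern_correlation" in want:
        best, _, _ = reference_correlation(r, labels, per_neuron=True)
        out["pattern_correlation"] = float(best[0])
    if "learning_curve" in want:
        curve = net.history_["soma_dendrite_corr"]
        out["soma_dendrite_corr_first"] = float(curve[0])
        out["soma_dendrite_corr_last"] = float(curve[-1])
    if "bss" in want:
        src = test.meta["sources_env"]
        assig = source_assignment(res.phi_som, list(src))
        mix = test.meta["mixtures_env"]
        try:
            dec = decode_sources(res.phi_som, assig)
            score = separation_score(dec, list(src))
        except ValueError:
            score = np.array([np.nan, np.nan])
        out["separation_corr_src0"] = float(score[0])
        out["separation_corr_src1"] = float(score[1])
        base = separation_score(list(mix), list(src))
        out["mixture_corr_src0"] = float(base[0])
        out["mixture_corr_src1"] = float(base[1])
        for k, e in enumerate(src):
            s = (e - e.mean()) / (e.std() or 1.0)
            out[f"negentropy_src{k}"] = float(negentropy(s))
    return out


def run_experiment(preset, seed: int, out_dir=None, overrides=None):
    """Run one preset end to end; returns (metrics dict, tidy DataFrame).

    Deterministic given ``seed``.  When ``out_dir`` is given, writes
    ``metrics.csv`` (tidy: experiment, seed, metric, value), weight
    snapshots, the learning curve and the resolved configuration.
    """
    if isinstance(preset, str):
        preset = get_preset(preset)
    if overrides:
        preset = preset.with_overrides(**overrides)
    cfg = preset.config()
    cfg_hash = hashlib.sha256(
        json.dumps(cfg, sort_keys=True, default=str).encode()).hexdigest()[:12]

    rng = np.random.default_rng(seed)
    stim_seed = int(rng.integers(0, 2**31 - 1))
    net_seed = int(rng.integers(0, 2**31 - 1))
    eval_seed = int(rng.integers(0, 2**31 - 1))

    prog = make_stimulus(preset, stim_seed)
    train = prog.time_slice(0, preset.train_ms)
    test = prog.time_slice(preset.train_ms, preset.train_ms + preset.eval_ms)
    net = MRILNetwork(random_state=net_seed, **preset.net)
    net.fit(train)
    metrics = _metrics_for(preset, net, test, np.random.default_rng(eval_seed))

    df = pd.DataFrame([{"experiment": preset.name, "seed": seed,
                        "metric": k, "value": v}
                       for k, v in sorted(metrics.items())])
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        df.to_csv(out / "metrics.csv", index=False)
        save_weights(net, out / "weights")
        curve = net.history_
        rows = []
        per_corr = curve["soma_dendrite_corr_per_neuron"]
        per_cost = curve["cost_per_neuron"]
        for w, t_ms in enumerate(curve["checkpoint_ms"]):
            for j in range(per_corr.shape[1]):
                rows.append({"time_ms": t_ms, "neuron": j,
                             "cost": per_cost[w, j],
                             "soma_dendrite_correlation": per_corr[w, j]})
        pd.DataFrame(rows).to_csv(out / "learning_curve.csv", index=False)
        with open(out / "config.json", "w") as fh:
            json.dump({"config": cfg, "config_hash": cfg_hash,
                       "seed": seed}, fh, indent=2, default=str)
    return metrics, df


# ---------------------------------------------------------------------------
# weight serialization (lossless round trip)

_FMT = "%.17g"


def save_weights(net: MRILNetwork, prefix) -> None:
    """Write w/G/adaptation state as CSV plus a JSON descriptor."""
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    np.savetxt(f"{prefix}_w.csv", net.w_, delimiter=",", fmt=_FMT)
    np.savetxt(f"{prefix}_G.csv", net.G_, delimiter=",", fmt=_FMT)
    np.savetxt(f"{prefix}_adapt.csv", np.vstack([net.mu_, net.sigma_]),
               delimiter=",", fmt=_FMT)
    with open(f"{prefix}_meta.json", "w") as fh:
        json.dump({"format_version": 1, "n_out": int(net.w_.shape[0]),
                   "n_in": int(net.w_.shape[1]),
                   "params": net.get_params()}, fh, indent=2, default=str)


def load_weights(prefix, net: MRILNetwork | None = None) -> MRILNetwork:
    """Restore a fitted network from :func:`save_weights` output.

    With ``net`` given, weights are loaded into it (shapes must match);
    otherwise a network is rebuilt from the stored hyperparameters.
    """
    prefix = Path(prefix)
    with open(f"{prefix}_meta.json") as fh:
        meta = json.load(fh)
    if meta.get("format_version") != 1:
        raise ValueError(f"unsupported weight-file version: "
                         f"{meta.get('format_version')}")
    w = np.atleast_2d(np.loadtxt(f"{prefix}_w.csv", delimiter=","))
    G = np.atleast_2d(np.loadtxt(f"{prefix}_G.csv", delimiter=","))
    adapt = np.atleast_2d(np.loadtxt(f"{prefix}_adapt.csv", delimiter=","))
    if net is None:
        params = meta["params"]
        params["random_state"] = None if params.get("random_state") in (
            None, "None") else int(params["random_state"])
        for key in ("n_out",):
            params[key] = int(params[key])
        for key in params:
            if isinstance(params[key], str) and params[key] not in (
                    "anti_hebbian", "conventional"):
                try:
                    params[key] = float(params[key])
                except ValueError:
                    pass
        net = MRILNetwork(**params)
    if getattr(net, "n_out", w.shape[0]) != w.shape[0]:
        raise ValueError(f"weight shape {w.shape} does not match "
                         f"n_out={net.n_out}")
    if hasattr(net, "n_in_") and net.n_in_ != w.shape[1]:
        raise ValueError(f"weight shape {w.shape} does not match "
                         f"fitted n_in={net.n_in_}")
    net.w_ = w
    net.G_ = G
    net.mu_ = adapt[0]
    net.sigma_ = adapt[1]
    net.n_in_ = w.shape[1]
    net.history_ = {"soma_dendrite_corr": np.array([]),
                    "rate_corr": np.array([]),
                    "checkpoint_ms": np.array([])}
    return net
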