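"""Spike rasters: the universal event format for input and output spikes.

A :class:`SpikeRaster` is a list of ``(neuron_index, spike_time_ms)`` events
over a population, canonically sorted by time.  Rasters round-trip through a
two-column whitespace text format with a one-line header, and convert to and
from dense binned arrays for the fixed-step simulator.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np

__all__ = ["SpikeRaster"]


@dataclass
class SpikeRaster:
    """Timestamped spikes of a population.

    Attributes
    ----------
    neuron : ndarray of int
        Neuron index of each event, in ``[0, n_neurons)``.
    time : ndarray of float
        Spike time of each event in ms, in ``[0, duration)``; events are
        sorted by time (ties broken by neuron index).
    n_neurons : int
    duration : float
        Extent of the observation window in ms.
    """

    neuron: np.ndarray
    time: np.ndarray
    n_neurons: int
    duration: float

    def __post_init__(self) -> None:
        self.neuron = np.asarray(self.neuron, dtype=np.int64).ravel()
        self.time = np.asarray(self.time, dtype=np.float64).ravel()
        if self.neuron.shape != self.time.shape:
            raise ValueError("neuron and time arrays must have equal length")
        if self.n_neurons < 1 or self.duration <= 0:
            raise ValueError("need n_neurons >= 1 and duration > 0")
        if self.neuron.size:
            if self.neuron.min() < 0 or self.neuron.max() >= self.n_neurons:
                raise ValueError("neuron index out of range")
            if self.time.min() < 0 or self.time.max() >= self.duration:
                raise ValueError("spike time out of [0, duration)")
        if self.time.size and np.any(np.diff(self.time) < 0):
            order = np.lexsort((self.neuron, self.time))
            self.neuron = self.neuron[order]
            self.time = self.time[order]

    def __len__(self) -> int:
        return self.neuron.size

    # ---- conversions -------------------------------------------------

    def to_bins(self, dt: float) -> np.ndarray:
        """Return a dense (n_bins, n_neurons) uint8 spike-count array."""
        n_bins = int(round(self.duration / dt))
        bins = np.zeros((n_bins, self.n_neurons), dtype=np.uint8)
        if self.neuron.size:
            idx = np.minimum((self.time / dt).astype(np.int64), n_bins - 1)
            np.add.at(bins, (idx, self.neuron), 1)
        return bins

    @classmethod
    def from_bins(cls, bins: np.ndarray, dt: float) -> "SpikeRaster":
        bins = np.asarray(bins)
        t_idx, n_idx = np.nonzero(bins)
        counts = bins[t_idx, n_idx].astype(np.int64)
        neuron = np.repeat(n_idx, counts)
        time = np.repeat(t_idx * dt, counts).astype(np.float64)
        return cls(neuron, time, n_neurons=bins.shape[1],
                   duration=bins.shape[0] * dt)

    def counts(self) -> np.ndarray:
        """Spike count per neuron."""
        return np.bincount(self.neuron, minlength=self.n_neurons)

    # ---- text I/O ----------------------------------------------------

    def to_text(self) -> str:
        buf = io.StringIO()
        buf.write(f"# n_neurons={self.n_neurons} "
                  f"duration_ms={float(self.duration)!r}\n")
        for n, t in zip(self.neuron.tolist(), self.time.tolist()):
            buf.write(f"{n} {t!r}\n")
        return buf.getvalue()

    def save(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(self.to_text())

    @classmethod
    def from_text(cls, text: str) -> "SpikeRaster":
        lines = text.strip().splitlines()
        if not lines or not lines[0].startswith("#"):
            raise ValueError("missing raster header line")
        header = dict(kv.split("=") for kv in lines[0][1:].split())
        n_neurons = int(header["n_neurons"])
        duration = float(header["duration_ms"])
        neuron, time = [], []
        for line in lines[1:]:
            if not line.strip():
                continue
            n, t = line.split()
            neuron.append(int(n))
            time.append(float(t))
        return cls(np.array(neuron, dtype=np.int64),
                   np.array(time, dtype=np.float64), n_neurons, duration)

    @classmethod
    def load(cls, path) -> "SpikeRaster":
        with open(path) as fh:
            return cls.from_text(fh.read())
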