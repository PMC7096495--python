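"""Stimulus generators: rate schedules plus ground-truth labels.

Every generator returns a :class:`StimulusProgram` — a per-ms rate schedule
for the input population together with a per-ms label track (chunk identity,
temporal community, orientation, or dominant source) used only by the
evaluation metrics, never by the network.  Generators that embed *frozen*
spatiotemporal patterns (identical spike realizations at every occurrence)
also carry an explicit spike raster, since a rate schedule cannot express
frozen structure.

All generators are deterministic given their seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .raster import SpikeRaster

__all__ = [
    "StimulusProgram",
    "MixingConfig",
    "frozen_pattern_stream",
    "corrupt_stream",
    "chunk_char_stream",
    "community_walk_stream",
    "community_graph",
    "bar_image_stream",
    "synth_correlated_sources",
    "mix_sources",
    "amplitude_to_rate",
    "save_wav",
    "load_wav",
]


@dataclass
class StimulusProgram:
    """A rate schedule over time plus ground-truth annotations.

    ``rates``: (n_bins, n_in) expected instantaneous rates, events/ms, on a
    ``dt``-ms grid (1 ms by default); a single (1, n_in) row broadcasts over
    the whole duration (stationary schedules).  ``labels``: per-bin integer
    ground truth (−1 = background/none), defining the duration.
    ``raster``/``event_tags`` are present for frozen-pattern stimuli (tag 1
    marks pattern spikes).
    """

    rates: np.ndarray
    labels: np.ndarray
    dt: float = 1.0
    meta: dict = field(default_factory=dict)
    raster: SpikeRaster | None = None
    event_tags: np.ndarray | None = None
    row_index: np.ndarray | None = None
    col_index: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.rates = np.atleast_2d(np.asarray(self.rates, dtype=np.float64))
        self.labels = np.asarray(self.labels, dtype=np.int64)
        if np.any(self.rates < 0):
            raise ValueError("rates must be nonnegative")
        if self.row_index is not None:
            self.row_index = np.asarray(self.row_index, dtype=np.int64)
            if self.row_index.shape[0] != self.labels.shape[0]:
                raise ValueError("row_index must span the full duration")
            if self.row_index.max(initial=0) >= self.rates.shape[0]:
                raise ValueError("row_index points past the rate table")
        elif self.labels.shape[0] != self.rates.shape[0] and self.rates.shape[0] != 1:
            raise ValueError("labels must span the full duration")
        if self.col_index is not None:
            self.col_index = np.asarray(self.col_index, dtype=np.int64)
            if self.col_index.max(initial=0) >= self.rates.shape[1]:
                raise ValueError("col_index points past the rate table")

    @property
    def n_in(self) -> int:
        return (self.col_index.shape[0] if self.col_index is not None
                else self.rates.shape[1])

    @property
    def duration(self) -> float:
        return self.labels.shape[0] * self.dt

    def _dense_block(self, b0: int, b1: int) -> np.ndarray:
        """Dense (b1-b0, n_in) rate block for bins [b0, b1)."""
        if self.row_index is not None:
            block = self.rates[self.row_index[b0:b1]]
        elif self.rates.shape[0] == 1:
            block = np.broadcast_to(self.rates, (b1 - b0, self.rates.shape[1]))
        else:
            block = self.rates[b0:b1]
        if self.col_index is not None:
            block = block[:, self.col_index]
        return block

    def rates_dense(self) -> np.ndarray:
        """Rates expanded to a full (n_bins, n_in) view/array."""
        return self._dense_block(0, self.labels.shape[0])

    def spike_bins(self, dt: float, rng: np.random.Generator) -> np.ndarray:
        """Realize the program as binned spikes on a dt-ms grid.

        Sampling is done block-wise to bound memory; the random stream is
        consumed in bin order, so the result does not depend on block size.
        """
        if self.raster is not None:
            return self.raster.to_bins(dt)
        rep = 1
        if dt != self.dt:
            rep = int(round(self.dt / dt))
            if not math.isclose(rep * dt, self.dt):
                raise ValueError("dt must divide the program grid spacing")
        if np.any(self.rates * dt > 1.0):
            raise ValueError("rate*dt exceeds 1; decrease dt")
        n_bins = self.labels.shape[0] * rep
        out = np.empty((n_bins, self.n_in), dtype=np.uint8)
        block = max((1 << 22) // max(self.n_in, 1), 1)  # ~4M samples per block
        block = max(block - block % rep, rep)
        for s in range(0, n_bins, block):
            e = min(s + block, n_bins)
            r = self._dense_block(s // rep, (e + rep - 1) // rep)
            if rep > 1:
                r = np.repeat(r, rep, axis=0)[:e - s]
            out[s:e] = rng.random((e - s, self.n_in)) < r * dt
        return out

    def time_slice(self, t0_ms: float, t1_ms: float) -> "StimulusProgram":
        """Restrict the program to [t0_ms, t1_ms), shifting times to zero."""
        b0, b1 = int(round(t0_ms / self.dt)), int(round(t1_ms / self.dt))
        raster = tags = None
        if self.raster is not None:
            m = (self.raster.time >= t0_ms) & (self.raster.time < t1_ms)
            raster = SpikeRaster(self.raster.neuron[m],
                                 self.raster.time[m] - t0_ms,
                                 self.raster.n_neurons, t1_ms - t0_ms)
            if self.event_tags is not None:
                tags = self.event_tags[m]
        if self.row_index is not None or self.rates.shape[0] == 1:
            rates = self.rates
        else:
            rates = self.rates[b0:b1]
        row_index = None if self.row_index is None else self.row_index[b0:b1]
        n_bins = self.labels.shape[0]
        meta = {k: (v[..., b0:b1] if isinstance(v, np.ndarray)
                    and v.shape and v.shape[-1] == n_bins else v)
                for k, v in self.meta.items()}
        return StimulusProgram(rates=rates,
                               labels=self.labels[b0:b1], dt=self.dt,
                               meta=meta, raster=raster, event_tags=tags,
                               row_index=row_index, col_index=self.col_index)

    def labels_at(self, dt: float) -> np.ndarray:
        """Label track resampled onto a dt-ms grid."""
        if dt == self.dt:
            return self.labels
        rep = int(round(self.dt / dt))
        return np.repeat(self.labels, rep)

    # ---- serialization: raster text + JSON label sidecar -------------

    def save(self, prefix, rng=None) -> None:
        """Write ``<prefix>.raster`` and ``<prefix>.labels.json``.

        Rate-only programs are realized as spikes first (pass ``rng`` or a
        seed for reproducibility).
        """
        import json
        raster = self.raster
        if raster is None:
            if rng is None or not isinstance(rng, np.random.Generator):
                rng = np.random.default_rng(rng)
            raster = SpikeRaster.from_bins(self.spike_bins(self.dt, rng),
                                           self.dt)
        raster.save(f"{prefix}.raster")
        meta = {k: v for k, v in self.meta.items()
                if isinstance(v, (str, int, float, bool, list))}
        with open(f"{prefix}.labels.json", "w") as fh:
            json.dump({"dt": self.dt, "labels": self.labels.tolist(),
                       "meta": meta}, fh)

    @classmethod
    def load(cls, prefix) -> "StimulusProgram":
        """Read a program saved by :meth:`save` (spikes become the raster)."""
        import json
        raster = SpikeRaster.load(f"{prefix}.raster")
        with open(f"{prefix}.labels.json") as fh:
            side = json.load(fh)
        rates = np.zeros((1, raster.n_neurons))
        return cls(rates=rates, labels=np.asarray(side["labels"]),
                   dt=float(side["dt"]), meta=side.get("meta", {}),
                   raster=raster)


@dataclass
class MixingConfig:
    """Rotation-like 2×2 mixing of two sources; cross-talk = tan(theta)."""

    theta: float
    matrix: np.ndarray

    def __post_init__(self) -> None:
        if not 0.0 <= self.theta <= math.pi / 4 + 1e-12:
            raise ValueError("theta must lie in [0, pi/4]")
        self.matrix = np.asarray(self.matrix, dtype=np.float64)

    @property
    def crosstalk(self) -> float:
        return math.tan(self.theta)


# ---------------------------------------------------------------------------
# frozen spatiotemporal patterns


def frozen_pattern_stream(n_in: int, n_patterns: int = 3,
                          pattern_ms: float = 50.0,
                          base_rate: float = 0.005,
                          occupancy: float = 0.5,
                          assembly_fraction: float = 1.0,
                          duration_ms: float = 100_000.0,
                          seed=0, pattern_seed=None) -> StimulusProgram:
    """Irregular spike trains with embedded frozen spatiotemporal patterns.

    The timeline is divided into ``pattern_ms`` slots; each slot is, with
    probability ``occupancy``, one of ``n_patterns`` patterns (chosen
    uniformly, so all patterns are equally probable), otherwise background.
    Each pattern owns a random subset of ``assembly_fraction·n_in`` neurons
    which replay a single frozen Poisson realization at every occurrence;
    all other activity is homogeneous Poisson at ``base_rate``.  The frozen
    realization contains exactly ``round(n_participants·base_rate·
    pattern_ms)`` spikes placed uniformly, so participants and
    non-participants have identical population-mean firing rates and the
    patterns are not detectable from rates alone.

    ``pattern_seed`` (defaults to ``seed``) controls the pattern membership
    and frozen realizations separately from the timeline and background, so
    successive stream segments can replay the same patterns in fresh noise.
    """
    if not 0.0 < assembly_fraction <= 1.0:
        raise ValueError("assembly_fraction must lie in (0, 1]")
    n_part = int(round(assembly_fraction * n_in))
    if n_part < 1:
        raise ValueError("assembly_fraction * n_in must be >= 1")
    rng = np.random.default_rng(seed)
    prng = np.random.default_rng(seed if pattern_seed is None else pattern_seed)
    n_slots = int(duration_ms // pattern_ms)
    duration_ms = n_slots * pattern_ms

    members = [prng.choice(n_in, size=n_part, replace=False)
               for _ in range(n_patterns)]
    # one frozen realization per pattern: exact total spike count
    frozen = []
    for p in range(n_patterns):
        k = int(round(n_part * base_rate * pattern_ms))
        neuron = prng.choice(members[p], size=k, replace=True)
        time = prng.random(k) * pattern_ms
        frozen.append((neuron, time))

    slot_kind = np.full(n_slots, -1, dtype=np.int64)
    is_pat = rng.random(n_slots) < occupancy
    slot_kind[is_pat] = rng.integers(0, n_patterns, size=int(is_pat.sum()))

    # homogeneous background over the full duration for every neuron
    n_bg = rng.poisson(base_rate * duration_ms * n_in)
    bg_neuron = rng.integers(0, n_in, size=n_bg)
    bg_time = rng.random(n_bg) * duration_ms
    # remove background of pattern members during that pattern's slots
    bg_slot = (bg_time // pattern_ms).astype(np.int64)
    keep = np.ones(n_bg, dtype=bool)
    for p in range(n_patterns):
        in_p_slot = slot_kind[bg_slot] == p
        is_member = np.isin(bg_neuron, members[p])
        keep &= ~(in_p_slot & is_member)
    ev_n = [bg_neuron[keep]]
    ev_t = [bg_time[keep]]
    ev_tag = [np.zeros(int(keep.sum()), dtype=np.int64)]

    for p in range(n_patterns):
        fn, ft = frozen[p]
        starts = np.nonzero(slot_kind == p)[0] * pattern_ms
        ev_n.append(np.tile(fn, starts.size))
        ev_t.append((ft[None, :] + starts[:, None]).ravel())
        ev_tag.append(np.ones(fn.size * starts.size, dtype=np.int64))

    neuron = np.concatenate(ev_n)
    time = np.concatenate(ev_t)
    tags = np.concatenate(ev_tag)
    order = np.lexsort((neuron, time))
    raster = SpikeRaster(neuron[order], time[order], n_in, duration_ms)
    tags = tags[order]

    rates = np.full((1, n_in), base_rate)
    labels = np.repeat(slot_kind, int(pattern_ms))
    return StimulusProgram(
        rates=rates, labels=labels, dt=1.0, raster=raster, event_tags=tags,
        meta={"kind": "frozen_pattern", "members": [m.tolist() for m in members],
              "pattern_ms": pattern_ms, "base_rate": base_rate,
              "occupancy": occupancy, "n_patterns": n_patterns, "seed": seed})


def corrupt_stream(prog: StimulusProgram, background_ratio: float = 0.0,
                   failure_prob: float = 0.0, jitter_sd_ms: float = 0.0,
                   seed=0) -> StimulusProgram:
    """Degrade a frozen-pattern stream with noise of three kinds.

    ``background_ratio``: extra independent Poisson background spikes are
    added so that their expected count is ``ratio × (number of pattern
    spikes)``.  ``failure_prob``: every spike is independently deleted with
    this probability (synaptic transmission failure).  ``jitter_sd_ms``:
    Gaussian timing jitter applied to pattern spikes, clipped to the pattern
    epoch they belong to.
    """
    if prog.raster is None or prog.event_tags is None:
        raise ValueError("corrupt_stream requires an explicit-raster program")
    if not 0.0 <= failure_prob <= 1.0:
        raise ValueError("failure_prob must lie in [0, 1]")
    if jitter_sd_ms < 0 or background_ratio < 0:
        raise ValueError("jitter_sd_ms and background_ratio must be >= 0")
    rng = np.random.default_rng(seed)
    neuron = prog.raster.neuron.copy()
    time = prog.raster.time.copy()
    tags = prog.event_tags.copy()
    duration = prog.raster.duration
    n_in = prog.raster.n_neurons

    if jitter_sd_ms > 0:
        pat = tags == 1
        jit = time[pat] + rng.normal(0.0, jitter_sd_ms, size=int(pat.sum()))
        # clip into the contiguous label run (pattern epoch) of each spike
        pattern_ms = float(prog.meta.get("pattern_ms", prog.dt))
        start = (time[pat] // pattern_ms) * pattern_ms
        jit = np.clip(jit, start, start + pattern_ms - 1e-9)
        time[pat] = jit

    if failure_prob > 0:
        keep = rng.random(neuron.size) >= failure_prob
        neuron, time, tags = neuron[keep], time[keep], tags[keep]

    if background_ratio > 0:
        n_target = int(np.sum(prog.event_tags == 1))
        n_new = rng.poisson(background_ratio * n_target)
        neuron = np.concatenate([neuron, rng.integers(0, n_in, size=n_new)])
        time = np.concatenate([time, rng.random(n_new) * duration])
        tags = np.concatenate([tags, np.zeros(n_new, dtype=np.int64)])

    order = np.lexsort((neuron, time))
    raster = SpikeRaster(neuron[order], time[order], n_in, duration)
    return StimulusProgram(
        rates=prog.rates, labels=prog.labels, dt=prog.dt, raster=raster,
        event_tags=tags[order],
        meta={**prog.meta, "background_ratio": background_ratio,
              "failure_prob": failure_prob, "jitter_sd_ms": jitter_sd_ms})


# ---------------------------------------------------------------------------
# character-sequence chunks


def chunk_char_stream(chunks, n_in: int, char_ms: float = 30.0,
                      burst_rate: float = 0.01, duration_ms: float = 100_000.0,
                      distractors: bool = False, seed=0,
                      alphabet: str | None = None) -> StimulusProgram:
    """Random concatenation of character chunks encoded by bursting neurons.

    Chunks (strings) are concatenated in random order with equal
    probabilities; with ``distractors=True`` a random string of arbitrary
    letters a–z with length 3–7 is inserted between chunks with probability
    1/2.  Each input neuron is randomly assigned one preferred character
    from the alphabet and fires a ``burst_rate`` (10 Hz default) burst for
    ``char_ms`` whenever that character is presented; it is silent
    otherwise.  The label track holds the current chunk index (−1 during
    distractors).
    """
    chunks = [str(c) for c in chunks]
    if not chunks or any(len(c) == 0 for c in chunks):
        raise ValueError("chunks must be nonempty strings")
    if alphabet is None:
        alphabet = "".join(sorted(set("".join(chunks))))
        if distractors:
            alphabet = "abcdefghijklmnopqrstuvwxyz"
    if not alphabet:
        raise ValueError("alphabet is empty")
    rng = np.random.default_rng(seed)
    prefs = rng.integers(0, len(alphabet), size=n_in)
    char_index = {c: k for k, c in enumerate(alphabet)}

    seq_chars: list[int] = []
    seq_label: list[int] = []
    n_chars_needed = int(duration_ms // char_ms)
    while len(seq_chars) < n_chars_needed:
        if distractors and rng.random() < 0.5:
            length = int(rng.integers(3, 8))
            for _ in range(length):
                seq_chars.append(int(rng.integers(0, 26)))
                seq_label.append(-1)
        c = int(rng.integers(0, len(chunks)))
        for ch in chunks[c]:
            if ch not in char_index:
                raise ValueError(f"character {ch!r} not in alphabet")
            seq_chars.append(char_index[ch])
            seq_label.append(c)
    seq_chars = seq_chars[:n_chars_needed]
    seq_label = seq_label[:n_chars_needed]

    bins_per_char = int(round(char_ms))
    # one rate row per character of the alphabet
    rows = np.zeros((len(alphabet), n_in))
    for k in range(len(alphabet)):
        rows[k, prefs == k] = burst_rate
    row_index = np.repeat(np.asarray(seq_chars), bins_per_char)
    labels = np.repeat(np.asarray(seq_label), bins_per_char)
    return StimulusProgram(
        rates=rows, labels=labels, dt=1.0, row_index=row_index,
        meta={"kind": "chunk_chars", "chunks": chunks, "alphabet": alphabet,
              "prefs": prefs.tolist(), "char_ms": char_ms,
              "burst_rate": burst_rate, "distractors": distractors,
              "char_sequence": seq_chars, "seed": seed})


# ---------------------------------------------------------------------------
# random walk on a community graph


def community_graph(n_communities: int = 3, size: int = 5):
    """Adjacency of the standard temporal-community graph.

    ``n_communities`` complete clusters of ``size`` nodes, except that the
    two boundary nodes of each cluster are not linked to each other and
    instead connect to a boundary node of the neighbouring cluster (clusters
    arranged in a ring).  Every node has degree ``size − 1`` (4 for the
    default 3×5 graph) and uniform transition probabilities defeat
    segmentation based on transition-probability dips.
    """
    n = n_communities * size
    adj = np.zeros((n, n), dtype=bool)
    for c in range(n_communities):
        lo = c * size
        for a in range(lo, lo + size):
            for b in range(a + 1, lo + size):
                adj[a, b] = adj[b, a] = True
        first, last = lo, lo + size - 1
        adj[first, last] = adj[last, first] = False
        nxt_first = ((c + 1) % n_communities) * size
        adj[last, nxt_first] = adj[nxt_first, last] = True
    return adj


def community_walk_stream(n_in: int, steps: int = 3000,
                          n_communities: int = 3, size: int = 5,
                          char_ms: float = 30.0, burst_rate: float = 0.01,
                          seed=0) -> StimulusProgram:
    """Random walk on the community graph, nodes encoded like characters.

    The walk moves to one of the current node's 4 neighbours with equal
    probability 0.25 at every step; each node is presented for ``char_ms``
    as a burst of its preferred input neurons.  Labels give the community
    of the current node.
    """
    adj = community_graph(n_communities, size)
    n_nodes = adj.shape[0]
    neighbors = [np.nonzero(adj[k])[0] for k in range(n_nodes)]
    rng = np.random.default_rng(seed)
    node = int(rng.integers(0, n_nodes))
    walk = np.empty(steps, dtype=np.int64)
    for s in range(steps):
        walk[s] = node
        node = int(neighbors[node][rng.integers(0, len(neighbors[node]))])

    prefs = rng.integers(0, n_nodes, size=n_in)
    bins_per = int(round(char_ms))
    rows = np.zeros((n_nodes, n_in))
    for k in range(n_nodes):
        rows[k, prefs == k] = burst_rate
    row_index = np.repeat(walk, bins_per)
    labels = np.repeat(walk // size, bins_per)
    return StimulusProgram(
        rates=rows, labels=labels, dt=1.0, row_index=row_index,
        meta={"kind": "community_walk", "walk": walk.tolist(),
              "prefs": prefs.tolist(), "n_communities": n_communities,
              "community_size": size, "char_ms": char_ms, "seed": seed})


# ---------------------------------------------------------------------------
# oriented-bar images


def bar_masks(image_px: int = 16, n_orientations: int = 8,
              thickness: float = 1.5) -> np.ndarray:
    """(n_orientations, image_px, image_px) binary masks of centred bars."""
    if image_px < 4:
        raise ValueError("image dimensions must be at least the bar length")
    c = (image_px - 1) / 2.0
    yy, xx = np.mgrid[0:image_px, 0:image_px]
    masks = np.empty((n_orientations, image_px, image_px))
    for k in range(n_orientations):
        ang = k * math.pi / n_orientations
        # distance from pixel to the line through the centre at angle ang
        d = np.abs(-(xx - c) * math.sin(ang) + (yy - c) * math.cos(ang))
        masks[k] = (d <= thickness / 2.0 + 0.25).astype(float)
    return masks


def bar_image_stream(image_px: int = 16, n_orientations: int = 8,
                     noise_level: float = 0.2, present_ms: float = 40.0,
                     gap_ms: float = 30.0, n_images: int = 1000,
                     max_rate: float = 0.02, seed=0) -> StimulusProgram:
    """Noisy oriented-bar images presented in random order.

    Each presentation picks a random orientation, adds truncated Gaussian
    pixel noise (s.d. ``noise_level``, clipped at 0), and maps intensities
    linearly to input rates in [0, ``max_rate``]; between images all inputs
    are at rate 0 for ``gap_ms``.  One input neuron per pixel.
    """
    masks = bar_masks(image_px, n_orientations)
    rng = np.random.default_rng(seed)
    n_in = image_px * image_px
    pb, gb = int(round(present_ms)), int(round(gap_ms))
    n_bins = n_images * (pb + gb)
    rates = np.zeros((n_bins, n_in))
    labels = np.full(n_bins, -1, dtype=np.int64)
    peak = 1.0 + 3.0 * noise_level  # fixed normalisation, rate*dt stays < 1
    for k in range(n_images):
        ori = int(rng.integers(0, n_orientations))
        img = masks[ori].ravel()
        if noise_level > 0:
            img = np.maximum(img + rng.normal(0.0, noise_level, size=n_in), 0.0)
        sl = slice(k * (pb + gb), k * (pb + gb) + pb)
        rates[sl] = np.minimum(img / peak, 1.0) * max_rate
        labels[sl] = ori
    return StimulusProgram(
        rates=rates, labels=labels, dt=1.0,
        meta={"kind": "bar_images", "image_px": image_px,
              "n_orientations": n_orientations, "noise_level": noise_level,
              "present_ms": present_ms, "gap_ms": gap_ms, "seed": seed})


# ---------------------------------------------------------------------------
# correlated sources, mixing and rate encoding


def synth_correlated_sources(duration_s: float = 100.0,
                             sample_rate: float = 100.0,
                             correlation_mode: str = "dependent",
                             seed=0, audio: bool = False):
    """Two synthetic instrument-like sources with note structure.

    In ``dependent`` mode the two sources play the same score — shared note
    onsets and durations with independent per-note amplitudes — giving
    positively correlated amplitude envelopes (≈0.4–0.8).  In
    ``independent`` mode the two note schedules are unrelated (|r| ≲ 0.1).
    With ``audio=True`` (requires ``sample_rate`` ≥ 8 kHz) each source is a
    harmonic tone stack under its envelope; otherwise the envelopes
    themselves are returned, which is the fast mode used in tests.
    """
    if correlation_mode not in ("independent", "dependent"):
        raise ValueError("correlation_mode must be 'independent' or 'dependent'")
    if audio and sample_rate < 8000:
        raise ValueError("audio mode requires sample_rate >= 8 kHz")
    rng = np.random.default_rng(seed)
    n = int(round(duration_s * sample_rate))
    t = np.arange(n) / sample_rate

    def schedule(r):
        # the score: note onsets, durations and score-wide rests are shared
        # by both instruments in dependent mode
        onsets = []
        cur = 0.0
        while cur < duration_s:
            dur = r.uniform(0.2, 0.4)
            rest = r.random() < 0.1
            onsets.append((cur, min(dur, duration_s - cur), rest))
            cur += dur
        return onsets

    def phrases(r):
        bounds = [0.0]
        while bounds[-1] < duration_s:
            bounds.append(bounds[-1] + r.uniform(2.0, 4.0))
        return np.asarray(bounds)

    def envelope(onsets, bounds, r):
        # each instrument plays its own part: per-note loudness, part-level
        # phrase dynamics and occasional part-specific rests are
        # instrument-private, so the balance between the two sources swings
        # on both the note (~0.3 s) and the phrase (~3 s) timescale
        gain = r.uniform(0.65, 1.0, size=len(bounds))
        env = np.zeros(n)
        for (start, dur, rest) in onsets:
            if rest or r.random() < 0.08:
                continue
            amp = r.uniform(0.6, 1.0) * gain[
                int(np.searchsorted(bounds, start, side="right") - 1)]
            i0 = int(start * sample_rate)
            i1 = min(int((start + dur) * sample_rate), n)
            tt = t[i0:i1] - start
            shape = (1.0 - np.exp(-tt / 0.015)) * np.exp(-tt / (1.2 * dur))
            env[i0:i1] = amp * shape
        return env

    if correlation_mode == "dependent":
        notes = schedule(rng)
        bounds = phrases(rng)
        env1 = envelope(notes, bounds, rng)
        env2 = envelope(notes, bounds, rng)
    else:
        env1 = envelope(schedule(rng), phrases(rng), rng)
        env2 = envelope(schedule(rng), phrases(rng), rng)

    # per-instrument amplitude roughness: each source carries its own
    # amplitude modulation in the 15-30 Hz band (the beating/roughness of
    # real instrument tones), at a rate distinct between the instruments.
    # This fine temporal fingerprint survives the 5-15 ms synaptic
    # filtering and is the timescale the spike-pairing plasticity senses.
    f1 = rng.uniform(14.0, 19.0)
    f2 = rng.uniform(24.0, 30.0)
    depth = 0.5
    env1 = env1 * (1.0 + depth * np.sin(2 * math.pi * f1 * t
                                        + rng.uniform(0, 2 * math.pi)))
    env2 = env2 * (1.0 + depth * np.sin(2 * math.pi * f2 * t
                                        + rng.uniform(0, 2 * math.pi)))

    if not audio:
        return env1, env2
    scale = [220.0, 246.9, 277.2, 293.7, 329.6, 370.0, 415.3]
    waves = []
    for env in (env1, env2):
        f = float(rng.choice(scale))
        carrier = np.zeros(n)
        for h in (1, 2, 3):
            carrier += np.sin(2 * math.pi * f * h * t) / h
        waves.append(env * carrier)
    return waves[0], waves[1]


def mix_sources(x1: np.ndarray, x2: np.ndarray, theta: float | None = None):
    """Linearly mix two sources.

    With ``theta`` given, the mixer is the rotation-like matrix
    [[cosθ, sinθ], [sinθ, cosθ]] and the cross-talk level is tanθ.  With
    ``theta=None`` the fixed matrix [[1, 0.5], [0.5, 1]] is used, which is
    the same mixing family scaled: its cross-talk level is 0.5.
    """
    x1 = np.asarray(x1, dtype=np.float64)
    x2 = np.asarray(x2, dtype=np.float64)
    if x1.shape != x2.shape:
        raise ValueError("sources must have equal length")
    if theta is None:
        matrix = np.array([[1.0, 0.5], [0.5, 1.0]])
        cfg = MixingConfig(theta=math.atan(0.5), matrix=matrix)
    else:
        matrix = np.array([[math.cos(theta), math.sin(theta)],
                           [math.sin(theta), math.cos(theta)]])
        cfg = MixingConfig(theta=float(theta), matrix=matrix)
    mixed = matrix @ np.vstack([x1, x2])
    return mixed[0], mixed[1], cfg


def save_wav(path, signal: np.ndarray, sample_rate: float) -> None:
    """Write a mono 16-bit PCM WAV file (peak-normalized)."""
    import wave
    x = np.asarray(signal, dtype=np.float64)
    peak = np.max(np.abs(x))
    if peak > 0:
        x = x / peak
    pcm = (x * 32767.0).astype("<i2")
    with wave.open(str(path), "wb") as fh:
        fh.setnchannels(1)
        fh.setsampwidth(2)
        fh.setframerate(int(round(sample_rate)))
        fh.writeframes(pcm.tobytes())


def load_wav(path):
    """Read a mono 16-bit PCM WAV file; returns (signal in [−1, 1], fs)."""
    import wave
    with wave.open(str(path), "rb") as fh:
        if fh.getnchannels() != 1 or fh.getsampwidth() != 2:
            raise ValueError("expected mono 16-bit PCM WAV")
        fs = float(fh.getframerate())
        pcm = np.frombuffer(fh.readframes(fh.getnframes()), dtype="<i2")
    return pcm.astype(np.float64) / 32767.0, fs


def envelope_of(signal: np.ndarray, fs: float, smooth_ms: float = 10.0) -> np.ndarray:
    """Rectify and box-smooth a signal into an amplitude envelope."""
    x = np.abs(np.asarray(signal, dtype=np.float64))
    k = max(int(round(smooth_ms * fs / 1000.0)), 1)
    kernel = np.ones(k) / k
    return np.convolve(x, kernel, mode="same")


def amplitude_to_rate(signals, n_in: int, fs: float,
                      max_rate: float = 0.01, dt: float = 1.0,
                      labels: np.ndarray | None = None) -> StimulusProgram:
    """Encode signal amplitudes as Poisson input rates.

    Each signal's rectified, 10 ms-smoothed envelope is normalized by its
    peak and scaled to [0, ``max_rate``] (so the peak maps to exactly
    ``max_rate`` and the coding is invariant to signal amplitude scaling);
    the input population is split evenly, each neuron encoding exactly one
    signal.  Envelopes are resampled onto a ``dt``-ms grid.
    """
    signals = [np.asarray(s, dtype=np.float64) for s in np.atleast_2d(signals)]
    n_sig = len(signals)
    if n_in % n_sig:
        raise ValueError("n_in must divide evenly between the signals")
    per = n_in // n_sig
    n_bins = int(round(len(signals[0]) / fs * 1000.0 / dt))
    rates = np.empty((n_bins, n_sig))
    t_bins = (np.arange(n_bins) + 0.5) * dt / 1000.0
    t_sig = np.arange(len(signals[0])) / fs
    for k, s in enumerate(signals):
        if len(s) != len(signals[0]):
            raise ValueError("signals must have equal length")
        env = envelope_of(s, fs)
        peak = env.max()
        if peak <= 0:
            raise ValueError("signal is identically zero; normalization undefined")
        rates[:, k] = np.interp(t_bins, t_sig, env / peak) * max_rate
    if labels is None:
        labels = np.full(n_bins, -1, dtype=np.int64)
    col_index = np.repeat(np.arange(n_sig), per)
    return StimulusProgram(rates=rates, labels=np.asarray(labels)[:n_bins],
                           dt=dt, col_index=col_index,
                           meta={"kind": "amplitude", "fs": fs,
                                 "max_rate": max_rate, "n_signals": n_sig})
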