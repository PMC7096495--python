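"""Metrics for the learned representations.

Covers the soma–dendrite consistency correlation (the learning curve),
chunk-selectivity assignment with its 50% ambiguity rule, correlations with
binary reference responses, principal-component variance of population
responses, decoding and scoring of separated sources, and the log-cosh
negentropy approximation used to quantify non-Gaussianity.
"""

from __future__ import annotations

import itertools
import warnings

import numpy as np

__all__ = [
    "smooth_responses",
    "label_runs",
    "event_locked_response",
    "soma_dendrite_correlation",
    "selectivity_assignment",
    "reference_tracks",
    "reference_correlation",
    "pc_variance",
    "source_assignment",
    "decode_sources",
    "separation_score",
    "negentropy",
    "gauss_logcosh_moment",
]

OTHERS = -1


def smooth_responses(responses: np.ndarray, window_bins: int = 10) -> np.ndarray:
    """Boxcar-smooth (n_time, n_neurons) rate traces along time."""
    responses = np.atleast_2d(np.asarray(responses, dtype=np.float64).T).T
    if window_bins <= 1:
        return responses
    kernel = np.ones(window_bins) / window_bins
    out = np.empty_like(responses)
    for j in range(responses.shape[1]):
        out[:, j] = np.convolve(responses[:, j], kernel, mode="same")
    return out


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    a = a - a.mean()
    b = b - b.mean()
    den = np.sqrt((a * a).sum() * (b * b).sum())
    if den == 0:
        return np.nan
    return float((a * b).sum() / den)


def soma_dendrite_correlation(u_rates: np.ndarray, v_rates: np.ndarray,
                              window_bins: int) -> np.ndarray:
    """Windowed Pearson correlation between somatic and dendritic rates.

    ``u_rates``/``v_rates``: aligned (n_time, n_out) traces of φ^som and
    φ^dend.  Returns (n_windows, n_out); windows with zero variance in
    either trace yield NaN (reported as missing).
    """
    u = np.atleast_2d(np.asarray(u_rates, dtype=np.float64).T).T
    v = np.atleast_2d(np.asarray(v_rates, dtype=np.float64).T).T
    if u.shape != v.shape:
        raise ValueError("traces must be aligned")
    n_w = u.shape[0] // window_bins
    out = np.full((n_w, u.shape[1]), np.nan)
    for w in range(n_w):
        sl = slice(w * window_bins, (w + 1) * window_bins)
        for j in range(u.shape[1]):
            out[w, j] = _pearson(u[sl, j], v[sl, j])
    return out


def label_runs(labels: np.ndarray, value: int):
    """Onsets and lengths of the contiguous runs where labels == value."""
    m = np.asarray(labels) == value
    d = np.diff(m.astype(np.int8))
    starts = np.nonzero(d == 1)[0] + 1
    ends = np.nonzero(d == -1)[0] + 1
    if m[0]:
        starts = np.r_[0, starts]
    if m[-1]:
        ends = np.r_[ends, m.size]
    return starts, ends - starts


def event_locked_response(responses: np.ndarray, labels: np.ndarray,
                          value: int) -> np.ndarray:
    """Mean response (time × neuron) locked to the onsets of one label.

    Occurrences are aligned at epoch onset and averaged over repetitions,
    truncated to the median epoch length.
    """
    r = np.atleast_2d(np.asarray(responses, dtype=np.float64).T).T
    starts, lengths = label_runs(labels, value)
    if starts.size == 0:
        return np.zeros((0, r.shape[1]))
    span = int(np.median(lengths))
    keep = [s for s, n in zip(starts, lengths)
            if n >= span and s + span <= r.shape[0]]
    if not keep:
        return np.zeros((0, r.shape[1]))
    return np.mean([r[s:s + span] for s in keep], axis=0)


def selectivity_assignment(responses: np.ndarray, labels: np.ndarray,
                           smooth_bins: int = 10) -> np.ndarray:
    """Preferred chunk per neuron, or OTHERS (−1) when ambiguous.

    Peak responses are read from the event-locked average response to each
    chunk (the PSTH over its presentation epochs), so single stray
    threshold crossings do not count as responses.  The preferred chunk is
    the one with the largest peak; a neuron is "others" when the peak
    response to its second-best chunk exceeds 50% of the peak response to
    the best one, or when it never responds.
    """
    r = smooth_responses(responses, smooth_bins)
    labels = np.asarray(labels)
    chunk_ids = np.unique(labels[labels >= 0])
    if chunk_ids.size < 1:
        raise ValueError("need at least one chunk label")
    peaks = np.zeros((len(chunk_ids), r.shape[1]))
    for k, c in enumerate(chunk_ids):
        locked = event_locked_response(r, labels, c)
        if locked.shape[0]:
            peaks[k] = locked.max(axis=0)
    out = np.empty(r.shape[1], dtype=np.int64)
    for j in range(r.shape[1]):
        p = peaks[:, j]
        best = int(np.argmax(p))
        if p[best] <= 0:
            out[j] = OTHERS
        else:
            second = np.max(np.delete(p, best)) if p.size > 1 else 0.0
            out[j] = OTHERS if second > 0.5 * p[best] else int(chunk_ids[best])
    return out


def reference_tracks(labels: np.ndarray) -> dict[int, np.ndarray]:
    """Binary reference response per chunk: 1 during its presentation."""
    labels = np.asarray(labels)
    return {int(c): (labels == c).astype(float)
            for c in np.unique(labels[labels >= 0])}


def reference_correlation(responses: np.ndarray, labels: np.ndarray,
                          assignment: np.ndarray | None = None,
                          smooth_bins: int = 10, per_neuron: bool = False):
    """Correlate assembly responses with the chunk reference responses.

    Assemblies are groups of neurons sharing a preferred chunk (from
    ``assignment``, computed here if not given); each assembly's mean
    smoothed response is correlated with every chunk's binary reference,
    and each chunk reports the maximally correlated assembly.  With
    ``per_neuron=True`` every neuron is its own assembly (used when a
    single embedded pattern makes group assignment meaningless).

    Returns
    -------
    best : dict chunk_id -> correlation (NaN if no assembly exists)
    matrix : (n_assemblies, n_chunks) correlation matrix
    assemblies : list of assembly identifiers defining the matrix rows
    """
    r = smooth_responses(responses, smooth_bins)
    refs = reference_tracks(labels)
    if per_neuron:
        assignment = np.arange(r.shape[1])
        assemblies = list(range(r.shape[1]))
    else:
        if assignment is None:
            assignment = selectivity_assignment(responses, labels, smooth_bins)
        assemblies = [c for c in sorted(set(assignment)) if c != OTHERS]
    chunk_ids = sorted(refs)
    matrix = np.full((len(assemblies), len(chunk_ids)), np.nan)
    for a, ca in enumerate(assemblies):
        mean_resp = r[:, assignment == ca].mean(axis=1)
        for k, c in enumerate(chunk_ids):
            matrix[a, k] = _pearson(mean_resp, refs[c])
    best = {}
    for k, c in enumerate(chunk_ids):
        col = matrix[:, k]
        best[c] = np.nan if (col.size == 0 or np.all(np.isnan(col))) \
            else float(np.nanmax(col))
    return best, matrix, assemblies


def pc_variance(responses: np.ndarray) -> np.ndarray:
    """Sorted explained-variance fractions of population response traces.

    Standard eigendecomposition of the (n_neurons × n_neurons) covariance
    of the time series; fractions are non-increasing and sum to 1.
    Zero-variance (rank-deficient) directions contribute zero fractions.
    """
    r = np.asarray(responses, dtype=np.float64)
    if r.shape[0] < 3:
        raise ValueError("need at least 3 time samples")
    c = np.cov(r, rowvar=False)
    ev = np.linalg.eigvalsh(np.atleast_2d(c))[::-1]
    ev = np.maximum(ev, 0.0)
    tot = ev.sum()
    if tot == 0:
        return np.zeros_like(ev)
    return ev / tot


def source_assignment(responses: np.ndarray, source_envs,
                      min_corr: float = 0.1,
                      smooth_bins: int = 100) -> np.ndarray:
    """Assign each neuron to the source envelope its response tracks best.

    Continuous sources are active simultaneously, so epoch-peak selectivity
    is uninformative; instead each neuron joins the source with the largest
    response–envelope correlation, or OTHERS when no correlation reaches
    ``min_corr``.
    """
    r = smooth_responses(responses, smooth_bins)
    envs = [np.asarray(e, dtype=np.float64) for e in source_envs]
    corr = np.array([[_pearson(r[:, j], e) for e in envs]
                     for j in range(r.shape[1])])
    out = np.argmax(corr, axis=1).astype(np.int64)
    out[np.nanmax(corr, axis=1) < min_corr] = OTHERS
    return out


def decode_sources(responses: np.ndarray, assignment: np.ndarray,
                   smooth_bins: int = 100) -> dict[int, np.ndarray]:
    """Decode source envelopes from assembly-mean firing rates.

    For each assembly (neurons sharing a preferred source), the mean rate
    trace is smoothed and peak-normalized.  Raises if fewer than two
    assemblies were found, which signals failed separation.
    """
    assignment = np.asarray(assignment)
    sources = [c for c in sorted(set(assignment)) if c != OTHERS]
    if len(sources) < 2:
        raise ValueError("fewer than two assemblies: separation failed")
    r = np.asarray(responses, dtype=np.float64)
    out = {}
    for c in sources:
        m = r[:, assignment == c].mean(axis=1)
        m = smooth_responses(m[:, None], smooth_bins)[:, 0]
        peak = m.max()
        out[int(c)] = m / peak if peak > 0 else m
    return out


def separation_score(decoded, true_sources) -> np.ndarray:
    """Per-source Pearson correlation under the best decoded↔source pairing.

    ``decoded``/``true_sources``: sequences of aligned envelope traces.
    All pairings are tried exhaustively and the one maximizing the total
    correlation is reported, so the score is invariant to a relabelling of
    the decoded outputs.
    """
    dec = [np.asarray(d, dtype=np.float64) for d in
           (decoded.values() if isinstance(decoded, dict) else decoded)]
    tru = [np.asarray(s, dtype=np.float64) for s in true_sources]
    if any(d.shape != tru[0].shape for d in dec + tru):
        raise ValueError("decoded and true sources must be aligned")
    best, best_sum = None, -np.inf
    for perm in itertools.permutations(range(len(dec)), len(tru)):
        cors = np.array([_pearson(dec[p], s) for p, s in zip(perm, tru)])
        if np.nansum(cors) > best_sum:
            best_sum, best = np.nansum(cors), cors
    return best


_GAUSS_LOGCOSH = {}


def gauss_logcosh_moment(a: float = 1.0, order: int = 200) -> float:
    """E[(1/a)·log cosh(aρ)] for standard normal ρ, by Gauss–Hermite quadrature."""
    key = (a, order)
    if key not in _GAUSS_LOGCOSH:
        nodes, weights = np.polynomial.hermite_e.hermegauss(order)
        q = np.log(np.cosh(a * nodes)) / a
        _GAUSS_LOGCOSH[key] = float((weights * q).sum() / np.sqrt(2 * np.pi))
    return _GAUSS_LOGCOSH[key]


def negentropy(samples: np.ndarray, a: float = 1.0) -> float:
    """Log-cosh negentropy approximation J = [E(Q(Y)) − E(Q(ρ))]².

    ``samples`` must be standardized (zero mean, unit variance); ρ is
    standard normal and E(Q(ρ)) is evaluated by high-accuracy quadrature.
    Nonnegative by construction and ≈0 for Gaussian data.
    """
    if not 1.0 <= a <= 2.0:
        raise ValueError("a must lie in [1, 2]")
    y = np.asarray(samples, dtype=np.float64).ravel()
    if y.size < 100:
        warnings.warn("fewer than 100 samples: negentropy estimate is noisy")
    q_y = float(np.mean(np.log(np.cosh(a * y)) / a))
    return (q_y - gauss_logcosh_moment(a)) ** 2
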