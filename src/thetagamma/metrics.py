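"""Spike-based synchrony and theta-modulation statistics.

Network coherence kappa is the mean zero-lag normalized cross-correlation of
binary-binned spike-train pairs; the volley peak height summarizes the same
synchrony from the population spike histogram.  Theta modulation is read
from the theta-period-folded population activity: its squared Pearson
correlation with the raw theta signal (r^2) and its relative amplitude after
coarse re-binning (the modulation score M).
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .inputs import raw_theta

KAPPA_BIN = 1.0        # ms, bin size at which kappa is reported
VOLLEY_BIN = 1.0       # ms, population histogram bin
M_COARSE_BINS = 10     # coarse phase bins for the modulation score


def bin_spikes(spike_times, t_begin: float, t_end: float,
               tau: float = KAPPA_BIN, binary: bool = True) -> np.ndarray:
    """Per-cell binned spike matrix (n_cells, n_bins) on [t_begin, t_end)."""
    n_bins = int(np.floor((t_end - t_begin) / tau))
    edges = t_begin + np.arange(n_bins + 1) * tau
    out = np.zeros((len(spike_times), n_bins))
    for i, s in enumerate(spike_times):
        s = np.asarray(s)
        s = s[(s >= t_begin) & (s < edges[-1])]
        counts, _ = np.histogram(s, bins=edges)
        out[i] = counts
    if binary:
        out = (out > 0).astype(float)
    return out


def pairwise_coherence(x: np.ndarray, y: np.ndarray) -> float:
    """Zero-lag coherence of two binary spike trains; 0 if either is empty."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("trains must have equal length")
    sx, sy = x.sum(), y.sum()
    if sx == 0 or sy == 0:
        return 0.0
    return float((x * y).sum() / np.sqrt(sx * sy))


def network_coherence(spike_times, t_begin: float, t_end: float,
                      tau: float = KAPPA_BIN,
                      max_pairs: int | None = None,
                      rng: np.random.Generator | None = None) -> float:
    """kappa: mean pairwise coherence over all unordered cell pairs.

    ``max_pairs`` subsamples pairs (seeded) for large populations.
    """
    x = bin_spikes(spike_times, t_begin, t_end, tau, binary=True)
    n = x.shape[0]
    if n < 2:
        raise ValueError("need at least two cells")
    s = x @ x.T
    diag = np.diag(s)
    iu = np.triu_indices(n, k=1)
    num = s[iu]
    den = np.sqrt(diag[iu[0]] * diag[iu[1]])
    vals = np.where(den > 0, num / np.where(den > 0, den, 1.0), 0.0)
    if max_pairs is not None and vals.size > max_pairs:
        rng = rng or np.random.default_rng(0)
        vals = rng.choice(vals, size=max_pairs, replace=False)
    return float(vals.mean())


def population_histogram(spike_times, t_begin: float, t_end: float,
                         bin_size: float = VOLLEY_BIN):
    """(bin centres, pooled spike counts) across all cells."""
    n_bins = int(np.floor((t_end - t_begin) / bin_size))
    edges = t_begin + np.arange(n_bins + 1) * bin_size
    pooled = np.concatenate([np.asarray(s) for s in spike_times]) \
        if len(spike_times) else np.empty(0)
    pooled = pooled[(pooled >= t_begin) & (pooled < edges[-1])]
    counts, _ = np.histogram(pooled, bins=edges)
    return 0.5 * (edges[:-1] + edges[1:]), counts.astype(float)


def detect_volleys(hist: np.ndarray, threshold: float) -> np.ndarray:
    """Indices of spike-volley peaks: discrete-derivative sign change from
    positive to non-positive, with height at least the threshold.

    A flat plateau apex is attributed to its first bin.
    """
    a = np.asarray(hist, dtype=float)
    if a.size < 3:
        return np.empty(0, dtype=np.int64)
    d = np.diff(a)
    rising = d[:-1] > 0
    falling = d[1:] <= 0
    peaks = np.nonzero(rising & falling)[0] + 1
    return peaks[a[peaks] >= threshold]


def mean_volley_height(hist: np.ndarray, threshold: float) -> float:
    """Average height of detected volley peaks; 0 when none occur."""
    peaks = detect_volleys(hist, threshold)
    if peaks.size == 0:
        return 0.0
    return float(np.asarray(hist, dtype=float)[peaks].mean())


@dataclass
class PhaseHistogram:
    """Theta-period-folded population activity."""

    counts: np.ndarray      # per phase bin
    bin_size: float         # ms
    period: float           # ms

    @property
    def phase(self) -> np.ndarray:
        """Phase (rad) of each bin centre: the sine argument of the cycle."""
        t = (np.arange(self.counts.size) + 0.5) * self.bin_size
        return 2.0 * np.pi * t / self.period


def aggregate_theta(spike_times, t_begin: float, t_end: float,
                    f_theta: float, bin_size: float = VOLLEY_BIN
                    ) -> PhaseHistogram:
    """Fold the pooled spike histogram over complete theta periods.

    The analysis window is truncated to an integer number of periods.
    """
    period = 1000.0 / f_theta
    n_per = int(np.floor((t_end - t_begin) / period))
    if n_per < 1:
        raise ValueError("window shorter than one theta period")
    t_end = t_begin + n_per * period
    _, counts = population_histogram(spike_times, t_begin, t_end, bin_size)
    n_bins = int(round(period / bin_size))
    folded = counts[: n_per * n_bins].reshape(n_per, n_bins).sum(axis=0)
    return PhaseHistogram(folded.astype(float), bin_size, period)


def theta_r2(hist: PhaseHistogram, amplitude: float = 1.0) -> float:
    """Squared Pearson correlation of the folded activity with raw theta."""
    t = (np.arange(hist.counts.size) + 0.5) * hist.bin_size
    ref = raw_theta(t, amplitude, 1000.0 / hist.period)
    a = hist.counts
    if np.std(a) == 0 or np.std(ref) == 0:
        import warnings
        warnings.warn("zero-variance profile; r^2 undefined, returning 0")
        return 0.0
    r = np.corrcoef(a, ref)[0, 1]
    return float(r ** 2)


def modulation_score(hist: PhaseHistogram,
                     n_coarse_bins: int = M_COARSE_BINS) -> float:
    """Relative amplitude M of the coarse-binned phase profile.

    The profile is re-binned into ``n_coarse_bins`` phase bins (removing
    gamma-rate structure), then M = (max - min) / (2 * mean) — the relative
    amplitude of any theta oscillation in the population activity.
    """
    a = np.asarray(hist.counts, dtype=float)
    if a.sum() <= 0:
        raise ValueError("zero total activity")
    edges = np.linspace(0, a.size, n_coarse_bins + 1).astype(int)
    coarse = np.array([a[lo:hi].mean() for lo, hi in
                       zip(edges[:-1], edges[1:])])
    mean = coarse.mean()
    return float((coarse.max() - coarse.min()) / (2.0 * mean))
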