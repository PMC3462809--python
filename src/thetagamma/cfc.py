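"""Cross-frequency phase/amplitude coupling analysis.

The LFP is band-pass filtered to the gamma band and its analytic amplitude
A_gamma(t) is taken from the Hilbert transform.  Theta phase phi(t) comes
from the raw sinusoid driving the theta fibres, not from the LFP.  The two
are combined into the composite complex signal

    z(t) = A_gamma(t) * exp(i * phi_theta(t)).

Theta phase is uniformly distributed, so under independence the z cloud is
radially symmetric around the origin; clustering (a non-zero mean vector)
indicates phase/amplitude coupling.  Significance of the mean-vector norm is
assessed against phase-shuffled surrogates built by block permutation of the
amplitude series: because the theta reference is a perfect sinusoid, a plain
circular time shift would leave the norm of any theta-locked amplitude
component unchanged, so blocks much shorter than a theta period (but longer
than the gamma-envelope autocorrelation) are permuted instead, scrambling
the phase alignment while preserving the envelope's local statistics.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal, stats

GAMMA_BAND = (30.0, 80.0)   # Hz
POLAR_PHASE_BINS = 16
POLAR_AMP_BINS = 20
EXTREME_WINDOW = np.pi / 4  # width of the peak/trough phase windows (rad)

THETA_PEAK = np.pi / 2      # sine-phase convention
THETA_TROUGH = -np.pi / 2


def bandpass_gamma(lfp: np.ndarray, fs: float,
                   band: tuple[float, float] = GAMMA_BAND) -> np.ndarray:
    """Zero-phase FIR band-pass of the LFP to the gamma band."""
    lo, hi = band
    if hi >= fs / 2:
        raise ValueError("band extends beyond the Nyquist frequency")
    x = np.asarray(lfp, dtype=float)
    numtaps = int(np.ceil(3.3 * fs / (0.2 * lo)))
    numtaps = min(numtaps | 1, (x.size - 1) | 1)
    h = signal.firwin(numtaps, [lo, hi], pass_zero=False, fs=fs)
    return signal.fftconvolve(x - x.mean(), h, mode="same")


@dataclass
class AnalyticSignal:
    """Instantaneous amplitude and phase from the Hilbert transform."""

    amplitude: np.ndarray
    phase: np.ndarray


def analytic(x: np.ndarray) -> AnalyticSignal:
    """Analytic representation of a detrended signal."""
    x = np.asarray(x, dtype=float)
    z = signal.hilbert(x - x.mean())
    return AnalyticSignal(np.abs(z), np.angle(z))


def edge_trim(n: int, fs: float, band_lo: float = GAMMA_BAND[0]) -> slice:
    """Samples to keep after discarding filter/Hilbert transients.

    Half a filter length (of the gamma band-pass) is dropped at each end.
    """
    half = int(np.ceil(3.3 * fs / (0.2 * band_lo)) // 2)
    half = min(half, n // 4)
    return slice(half, n - half)


def composite_z(gamma_amplitude: np.ndarray,
                theta_phase: np.ndarray) -> np.ndarray:
    """Composite phase/amplitude samples z = A_gamma * exp(i phi_theta)."""
    a = np.asarray(gamma_amplitude, dtype=float)
    p = np.asarray(theta_phase, dtype=float)
    if a.shape != p.shape:
        raise ValueError("amplitude and phase grids differ")
    return a * np.exp(1j * p)


def mean_vector(z: np.ndarray) -> complex:
    return complex(np.mean(z))


def mean_vector_norm(z: np.ndarray) -> float:
    return float(abs(np.mean(z)))


def surrogate_norms(gamma_amplitude: np.ndarray, theta_phase: np.ndarray,
                    n_surrogates: int = 200,
                    rng: np.random.Generator | None = None,
                    block: int = 50) -> np.ndarray:
    """Mean-vector norms under block permutation of the amplitude series.

    ``block`` is the permuted block length in samples; it should exceed the
    gamma-envelope autocorrelation time and stay well below a theta period.
    """
    rng = rng or np.random.default_rng(0)
    a = np.asarray(gamma_amplitude, dtype=float)
    n = a.size
    n_blocks = n // block
    if n_blocks < 4:
        raise ValueError("too few blocks for a surrogate distribution")
    trimmed = a[: n_blocks * block].reshape(n_blocks, block)
    phase = np.exp(1j * np.asarray(theta_phase, dtype=float)[: n_blocks * block])
    out = np.empty(n_surrogates)
    for i in range(n_surrogates):
        perm = trimmed[rng.permutation(n_blocks)].ravel()
        out[i] = abs(np.mean(perm * phase))
    return out


def combined_coupling(amplitudes: list[np.ndarray],
                      phases: list[np.ndarray],
                      n_surrogates: int = 200,
                      rng: np.random.Generator | None = None,
                      block: int = 50) -> tuple[float, np.ndarray]:
    """Coupling norm pooled coherently over independent runs, with its null.

    The theta-locked mean vector shares its phase across runs (all runs are
    locked to the same theta clock), so the per-run complex means are
    averaged before taking the norm; surrogate draws permute each run's
    amplitude blocks independently and are combined the same way, which
    shrinks the null by 1/sqrt(n_runs) while leaving genuine coupling
    untouched.  Returns (norm, surrogate norms).
    """
    rng = rng or np.random.default_rng(0)
    if len(amplitudes) != len(phases) or not amplitudes:
        raise ValueError("need matching, non-empty run lists")
    means = []
    runs = []
    for a, p in zip(amplitudes, phases):
        a = np.asarray(a, dtype=float)
        n_blocks = a.size // block
        if n_blocks < 4:
            raise ValueError("too few blocks for a surrogate distribution")
        trimmed = a[: n_blocks * block].reshape(n_blocks, block)
        ph = np.exp(1j * np.asarray(p, dtype=float)[: n_blocks * block])
        means.append(np.mean(trimmed.ravel() * ph))
        runs.append((trimmed, ph, n_blocks))
    norm = float(abs(np.mean(means)))
    sur = np.empty(n_surrogates)
    for i in range(n_surrogates):
        acc = 0.0 + 0.0j
        for trimmed, ph, n_blocks in runs:
            perm = trimmed[rng.permutation(n_blocks)].ravel()
            acc += np.mean(perm * ph)
        sur[i] = abs(acc / len(runs))
    return norm, sur


def polar_histogram(z: np.ndarray,
                    n_phase_bins: int = POLAR_PHASE_BINS,
                    n_amp_bins: int = POLAR_AMP_BINS):
    """2-D histogram of z over (phase, amplitude) bins.

    Phase bins are uniform on the circle with a bin *edge* at phase 0 (hence
    also at the theta peak and trough); amplitude bins are uniform from 0 to
    the sample maximum.  Returns (counts, phase_edges, amp_edges).
    """
    z = np.asarray(z)
    if z.size == 0:
        raise ValueError("no samples")
    ph = np.mod(np.angle(z), 2.0 * np.pi)
    am = np.abs(z)
    phase_edges = np.linspace(0.0, 2.0 * np.pi, n_phase_bins + 1)
    amp_edges = np.linspace(0.0, am.max() * (1 + 1e-12) or 1.0,
                            n_amp_bins + 1)
    counts, _, _ = np.histogram2d(ph, am, bins=[phase_edges, amp_edges])
    return counts, phase_edges, amp_edges


def peak_and_trough_amplitudes(z: np.ndarray,
                               window_width: float = EXTREME_WINDOW):
    """Gamma-amplitude samples in phase windows *centred* at the theta peak
    (+pi/2) and trough (-pi/2).  Returns (peak_samples, trough_samples)."""
    if window_width <= 0:
        raise ValueError("window width must be positive")
    z = np.asarray(z)
    ph = np.angle(z)
    am = np.abs(z)
    half = window_width / 2.0

    def _window(center):
        d = np.angle(np.exp(1j * (ph - center)))
        return am[np.abs(d) <= half]

    return _window(THETA_PEAK), _window(THETA_TROUGH)


def fit_gamma_dist(samples: np.ndarray) -> tuple[float, float]:
    """Maximum-likelihood gamma-distribution fit; returns (shape, scale)."""
    x = np.asarray(samples, dtype=float)
    if x.size == 0 or np.any(x <= 0):
        raise ValueError("gamma fit requires positive samples")
    if np.ptp(x) == 0:
        raise ValueError("degenerate (constant) sample")
    shape, _, scale = stats.gamma.fit(x, floc=0.0)
    return float(shape), float(scale)


def peak_gamma_frequency_track(lfp: np.ndarray, fs: float,
                               band: tuple[float, float] = GAMMA_BAND,
                               window_ms: float = 250.0,
                               hop_ms: float = 10.0,
                               statistic: str = "argmax"):
    """Per-time-slice dominant frequency within the gamma band.

    Short-time Fourier transform with a Hann window; returns (t_ms, f_Hz).
    ``statistic`` selects the per-slice reduction: ``"argmax"`` is the
    frequency of maximal power (the plotted peak-frequency track);
    ``"centroid"`` is the power-weighted mean frequency, which varies
    smoothly and resolves small frequency shifts that the grid-quantized
    argmax misses on short, noisy segments.
    """
    x = np.asarray(lfp, dtype=float)
    nperseg = min(int(round(window_ms * fs / 1000.0)), x.size)
    hop = max(1, int(round(hop_ms * fs / 1000.0)))
    f, t, s = signal.stft(x - x.mean(), fs=fs, window="hann",
                          nperseg=nperseg, noverlap=nperseg - hop,
                          boundary=None, padded=False)
    power = np.abs(s) ** 2
    sel = (f >= band[0]) & (f <= band[1])
    if statistic == "argmax":
        track = f[sel][np.argmax(power[sel], axis=0)]
    elif statistic == "centroid":
        p = power[sel]
        track = (f[sel][:, None] * p).sum(axis=0) / p.sum(axis=0)
    else:
        raise ValueError("statistic must be 'argmax' or 'centroid'")
    return t * 1000.0, track


def theta_gamma_envelope_correlation(theta_ref: np.ndarray,
                                     gamma_amplitude: np.ndarray) -> float:
    """Pearson correlation between the theta input and the gamma envelope."""
    a = np.asarray(theta_ref, dtype=float)
    b = np.asarray(gamma_amplitude, dtype=float)
    if a.shape != b.shape:
        raise ValueError("signals must share the time grid")
    if np.std(b) == 0:
        raise ValueError("zero-variance envelope")
    return float(np.corrcoef(a, b)[0, 1])


def envelope_lag(theta_ref: np.ndarray, gamma_amplitude: np.ndarray,
                 fs: float, max_lag_ms: float = 500.0) -> float:
    """Lag (ms) maximizing the correlation of -theta with the gamma envelope.

    Positive values mean the envelope trails the (inverted) theta extremes.
    """
    a = -np.asarray(theta_ref, dtype=float)
    b = np.asarray(gamma_amplitude, dtype=float)
    a = a - a.mean()
    b = b - b.mean()
    corr = signal.correlate(b, a, mode="full")
    lags = signal.correlation_lags(b.size, a.size, mode="full")
    keep = np.abs(lags) <= max_lag_ms * fs / 1000.0
    best = lags[keep][np.argmax(corr[keep])]
    return float(best * 1000.0 / fs)
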