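"""Afferent input: heterogeneous DC drive, Poisson fibre pools, theta signal.

The heterogeneous direct-current drive (FS-ring experiments) draws a mean
amplitude per cell from a normal distribution around the population mean,
then redraws the actual amplitude around that cell mean in fixed time
windows; both spreads are parameterized as coefficients of variation.

Afferent fibres are Bernoulli-thinned Poisson processes: in every window of
length dt a fibre spikes with probability rate * dt.  The theta pool
modulates its rate sinusoidally,

    r(t) = r_mean * (1 + a * sin(2 pi f_theta t)),   clipped at 0,

and the same sinusoid (the "raw" theta signal) later serves as the phase
reference for cross-frequency analysis: theta phase is the sine argument,
so a theta peak sits at +pi/2 and a trough at -pi/2.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "DriveSchedule", "draw_drive", "theta_rate", "raw_theta", "theta_phase",
    "generate_poisson_trains", "PoissonPool",
]


@dataclass
class DriveSchedule:
    """Per-cell, per-window DC drive amplitudes (uA/cm^2)."""

    mu: float
    cv_cells: float
    cv_time: float
    window: float                 # ms
    cell_means: np.ndarray        # (n_cells,)
    amplitudes: np.ndarray        # (n_cells, n_windows)

    def at(self, t: float) -> np.ndarray:
        """Drive per cell at time t (ms)."""
        w = min(int(t // self.window), self.amplitudes.shape[1] - 1)
        return self.amplitudes[:, w]


def draw_drive(mu: float, cv_cells: float, cv_time: float, window: float,
               n_cells: int, duration: float,
               rng: np.random.Generator) -> DriveSchedule:
    """Draw the two-level heterogeneous drive schedule."""
    if cv_cells < 0 or cv_time < 0:
        raise ValueError("coefficients of variation must be non-negative")
    if window <= 0:
        raise ValueError("window must be positive")
    n_windows = max(1, int(np.ceil(duration / window)))
    cell_means = rng.normal(mu, cv_cells * abs(mu), size=n_cells)
    sd_t = cv_time * np.abs(cell_means)
    amplitudes = rng.normal(cell_means[:, None],
                            np.broadcast_to(sd_t[:, None],
                                            (n_cells, n_windows)))
    return DriveSchedule(mu, cv_cells, cv_time, window, cell_means, amplitudes)


def theta_rate(t, r_mean: float, a: float, f_theta: float):
    """Instantaneous theta-pool rate (Hz); t in ms; negative values clip to 0."""
    if a < 0:
        raise ValueError("amplitude must be non-negative")
    t = np.asarray(t, dtype=float)
    r = r_mean * (1.0 + a * np.sin(2.0 * np.pi * f_theta * t * 1e-3))
    return np.maximum(r, 0.0)


def raw_theta(t, amplitude: float = 1.0, f_theta: float = 4.0):
    """The raw theta reference signal, a pure sinusoid; t in ms."""
    t = np.asarray(t, dtype=float)
    return amplitude * np.sin(2.0 * np.pi * f_theta * t * 1e-3)


def theta_phase(t, f_theta: float = 4.0):
    """Theta phase in (-pi, pi]: the sine argument wrapped; peak at +pi/2."""
    t = np.asarray(t, dtype=float)
    ph = 2.0 * np.pi * f_theta * t * 1e-3
    return np.angle(np.exp(1j * ph))


def generate_poisson_trains(rate_fn, n_fibres: int, dt: float,
                            duration: float, rng: np.random.Generator):
    """Spike trains for a fibre pool; ``rate_fn(t_ms) -> Hz`` (scalar or vector).

    Returns a list of spike-time arrays (ms), one per fibre.  At most one
    spike per fibre per dt window; requires rate * dt < 1.
    """
    n_steps = int(round(duration / dt))
    t = np.arange(n_steps) * dt
    rates = np.broadcast_to(np.asarray(rate_fn(t), dtype=float), (n_steps,))
    p = rates * dt * 1e-3
    if np.any(p >= 1.0):
        raise ValueError("rate * dt must stay below 1 spike per window")
    hits = rng.random((n_fibres, n_steps)) < p[None, :]
    return [t[row] for row in hits]


class PoissonPool:
    """Online Bernoulli spike source for one fibre pool (engine-facing)."""

    def __init__(self, n_fibres: int, rate_fn, dt: float,
                 rng: np.random.Generator):
        self.n_fibres = n_fibres
        self.rate_fn = rate_fn
        self.dt = dt
        self.rng = rng

    def spikes_at(self, t: float) -> np.ndarray:
        """Indices of fibres spiking in the window starting at t (ms)."""
        p = float(np.asarray(self.rate_fn(t))) * self.dt * 1e-3
        if p <= 0.0:
            return np.empty(0, dtype=np.int64)
        if p >= 1.0:
            raise ValueError("rate * dt must stay below 1 spike per window")
        return np.nonzero(self.rng.random(self.n_fibres) < p)[0]
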