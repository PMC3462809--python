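"""Chemical synapse kinetics and gap-junction coupling.

A synaptic event inserts a conductance with a bi-exponential time course

    g(t) = g_max * N * (exp(-t/tau_decay) - exp(-t/tau_rise)),  t >= 0

where N normalizes the peak of the difference-of-exponentials to 1 so that
the peak conductance equals g_max.  The same code path serves GABA, AMPA and
NMDA; the three receptor kinds differ only in their (tau_rise, tau_decay),
g_max and reversal potential.  Events superpose linearly, which allows the
whole convergent input of one receptor kind onto a cell to be carried by a
single pair of exponential state variables.
"""
from __future__ import annotations

import math

import numpy as np

from .params import GapJunctionSpec, SynapseSpec

__all__ = [
    "biexp_peak_time",
    "biexp_normalization",
    "ExpSynGates",
    "synaptic_current",
    "gap_current",
]


def biexp_peak_time(tau_rise: float, tau_decay: float) -> float:
    """Time of the conductance maximum after a single event (ms)."""
    if not 0.0 < tau_rise < tau_decay:
        raise ValueError("need 0 < tau_rise < tau_decay")
    return (tau_decay * tau_rise / (tau_decay - tau_rise)) * math.log(
        tau_decay / tau_rise
    )


def biexp_normalization(tau_rise: float, tau_decay: float) -> float:
    """Factor N with N*(exp(-t_pk/tau_d) - exp(-t_pk/tau_r)) = 1."""
    t_pk = biexp_peak_time(tau_rise, tau_decay)
    return 1.0 / (math.exp(-t_pk / tau_decay) - math.exp(-t_pk / tau_rise))


class ExpSynGates:
    """Aggregated bi-exponential gates for one receptor kind on a population.

    State ``a`` carries the decay exponential and ``b`` the rise exponential;
    the population conductance is ``a - b``.  ``add_events(w)`` increments
    both states by ``w`` (already scaled by N * g_max per arriving event), so
    the trace after an isolated unit event peaks exactly at ``g_max``.
    """

    def __init__(self, n_cells: int, spec: SynapseSpec, dt: float):
        self.spec = spec
        self.norm = biexp_normalization(spec.tau_rise, spec.tau_decay)
        self._decay_a = math.exp(-dt / spec.tau_decay)
        self._decay_b = math.exp(-dt / spec.tau_rise)
        self.a = np.zeros(n_cells)
        self.b = np.zeros(n_cells)

    def step(self) -> None:
        """Advance the gates one time step (exact exponential decay)."""
        self.a *= self._decay_a
        self.b *= self._decay_b

    def add_events(self, counts: np.ndarray) -> None:
        """Register ``counts`` presynaptic events per cell (may be float)."""
        w = self.norm * self.spec.g_max
        self.a += w * counts
        self.b += w * counts

    @property
    def g(self) -> np.ndarray:
        """Instantaneous conductance per cell (mS/cm^2)."""
        return self.a - self.b

    def current(self, v: np.ndarray) -> np.ndarray:
        return synaptic_current(self.g, v, self.spec.e_syn)


def synaptic_current(g, v_post, e_syn):
    """Synaptic current (uA/cm^2), positive = depolarizing.

    With ``e_syn`` above ``v_post`` the current is positive, so a shunting
    GABA event (reversal above rest) depolarizes a cell sitting at rest.
    """
    return np.asarray(g) * (np.asarray(e_syn) - np.asarray(v_post))


def gap_current(v_i, v_j, spec: GapJunctionSpec):
    """Currents into cells i and j of a gap-junction pair (sum to zero)."""
    i_into_i = spec.g_gap * (np.asarray(v_j) - np.asarray(v_i))
    return i_into_i, -i_into_i
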