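"""Single-compartment membrane dynamics for the two cell classes.

Fast-spiking (FS) interneurons follow the Wang-Buzsaki variant of the
Hodgkin-Huxley formalism: the Na activation gate m is replaced by its
steady-state value m_inf(V), and the h and n kinetics are sped up by the
factor phi, producing the fast-spiking phenotype.  Pyramidal (P) cells are
classical Hodgkin-Huxley neurons with a dynamic m gate (rate functions of
the standard point-process implementation, resting near -65 mV).

All rate functions take V in mV and return 1/ms.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Optional

import numpy as np
from scipy.optimize import brentq

from .params import CellParameters, WB_FS, HH_P

SPIKE_THRESHOLD = 0.0   # mV, upward crossing counts as a spike
REFRACTORY = 1.0        # ms, for spike counting


def _vtrap(x, y):
    """x / (1 - exp(-x/y)) with the analytic limit y at x -> 0."""
    x = np.asarray(x, dtype=float)
    z = np.clip(x / y, -50.0, 50.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = x / -np.expm1(-z)
    small = np.abs(z) < 1e-6
    if np.any(small):
        out = np.where(small, y * (1.0 + z / 2.0), out)
    return out


# -- Wang-Buzsaki (FS) rate functions -----------------------------------------

def wb_alpha_m(v):
    return 0.1 * _vtrap(v + 35.0, 10.0)


def wb_beta_m(v):
    return 4.0 * np.exp(-(np.asarray(v, dtype=float) + 60.0) / 18.0)


def wb_m_inf(v):
    """Steady-state Na activation used in place of a dynamic m gate."""
    a, b = wb_alpha_m(v), wb_beta_m(v)
    return a / (a + b)


def wb_alpha_h(v):
    return 0.07 * np.exp(-(np.asarray(v, dtype=float) + 58.0) / 20.0)


def wb_beta_h(v):
    return 1.0 / (1.0 + np.exp(-(np.asarray(v, dtype=float) + 28.0) / 10.0))


def wb_alpha_n(v):
    return 0.01 * _vtrap(v + 34.0, 10.0)


def wb_beta_n(v):
    return 0.125 * np.exp(-(np.asarray(v, dtype=float) + 44.0) / 80.0)


# -- classical HH (P) rate functions ------------------------------------------

def hh_alpha_m(v):
    return 0.1 * _vtrap(v + 40.0, 10.0)


def hh_beta_m(v):
    return 4.0 * np.exp(-(np.asarray(v, dtype=float) + 65.0) / 18.0)


def hh_alpha_h(v):
    return 0.07 * np.exp(-(np.asarray(v, dtype=float) + 65.0) / 20.0)


def hh_beta_h(v):
    return 1.0 / (1.0 + np.exp(-(np.asarray(v, dtype=float) + 35.0) / 10.0))


def hh_alpha_n(v):
    return 0.01 * _vtrap(v + 55.0, 10.0)


def hh_beta_n(v):
    return 0.125 * np.exp(-(np.asarray(v, dtype=float) + 65.0) / 80.0)


def _inf(alpha: Callable, beta: Callable, v):
    a, b = alpha(v), beta(v)
    return a / (a + b)


@dataclass
class MembraneState:
    """V (mV) plus gating variables; m is present only for the HH class."""

    v: np.ndarray
    h: np.ndarray
    n: np.ndarray
    m: Optional[np.ndarray] = None

    def copy(self) -> "MembraneState":
        return MembraneState(
            self.v.copy(), self.h.copy(), self.n.copy(),
            None if self.m is None else self.m.copy(),
        )


def _channel_currents(kind: str, state: MembraneState, p: CellParameters):
    v = state.v
    if kind == "wb":
        m = wb_m_inf(v)
    else:
        m = state.m
    i_na = p.g_na * m ** 3 * state.h * (v - p.e_na)
    i_k = p.g_k * state.n ** 4 * (v - p.e_k)
    i_l = p.g_l * (v - p.e_l)
    return i_na, i_k, i_l


def wb_derivatives(state: MembraneState, p: CellParameters, i_total):
    """Right-hand side of the WB model; i_total in uA/cm^2 (depolarizing > 0)."""
    v = state.v
    i_na, i_k, i_l = _channel_currents("wb", state, p)
    dv = (np.asarray(i_total) - i_l - i_na - i_k) / p.c_m
    dh = p.phi * (wb_alpha_h(v) * (1.0 - state.h) - wb_beta_h(v) * state.h)
    dn = p.phi * (wb_alpha_n(v) * (1.0 - state.n) - wb_beta_n(v) * state.n)
    return MembraneState(dv, dh, dn)


def hh_derivatives(state: MembraneState, p: CellParameters, i_total):
    """Right-hand side of the classical HH model (dynamic m gate)."""
    if state.m is None:
        raise ValueError("HH state requires an m gate")
    v = state.v
    i_na, i_k, i_l = _channel_currents("hh", state, p)
    dv = (np.asarray(i_total) - i_l - i_na - i_k) / p.c_m
    dm = p.phi * (hh_alpha_m(v) * (1.0 - state.m) - hh_beta_m(v) * state.m)
    dh = p.phi * (hh_alpha_h(v) * (1.0 - state.h) - hh_beta_h(v) * state.h)
    dn = p.phi * (hh_alpha_n(v) * (1.0 - state.n) - hh_beta_n(v) * state.n)
    return MembraneState(dv, dh, dn, dm)


def steady_state(kind: str, p: CellParameters, n_cells: int = 1) -> MembraneState:
    """Resting fixed point (zero input) of one cell class, replicated n_cells."""
    v0 = resting_potential(kind, p)
    ones = np.ones(n_cells)
    if kind == "wb":
        return MembraneState(
            v0 * ones,
            _inf(wb_alpha_h, wb_beta_h, v0) * ones,
            _inf(wb_alpha_n, wb_beta_n, v0) * ones,
        )
    return MembraneState(
        v0 * ones,
        _inf(hh_alpha_h, hh_beta_h, v0) * ones,
        _inf(hh_alpha_n, hh_beta_n, v0) * ones,
        _inf(hh_alpha_m, hh_beta_m, v0) * ones,
    )


def resting_potential(kind: str, p: CellParameters) -> float:
    """Solve I_ss(V) = 0 with all gates at steady state.

    The steady-state current can cross zero more than once (the upper
    crossing is the spike threshold); the root returned is the lowest
    crossing with positive slope of I_ss, i.e. the stable resting point.
    """

    def i_ss(v):
        if kind == "wb":
            st = MembraneState(
                np.array([v]),
                _inf(wb_alpha_h, wb_beta_h, v) * np.ones(1),
                _inf(wb_alpha_n, wb_beta_n, v) * np.ones(1),
            )
            i_na, i_k, i_l = _channel_currents("wb", st, p)
        else:
            st = MembraneState(
                np.array([v]),
                _inf(hh_alpha_h, hh_beta_h, v) * np.ones(1),
                _inf(hh_alpha_n, hh_beta_n, v) * np.ones(1),
                _inf(hh_alpha_m, hh_beta_m, v) * np.ones(1),
            )
            i_na, i_k, i_l = _channel_currents("hh", st, p)
        return float((i_na + i_k + i_l)[0])

    grid = np.linspace(-80.0, -45.0, 701)
    vals = np.array([i_ss(v) for v in grid])
    up = np.nonzero((vals[:-1] < 0) & (vals[1:] >= 0))[0]
    if up.size == 0:
        raise ValueError("no stable resting point found in [-80, -45] mV")
    lo, hi = grid[up[0]], grid[up[0] + 1]
    return brentq(i_ss, lo, hi, xtol=1e-10)


def integrate_single(
    kind: str,
    p: CellParameters,
    duration: float,
    dt: float = 0.025,
    i_dc: float = 0.0,
    i_of_t: Optional[Callable[[float], float]] = None,
    record: bool = False,
    state: Optional[MembraneState] = None,
):
    """Integrate one isolated cell with RK4; return spike times (and trace).

    ``i_of_t`` supplies a time-varying injected current (uA/cm^2) added to
    ``i_dc``.  Spikes are upward crossings of 0 mV with a 1 ms refractory,
    linearly interpolated within the step.
    """
    deriv = wb_derivatives if kind == "wb" else hh_derivatives
    st = state.copy() if state is not None else steady_state(kind, p)
    n_steps = int(round(duration / dt))
    spikes = []
    last_spike = -np.inf
    trace = np.empty(n_steps + 1) if record else None
    if record:
        trace[0] = st.v[0]
    for k in range(n_steps):
        t = k * dt
        i_ext = i_dc + (i_of_t(t) if i_of_t is not None else 0.0)
        v_old = st.v[0]
        st = _rk4_step(deriv, st, p, i_ext, dt)
        v_new = st.v[0]
        if record:
            trace[k + 1] = v_new
        if v_old < SPIKE_THRESHOLD <= v_new and (t - last_spike) > REFRACTORY:
            frac = (SPIKE_THRESHOLD - v_old) / (v_new - v_old)
            t_sp = t + frac * dt
            spikes.append(t_sp)
            last_spike = t_sp
        if not np.isfinite(v_new):
            raise FloatingPointError("membrane potential diverged")
    spikes = np.asarray(spikes)
    if record:
        return spikes, trace
    return spikes


def _axpy(s: MembraneState, d: MembraneState, c: float) -> MembraneState:
    return MembraneState(
        s.v + c * d.v, s.h + c * d.h, s.n + c * d.n,
        None if s.m is None else s.m + c * d.m,
    )


def _rk4_step(deriv, st, p, i_ext, dt):
    k1 = deriv(st, p, i_ext)
    k2 = deriv(_axpy(st, k1, dt / 2), p, i_ext)
    k3 = deriv(_axpy(st, k2, dt / 2), p, i_ext)
    k4 = deriv(_axpy(st, k3, dt), p, i_ext)
    out = st.copy()
    out.v = st.v + dt / 6 * (k1.v + 2 * k2.v + 2 * k3.v + k4.v)
    out.h = np.clip(st.h + dt / 6 * (k1.h + 2 * k2.h + 2 * k3.h + k4.h), 0.0, 1.0)
    out.n = np.clip(st.n + dt / 6 * (k1.n + 2 * k2.n + 2 * k3.n + k4.n), 0.0, 1.0)
    if st.m is not None:
        out.m = np.clip(st.m + dt / 6 * (k1.m + 2 * k2.m + 2 * k3.m + k4.m), 0.0, 1.0)
    return out


def fi_response(
    cell_kind: str,
    input_rate_grid,
    fibre_params: dict | None = None,
    seed: int = 0,
    duration: float = 2000.0,
    dt: float = 0.025,
):
    """Mean firing rate of an isolated cell driven by Poisson synaptic input.

    ``input_rate_grid`` is the total afferent spike rate (Hz, summed over all
    incoming fibres).  Each afferent event opens an AMPA and an NMDA
    conductance with the population-appropriate unitary strengths.  Returns
    (input rates, output rates in Hz).
    """
    from . import params as P
    from .synapses import ExpSynGates

    grid = np.asarray(input_rate_grid, dtype=float)
    if grid.size == 0:
        raise ValueError("empty input-rate grid")
    if cell_kind == "wb":
        cellp, ampa, nmda = WB_FS, P.ampa_on_fs(), P.nmda_on_fs()
    else:
        cellp, ampa, nmda = HH_P, P.ampa_on_p(), P.nmda_on_p()
    if fibre_params:
        ampa = ampa.with_(**fibre_params.get("ampa", {}))
        nmda = nmda.with_(**fibre_params.get("nmda", {}))
    deriv = wb_derivatives if cell_kind == "wb" else hh_derivatives
    rng = np.random.default_rng(seed)
    n_steps = int(round(duration / dt))
    n = grid.size
    # one independent cell per grid point, advanced in lock-step
    st = steady_state(cell_kind, cellp, n_cells=n)
    ga = ExpSynGates(n, ampa, dt)
    gn = ExpSynGates(n, nmda, dt)
    p_event = grid * dt * 1e-3
    if np.any(p_event >= 1.0):
        raise ValueError("rate * dt must stay below 1 event per step")
    n_spk = np.zeros(n)
    last_spike = np.full(n, -np.inf)
    for k in range(n_steps):
        ga.step()
        gn.step()
        events = (rng.random(n) < p_event).astype(float)
        if events.any():
            ga.add_events(events)
            gn.add_events(events)
        i_syn = ga.current(st.v) + gn.current(st.v)
        v_old = st.v.copy()
        st = _rk4_step(deriv, st, cellp, i_syn, dt)
        t = k * dt
        crossed = (v_old < SPIKE_THRESHOLD) & (st.v >= SPIKE_THRESHOLD) \
            & ((t - last_spike) > REFRACTORY)
        n_spk += crossed
        last_spike = np.where(crossed, t, last_spike)
    return grid, n_spk / (duration * 1e-3)
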