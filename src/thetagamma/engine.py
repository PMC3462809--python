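"""Network integration engine and simulated LFP.

The full model is advanced with a fixed-step exponential-Euler scheme: at
every step each membrane is relaxed toward the instantaneous steady state
set by its total conductance load (channels evaluated at the current gate
values, synaptic gates, gap junctions), and the gating variables relax
toward their voltage-dependent targets.  Gap-junction coupling uses the
previous-step voltages (explicit coupling); recurrent synaptic events take
effect after a short fixed latency, afferent fibre events on the following
step.  The update is deterministic and order-independent, so identical
seeds give identical spike rasters.

Following the simulation protocol, cells evolve uncoupled under their
afferent input from t = 0; recurrent synapses and gap junctions are inserted
at ``t_connect`` and all analyses start at ``t_analysis``, so that no
initialization transient contaminates the results.

The simulated LFP is the negative summed pyramidal membrane potential,
low-pass filtered with a zero-phase FIR filter (the sign flip maps the
intracellular sum onto the extracellularly measured sign convention).  A
current-based variant sums the synaptic transmembrane currents of the P
cells instead.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import signal

from . import params as P
from .inputs import DriveSchedule, raw_theta, theta_rate
from .network import NetworkGraph
from .neurons import (
    REFRACTORY, SPIKE_THRESHOLD,
    hh_alpha_h, hh_alpha_m, hh_alpha_n, hh_beta_h, hh_beta_m, hh_beta_n,
    steady_state, wb_alpha_h, wb_alpha_n, wb_beta_h, wb_beta_n, wb_m_inf,
)
from .synapses import ExpSynGates

DEFAULT_LFP_CUTOFF = 100.0  # Hz


@dataclass(frozen=True)
class SimulationProtocol:
    """Timing landmarks (ms) and integration step of one network run."""

    dt: float = 0.025
    t_connect: float = 100.0
    t_analysis: float = 300.0
    t_stop: float = 1300.0
    record_dt: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.t_connect < self.t_analysis < self.t_stop:
            raise ValueError("need 0 < t_connect < t_analysis < t_stop")


@dataclass
class SimulationResult:
    """Spike times, LFP precursors and the theta reference of one run."""

    protocol: SimulationProtocol
    spikes_fs: list          # per-cell arrays of spike times (ms)
    spikes_p: list
    t_rec: np.ndarray        # record grid (ms)
    v_sum_neg: np.ndarray    # -sum of P membrane potentials on t_rec
    i_syn_p_sum: np.ndarray  # summed synaptic currents onto P cells on t_rec
    theta: np.ndarray        # raw theta reference on t_rec
    f_theta: float
    v_traces: Optional[np.ndarray] = None   # (n_recorded, n_t) if requested

    @property
    def analysis_mask(self) -> np.ndarray:
        return self.t_rec >= self.protocol.t_analysis

    def lfp(self, cutoff: float = DEFAULT_LFP_CUTOFF,
            analysis_only: bool = True) -> tuple[np.ndarray, np.ndarray]:
        """(t, LFP): low-pass filtered negative summed P potential."""
        fs = 1000.0 / self.protocol.record_dt
        out = fir_lowpass(self.v_sum_neg, fs, cutoff)
        if analysis_only:
            m = self.analysis_mask
            return self.t_rec[m], out[m]
        return self.t_rec, out

    def lfp_current_variant(self, cutoff: float = DEFAULT_LFP_CUTOFF,
                            analysis_only: bool = True):
        """(t, LFP) from summed P-cell synaptic currents, same filtering."""
        fs = 1000.0 / self.protocol.record_dt
        out = fir_lowpass(self.i_syn_p_sum, fs, cutoff)
        if analysis_only:
            m = self.analysis_mask
            return self.t_rec[m], out[m]
        return self.t_rec, out


def fir_lowpass(x: np.ndarray, fs: float, cutoff: float) -> np.ndarray:
    """Zero-phase FIR low-pass (symmetric kernel, FFT convolution).

    Kernel length is chosen so the transition band stays below 20% of the
    cutoff frequency.
    """
    x = np.asarray(x, dtype=float)
    if x.size == 0:
        raise ValueError("empty signal")
    numtaps = int(np.ceil(3.3 * fs / (0.2 * cutoff)))
    numtaps = min(numtaps | 1, (x.size - 1) | 1)
    h = signal.firwin(numtaps, cutoff, fs=fs)
    return signal.fftconvolve(x, h, mode="same")


class _Fanout:
    """Adjacency by presynaptic index, for fast spike-event scattering."""

    def __init__(self, edges: np.ndarray, n_post: int, n_pre: int):
        self.n_post = n_post
        order = np.argsort(edges[0], kind="stable")
        pre = edges[0][order]
        self.post = edges[1][order].astype(np.intp)
        self.ptr = np.searchsorted(pre, np.arange(n_pre + 1))

    def gather(self, idx: np.ndarray) -> np.ndarray:
        """Event counts per postsynaptic cell for presynaptic spikers."""
        parts = [self.post[self.ptr[i]:self.ptr[i + 1]] for i in idx]
        flat = np.concatenate(parts) if parts else np.empty(0, dtype=np.intp)
        if flat.size == 0:
            return None
        return np.bincount(flat, minlength=self.n_post).astype(float)


class _Population:
    """Vectorized exponential-Euler state for one cell class."""

    def __init__(self, kind: str, cellp: P.CellParameters, n: int, dt: float,
                 rng: np.random.Generator):
        self.kind = kind
        self.p = cellp
        self.n = n
        self.dt = dt
        st = steady_state(kind, cellp, n)
        st.v = st.v + rng.uniform(-5.0, 5.0, size=n)   # decorrelate start
        self.st = st
        self.last_spike = np.full(n, -np.inf)

    def channel_conductances(self):
        st, p = self.st, self.p
        m = wb_m_inf(st.v) if self.kind == "wb" else st.m
        g_na = p.g_na * m ** 3 * st.h
        g_k = p.g_k * st.n ** 4
        return g_na, g_k

    def step(self, g_syn_sum, ge_syn_sum, i_inj, t):
        """One exponential-Euler step; returns indices of spiking cells.

        ``g_syn_sum``/``ge_syn_sum`` are the summed synaptic + gap
        conductances and conductance-weighted reversal terms.
        """
        st, p, dt = self.st, self.p, self.dt
        g_na, g_k = self.channel_conductances()
        g_tot = p.g_l + g_na + g_k + g_syn_sum
        ge = (p.g_l * p.e_l + g_na * p.e_na + g_k * p.e_k
              + ge_syn_sum + i_inj)
        v_inf = ge / g_tot
        v_old = st.v
        v_new = v_inf + (v_old - v_inf) * np.exp(-dt * g_tot / p.c_m)

        # gate relaxation at the pre-step voltage
        if self.kind == "wb":
            gates = (("h", wb_alpha_h, wb_beta_h), ("n", wb_alpha_n, wb_beta_n))
        else:
            gates = (("h", hh_alpha_h, hh_beta_h), ("n", hh_alpha_n, hh_beta_n),
                     ("m", hh_alpha_m, hh_beta_m))
        for name, fa, fb in gates:
            a, b = fa(v_old), fb(v_old)
            x_inf = a / (a + b)
            x = getattr(st, name)
            setattr(st, name,
                    x_inf + (x - x_inf) * np.exp(-dt * p.phi * (a + b)))
        st.v = v_new

        crossed = (v_old < SPIKE_THRESHOLD) & (v_new >= SPIKE_THRESHOLD)
        if np.any(crossed):
            ok = (t - self.last_spike[crossed]) > REFRACTORY
            idx = np.nonzero(crossed)[0][ok]
        else:
            idx = np.empty(0, dtype=np.int64)
        if idx.size:
            frac = (SPIKE_THRESHOLD - v_old[idx]) / (v_new[idx] - v_old[idx])
            self.last_spike[idx] = t + frac * dt
        return idx


def run(network: NetworkGraph,
        protocol: SimulationProtocol = SimulationProtocol(),
        inputs: P.InputParams = P.InputParams(),
        *,
        drive: Optional[DriveSchedule] = None,
        poisson_input: bool = True,
        theta_to_fs: bool = True,
        theta_to_p: bool = True,
        gaba_fs: Optional[P.SynapseSpec] = None,
        gaba_p: Optional[P.SynapseSpec] = None,
        gap: Optional[P.GapJunctionSpec] = None,
        fs_only: bool = False,
        syn_delay: float = 0.5,
        record_v_fs: int = 0,
        record_v_p: int = 0) -> SimulationResult:
    """Integrate the network and record spikes, LFP precursors and theta.

    ``drive`` supplies the heterogeneous DC schedule to the FS cells (ring
    experiments); ``poisson_input`` enables the two afferent fibre pools.
    ``theta_to_fs``/``theta_to_p`` select the theta input condition.
    ``fs_only`` drops the P subnetwork entirely (FS-ring experiments).

    ``syn_delay`` (ms) is the latency between a presynaptic threshold
    crossing and the postsynaptic conductance onset of recurrent chemical
    synapses.  A short, sub-millisecond latency is what lets fast mutual
    inhibition synchronize the ring rather than split it into antiphase
    clusters; afferent fibre events and gap junctions are not delayed.
    """
    np_ = network.params
    dt = protocol.dt
    n_fs, n_p = np_.n_fs, (0 if fs_only else np_.n_p)
    gaba_fs = gaba_fs or P.gaba_on_fs()
    gaba_p = gaba_p or P.gaba_on_p()
    gap = gap or P.GapJunctionSpec(0.05)

    root = np.random.SeedSequence(protocol.seed)
    rng_init, rng_const, rng_theta = (np.random.default_rng(s)
                                      for s in root.spawn(3))

    fs = _Population("wb", P.WB_FS, n_fs, dt, rng_init)
    pp = _Population("hh", P.HH_P, n_p, dt, rng_init) if n_p else None

    # aggregated receptor gates per population
    syn_fs = {"GABA": ExpSynGates(n_fs, gaba_fs, dt),
              "AMPA": ExpSynGates(n_fs, P.ampa_on_fs(), dt),
              "NMDA": ExpSynGates(n_fs, P.nmda_on_fs(), dt)}
    syn_p = {"GABA": ExpSynGates(n_p, gaba_p, dt),
             "AMPA": ExpSynGates(n_p, P.ampa_on_p(), dt),
             "NMDA": ExpSynGates(n_p, P.nmda_on_p(), dt)} if n_p else None

    # adjacency by presynaptic index
    w_ff = _Fanout(network.fs_fs, n_fs, n_fs)
    if n_p:
        w_pf = _Fanout(network.p_fs, n_fs, n_p)
        w_pp = _Fanout(network.p_p, n_p, n_p)
        w_fp = _Fanout(network.fs_p, n_p, n_fs)
        wf_cp = _Fanout(network.const_p, n_p, np_.n_fibres_const)
        wf_tp = _Fanout(network.theta_p, n_p, np_.n_fibres_theta)
    wf_cf = _Fanout(network.const_fs, n_fs, np_.n_fibres_const)
    wf_tf = _Fanout(network.theta_fs, n_fs, np_.n_fibres_theta)

    if network.gap.size:
        gap_adj = np.zeros((n_fs, n_fs))
        gap_adj[network.gap[0], network.gap[1]] = 1.0
        gap_adj[network.gap[1], network.gap[0]] = 1.0
        gap_deg = gap_adj.sum(axis=1)
    else:
        gap_adj = None
        gap_deg = np.zeros(n_fs)

    pools = poisson_input
    if poisson_input:
        # per-step spike probabilities, precomputed over the whole run
        p_const = inputs.r_const * dt * 1e-3
        t_all = np.arange(int(round(protocol.t_stop / dt))) * dt
        p_theta = theta_rate(t_all, inputs.r_theta_mean,
                             inputs.theta_amplitude,
                             inputs.f_theta) * dt * 1e-3
        if p_const >= 1.0 or np.any(p_theta >= 1.0):
            raise ValueError("rate * dt must stay below 1 spike per window")

    n_steps = int(round(protocol.t_stop / dt))
    stride = max(1, int(round(protocol.record_dt / dt)))
    n_rec = n_steps // stride
    t_rec = (np.arange(n_rec) + 1) * stride * dt
    v_sum_neg = np.zeros(n_rec)
    i_syn_p_sum = np.zeros(n_rec)
    rec_fs = np.zeros((record_v_fs, n_rec)) if record_v_fs else None
    rec_p = np.zeros((record_v_p, n_rec)) if record_v_p else None

    spikes_fs: list[list[float]] = [[] for _ in range(n_fs)]
    spikes_p: list[list[float]] = [[] for _ in range(n_p)]

    # rotating event queues: fibre events land on the next step, recurrent
    # events after the synaptic latency
    d_steps = max(1, int(round(syn_delay / dt)))
    q_len = d_steps + 1
    q_fs = {k: np.zeros((q_len, n_fs)) for k in ("GABA", "AMPA", "NMDA")}
    q_p = {k: np.zeros((q_len, n_p)) for k in ("GABA", "AMPA", "NMDA")}
    dirty_fs = {k: np.zeros(q_len, dtype=bool) for k in q_fs}
    dirty_p = {k: np.zeros(q_len, dtype=bool) for k in q_p}
    ptr = 0

    connected = False
    for k in range(n_steps):
        t = k * dt
        if not connected and t >= protocol.t_connect:
            connected = True

        # deliver due events, then advance the gates
        for key, gates in syn_fs.items():
            gates.step()
            if dirty_fs[key][ptr]:
                buf = q_fs[key][ptr]
                gates.add_events(buf)
                buf.fill(0.0)
                dirty_fs[key][ptr] = False
        if n_p:
            for key, gates in syn_p.items():
                gates.step()
                if dirty_p[key][ptr]:
                    buf = q_p[key][ptr]
                    gates.add_events(buf)
                    buf.fill(0.0)
                    dirty_p[key][ptr] = False
        nxt = (ptr + 1) % q_len
        due = (ptr + d_steps) % q_len

        # fibre spikes act through AMPA and NMDA on the next step
        if pools:
            idx_c = np.nonzero(
                rng_const.random(np_.n_fibres_const) < p_const)[0]
            idx_t = np.nonzero(
                rng_theta.random(np_.n_fibres_theta) < p_theta[k])[0]
            if idx_c.size:
                cnt = wf_cf.gather(idx_c)
                if cnt is not None:
                    q_fs["AMPA"][nxt] += cnt
                    q_fs["NMDA"][nxt] += cnt
                    dirty_fs["AMPA"][nxt] = dirty_fs["NMDA"][nxt] = True
                if n_p:
                    cnt = wf_cp.gather(idx_c)
                    if cnt is not None:
                        q_p["AMPA"][nxt] += cnt
                        q_p["NMDA"][nxt] += cnt
                        dirty_p["AMPA"][nxt] = dirty_p["NMDA"][nxt] = True
            if idx_t.size:
                if theta_to_fs:
                    cnt = wf_tf.gather(idx_t)
                    if cnt is not None:
                        q_fs["AMPA"][nxt] += cnt
                        q_fs["NMDA"][nxt] += cnt
                        dirty_fs["AMPA"][nxt] = dirty_fs["NMDA"][nxt] = True
                if n_p and theta_to_p:
                    cnt = wf_tp.gather(idx_t)
                    if cnt is not None:
                        q_p["AMPA"][nxt] += cnt
                        q_p["NMDA"][nxt] += cnt
                        dirty_p["AMPA"][nxt] = dirty_p["NMDA"][nxt] = True

        # synaptic conductance load (recurrent input only once connected)
        g_sum_fs = np.zeros(n_fs)
        ge_sum_fs = np.zeros(n_fs)
        for gates in syn_fs.values():
            g = gates.g
            g_sum_fs += g
            ge_sum_fs += g * gates.spec.e_syn
        if connected and gap_adj is not None:
            g_sum_fs = g_sum_fs + gap.g_gap * gap_deg
            ge_sum_fs = ge_sum_fs + gap.g_gap * (gap_adj @ fs.st.v)

        i_inj_fs = drive.at(t) if drive is not None else 0.0
        idx_fs = fs.step(g_sum_fs, ge_sum_fs, i_inj_fs, t)

        if n_p:
            g_sum_p = np.zeros(n_p)
            ge_sum_p = np.zeros(n_p)
            i_syn_now = 0.0
            for gates in syn_p.values():
                g = gates.g
                g_sum_p += g
                ge_sum_p += g * gates.spec.e_syn
                i_syn_now += float(np.sum(g * (gates.spec.e_syn - pp.st.v)))
            idx_p = pp.step(g_sum_p, ge_sum_p, 0.0, t)
        else:
            idx_p = np.empty(0, dtype=np.int64)

        # recurrent propagation (only while connected)
        if connected:
            if idx_fs.size:
                cnt = w_ff.gather(idx_fs)
                if cnt is not None:
                    q_fs["GABA"][due] += cnt
                    dirty_fs["GABA"][due] = True
                if n_p:
                    cnt = w_fp.gather(idx_fs)
                    if cnt is not None:
                        q_p["GABA"][due] += cnt
                        dirty_p["GABA"][due] = True
            if idx_p.size:
                cnt = w_pf.gather(idx_p)
                if cnt is not None:
                    q_fs["AMPA"][due] += cnt
                    q_fs["NMDA"][due] += cnt
                    dirty_fs["AMPA"][due] = dirty_fs["NMDA"][due] = True
                cnt = w_pp.gather(idx_p)
                if cnt is not None:
                    q_p["AMPA"][due] += cnt
                    q_p["NMDA"][due] += cnt
                    dirty_p["AMPA"][due] = dirty_p["NMDA"][due] = True

        for i in idx_fs:
            spikes_fs[i].append(fs.last_spike[i])
        for i in idx_p:
            spikes_p[i].append(pp.last_spike[i])
        ptr = nxt

        if (k + 1) % stride == 0:
            r = (k + 1) // stride - 1
            if n_p:
                v_sum_neg[r] = -float(np.sum(pp.st.v))
                i_syn_p_sum[r] = i_syn_now
            if rec_fs is not None:
                rec_fs[:, r] = fs.st.v[:record_v_fs]
            if rec_p is not None and n_p:
                rec_p[:, r] = pp.st.v[:record_v_p]
            if not np.all(np.isfinite(fs.st.v)) or (
                    n_p and not np.all(np.isfinite(pp.st.v))):
                raise FloatingPointError(
                    f"membrane potential diverged at t={t:.2f} ms")

    traces = None
    if rec_fs is not None or rec_p is not None:
        traces = np.vstack([x for x in (rec_fs, rec_p) if x is not None])
    return SimulationResult(
        protocol=protocol,
        spikes_fs=[np.asarray(s) for s in spikes_fs],
        spikes_p=[np.asarray(s) for s in spikes_p],
        t_rec=t_rec,
        v_sum_neg=v_sum_neg,
        i_syn_p_sum=i_syn_p_sum,
        theta=raw_theta(t_rec, 1.0, inputs.f_theta),
        f_theta=inputs.f_theta,
        v_traces=traces,
    )


def compute_lfp(v_traces: np.ndarray, cutoff: float = DEFAULT_LFP_CUTOFF,
                fs: float = 1000.0) -> np.ndarray:
    """LFP from P-cell membrane traces: low-passed negative sum.

    ``v_traces`` is (n_cells, n_t); a 1-D input is treated as an already
    negated and summed potential.
    """
    v_traces = np.asarray(v_traces, dtype=float)
    if v_traces.size == 0:
        raise ValueError("no membrane traces supplied")
    raw = -v_traces.sum(axis=0) if v_traces.ndim == 2 else v_traces
    return fir_lowpass(raw, fs, cutoff)


def compute_lfp_current_variant(i_traces: np.ndarray,
                                cutoff: float = DEFAULT_LFP_CUTOFF,
                                fs: float = 1000.0) -> np.ndarray:
    """LFP variant from summed synaptic transmembrane currents of P cells."""
    i_traces = np.asarray(i_traces, dtype=float)
    if i_traces.size == 0:
        raise ValueError("no current traces supplied")
    raw = i_traces.sum(axis=0) if i_traces.ndim == 2 else i_traces
    return fir_lowpass(raw, fs, cutoff)
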