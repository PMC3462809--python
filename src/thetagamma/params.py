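"""Parameter containers and default parameter sets.

Units are fixed project-wide: mV, ms, uA/cm^2 for currents, mS/cm^2 for
conductances (membrane and synaptic, both expressed per unit area), um^2 for
membrane surface area.  Rates are in Hz where noted.
"""
from __future__ import annotations

from dataclasses import dataclass, asdict


@dataclass(frozen=True)
class CellParameters:
    """Channel densities and passive properties of one point-neuron class.

    ``phi`` is the dimensionless gating-speed factor applied to the h and n
    gate kinetics (the fast-spiking phenotype of the Wang-Buzsaki model is
    obtained with ``phi`` = 5; the pyramidal model uses 1).
    """

    name: str
    c_m: float          # uF/cm^2
    g_na: float         # mS/cm^2
    g_k: float          # mS/cm^2
    g_l: float          # mS/cm^2
    e_na: float         # mV
    e_k: float          # mV
    e_l: float          # mV
    phi: float
    area: float         # um^2 (metadata; dynamics are per-area)
    v_rest: float       # mV, nominal resting potential

    def __post_init__(self) -> None:
        for g in (self.g_na, self.g_k, self.g_l):
            if g < 0:
                raise ValueError("conductances must be non-negative")
        if self.phi <= 0:
            raise ValueError("phi must be positive")


#: Wang-Buzsaki fast-spiking interneuron.
WB_FS = CellParameters(
    name="wb_fs", c_m=1.0, g_na=35.0, g_k=9.0, g_l=0.1,
    e_na=55.0, e_k=-90.0, e_l=-65.0, phi=5.0, area=1.0e4, v_rest=-65.0,
)

#: Classical Hodgkin-Huxley pyramidal cell (rates shifted to rest near -65 mV).
HH_P = CellParameters(
    name="hh_p", c_m=1.0, g_na=120.0, g_k=36.0, g_l=0.3,
    e_na=50.0, e_k=-77.0, e_l=-54.3, phi=1.0, area=1.0e4, v_rest=-65.0,
)


@dataclass(frozen=True)
class SynapseSpec:
    """Bi-exponential chemical synapse: kind, kinetics, strength, reversal."""

    kind: str           # "GABA" | "AMPA" | "NMDA"
    tau_rise: float     # ms
    tau_decay: float    # ms
    g_max: float        # mS/cm^2, unitary peak conductance
    e_syn: float        # mV

    def __post_init__(self) -> None:
        if not 0.0 < self.tau_rise < self.tau_decay:
            raise ValueError("need 0 < tau_rise < tau_decay")
        if self.g_max < 0:
            raise ValueError("g_max must be non-negative")

    def with_(self, **kw) -> "SynapseSpec":
        d = asdict(self)
        d.update(kw)
        return SynapseSpec(**d)


@dataclass(frozen=True)
class GapJunctionSpec:
    """Ohmic electrical coupling with a constant conductance."""

    g_gap: float        # mS/cm^2

    def __post_init__(self) -> None:
        if self.g_gap < 0:
            raise ValueError("g_gap must be non-negative")


# Kinetic time constants: GABA per fast perisomatic basket-cell synapses,
# AMPA fast glutamatergic, NMDA slow glutamatergic (no Mg block; the NMDA
# conductance is a plain bi-exponential with its own time constants).
GABA_TAU = (0.16, 1.8)
AMPA_TAU = (0.5, 2.0)
NMDA_TAU = (2.0, 100.0)

E_GABA_SHUNT = -55.0    # mV, above rest: shunting
E_GABA_HYPER = -75.0    # mV, below rest: hyperpolarizing
E_GLU = 0.0             # mV


def gaba_on_fs(e_syn: float = E_GABA_SHUNT, g_max: float = 0.1) -> SynapseSpec:
    return SynapseSpec("GABA", *GABA_TAU, g_max=g_max, e_syn=e_syn)


def gaba_on_p(e_syn: float = E_GABA_SHUNT, g_max: float = 0.08) -> SynapseSpec:
    return SynapseSpec("GABA", *GABA_TAU, g_max=g_max, e_syn=e_syn)


def ampa_on_fs(g_max: float = 0.0018) -> SynapseSpec:
    return SynapseSpec("AMPA", *AMPA_TAU, g_max=g_max, e_syn=E_GLU)


def nmda_on_fs(g_max: float = 2.25e-5) -> SynapseSpec:
    return SynapseSpec("NMDA", *NMDA_TAU, g_max=g_max, e_syn=E_GLU)


def ampa_on_p(g_max: float = 0.0064) -> SynapseSpec:
    return SynapseSpec("AMPA", *AMPA_TAU, g_max=g_max, e_syn=E_GLU)


def nmda_on_p(g_max: float = 1.36e-4) -> SynapseSpec:
    return SynapseSpec("NMDA", *NMDA_TAU, g_max=g_max, e_syn=E_GLU)


@dataclass(frozen=True)
class NetworkParams:
    """Sizes, in-degrees and wiring parameters of the two-subnetwork model.

    The defaults are the full model: a ring of 100 fast-spiking cells, a
    20 x 20 pyramidal torus (the anatomically realistic 4:1 P:FS ratio), and
    mean in-degrees chosen to reproduce the anatomical synapse-type census.
    """

    n_fs: int = 100
    p_rows: int = 20
    p_cols: int = 20

    # mean in-degrees (expected number of incoming synapses per cell)
    m_fs_fs: float = 60.0    # GABA, within the ring
    m_p_fs: float = 63.0     # glutamate, P -> FS
    m_p_p: float = 100.0     # glutamate, within the torus
    m_fs_p: float = 22.0     # GABA, FS -> P

    # Gaussian footprint of the distance-dependent connection probability
    sigma_fs: float = 30.0   # cells
    d_max_fs: int = 50       # cells
    sigma_p: float = 5.0     # cells
    d_max_p: float = 8.0     # cells (Euclidean, after folding)

    # gap junctions among FS cells
    gap_neighbour_range: int = 2   # couple to the 2*range nearest neighbours
    gap_probability: float = 0.75  # -> on average 3 junctions per cell

    # afferent fibre fan-in per cell (constant-rate pool, theta pool)
    fibres_const_fs: float = 50.0
    fibres_theta_fs: float = 50.0
    fibres_const_p: float = 150.0
    fibres_theta_p: float = 25.0
    n_fibres_const: int = 1000
    n_fibres_theta: int = 1000

    @property
    def n_p(self) -> int:
        return self.p_rows * self.p_cols


#: Desk-scale profile: same architecture and per-cell input statistics at
#: roughly half the linear size, for sweeps and CI.
DESK_NET = NetworkParams(
    n_fs=50, p_rows=12, p_cols=12,
    m_fs_fs=30.0, m_p_fs=30.0, m_p_p=36.0, m_fs_p=22.0,
    sigma_fs=15.0, d_max_fs=25, sigma_p=3.0, d_max_p=5.0,
)

PAPER_NET = NetworkParams()


@dataclass(frozen=True)
class InputParams:
    """Afferent drive: Poisson fibre rates and the theta rate law."""

    r_const: float = 10.0     # Hz, constant-rate pool
    r_theta_mean: float = 10.0  # Hz, mean of the theta-modulated pool
    theta_amplitude: float = 1.0   # relative modulation amplitude a
    f_theta: float = 4.0      # Hz

    # heterogeneous DC drive (FS-ring experiments)
    i_mu: float = 1.0         # uA/cm^2
    cv_cells: float = 0.0
    cv_time: float = 0.05
    drive_window: float = 100.0  # ms
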