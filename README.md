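# thetagamma

A biophysical network model of how the hippocampal theta rhythm modulates
neocortical gamma oscillations, for computational neuroscientists studying
cross-frequency coupling mechanisms.

## The model

A patch of neocortex is simulated as two coupled conductance-based
subnetworks:

* a **ring of fast-spiking (FS) interneurons** (Wang–Buzsáki kinetics:
  m → m∞(V), h/n sped up by φ = 5) coupled by *shunting* GABA synapses
  (E_GABA = −55 mV, above the −65 mV rest) and gap junctions — the gamma
  generator (ING mechanism);
* a **torus of Hodgkin–Huxley pyramidal (P) cells** (4:1 P:FS ratio),
  receiving the FS rhythm through shunting GABA projections.

Both subnetworks receive Poisson afferent fibres: a constant-rate pool
(cortical background) and a theta pool whose rate follows
r(t) = r̄·(1 + a·sin 2πf_θt), the modelled hippocampal afferent.  The
simulated LFP is the low-pass-filtered negative sum of pyramidal membrane
potentials.

Analyses include the Wang–Buzsáki network coherence

κ = mean over pairs of Σ_l X(l)Y(l) / √(Σ_l X(l)·Σ_l Y(l))

on 1 ms binary bins, spike-volley peak heights, theta-phase-folded activity
profiles (Pearson r² against the theta sinusoid and the relative-amplitude
modulation score M), and the composite cross-frequency signal
z(t) = A_γ(t)·e^(iφ_θ(t)) combining the Hilbert amplitude of the 30–80 Hz
LFP with the raw theta phase; clustering of z in the complex plane (a mean
vector exceeding phase-shuffled surrogates) indicates theta-phase/gamma-
amplitude coupling.

The model's headline behaviours, each encoded as an automated test:

1. the connectivity census of the full network reproduces the anatomical
   synapse-type percentages;
2. shunting inhibition keeps the FS ring gamma-coherent at drive
   heterogeneities where hyperpolarizing inhibition fails;
3. FS→P projections impose gamma on the pyramidal LFP, with a fan-in
   threshold for P spike synchronization;
4. theta phase modulates gamma amplitude (higher at the theta trough) and
   gamma frequency (higher at the peak) **iff** the FS cells receive
   theta-modulated input.

## Worked example

```python
from thetagamma import build_network, run, SimulationProtocol, DESK_NET
from thetagamma import metrics

graph = build_network(DESK_NET, seed=0)
print(graph.census().round(2).to_string())

res = run(graph, SimulationProtocol(t_stop=1300.0, seed=0),
          theta_to_fs=True, theta_to_p=True)
kappa = metrics.network_coherence(res.spikes_fs, 300.0, 1300.0)
agg = metrics.aggregate_theta(res.spikes_p, 300.0, 1300.0, f_theta=4.0)
print(f"FS coherence kappa = {kappa:.3f}")
print(f"P theta modulation M = {metrics.modulation_score(agg):.3f}")
```

prints

```
FS->FS      3.53
P->FS       3.51
P->P       12.53
FS->P       7.80
ext->FS    12.01
ext->P     60.61
FS coherence kappa = 0.480
P theta modulation M = 0.245
```

— the desk-scale census (percent of all synapses by type; the half-scale
profile keeps per-cell input statistics, so its percentages differ from the
full-scale network, which reproduces the anatomical census), the FS
subnetwork's spike-train coherence on 1 ms bins during the analysis window,
and the relative amplitude of the theta modulation of pyramidal spiking
(M ≈ 0.25: pyramidal firing swings about ±25% around its mean over the
theta cycle at this amplitude and duration).

A command-line interface wraps the same library:

```sh
thetagamma census --profile paper --seeds 10
thetagamma simulate --profile desk --condition FS_only --out runs/fs_only
thetagamma sweep --kind cfc --profile desk --out cfc.json
```

## Layout

- `src/thetagamma/neurons.py` — WB and HH membrane dynamics, f–I curves
- `src/thetagamma/synapses.py` — bi-exponential receptor kinetics, gap junctions
- `src/thetagamma/network.py` — ring/torus wiring, census
- `src/thetagamma/inputs.py` — DC drive schedules, Poisson fibre pools, theta reference
- `src/thetagamma/engine.py` — network integration, simulated LFP
- `src/thetagamma/metrics.py` — κ, volley heights, r², modulation score M
- `src/thetagamma/cfc.py` — gamma band-pass, analytic signal, composite z, surrogates
- `src/thetagamma/experiments.py` — the experiment/sweep drivers
- `docs/methods.md` — model equations, parameter rationale, numerical choices
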