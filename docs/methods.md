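# Methods

## Model overview

The package simulates a small patch of neocortex receiving hippocampal
theta-rhythmic afferents.  Two conductance-based subnetworks are coupled:

* **FS subnetwork** — 100 fast-spiking interneurons on a virtual ring,
  modelled with Wang–Buzsáki (WB) kinetics: the Na⁺ activation gate m is
  replaced by its steady state m∞(V) and the h/n kinetics are accelerated by
  the factor φ = 5, which yields the narrow spikes and high sustainable
  rates of the fast-spiking phenotype.  Channel densities are the WB
  values (g_Na = 35, g_K = 9, g_L = 0.1 mS/cm²; E_Na = 55, E_K = −90,
  E_L = −65 mV; C_m = 1 µF/cm²); the computed stable resting point is
  −64.0 mV.
* **P subnetwork** — 400 pyramidal cells on a 20 × 20 torus (the
  anatomically realistic 4:1 pyramidal-to-interneuron ratio), modelled as
  classical Hodgkin–Huxley point neurons with the standard rate functions
  shifted to rest near −65 mV, i.e. at the interneurons' resting potential.

The ring and the torus exist to remove edge effects from the
distance-dependent wiring: every cell sees the same neighbourhood
statistics.  Ring distance is min(|i−j|, n−|i−j|); torus distance is the
Euclidean metric after folding opposite edges onto each other.

## Synapses and gap junctions

All chemical synapses insert a bi-exponential conductance
g(t) = g_max·N·(e^(−t/τ_d) − e^(−t/τ_r)), with N normalizing the peak to 1
so that g_max is the unitary peak conductance.  GABA (τ_r = 0.16 ms,
τ_d = 1.8 ms), AMPA (0.5/2 ms) and NMDA (2/100 ms) share one code path and
differ only in parameters.  The NMDA conductance is deliberately a plain
fixed-kinetics bi-exponential: no voltage-dependent Mg²⁺ block is modelled,
matching the model description this package implements.  Events superpose
linearly, so all convergent input of one receptor kind on a cell is carried
by two exponential state variables.

The default GABA reversal is **shunting** (−55 mV, 10 mV above rest); the
robustness experiments compare it against a hyperpolarizing reversal
(−75 mV).  A shunting IPSP is depolarizing for a cell at rest yet still
stabilizes network firing through its conductance load.

Gap junctions couple each FS cell to its nearest ring neighbours (distance
≤ 2) with probability 0.75 — about 3 junctions per cell — with a constant
conductance of 0.05 mS/cm², an ohmic current g·(V_j − V_i) in each
direction.

**Synaptic latency.**  Recurrent chemical synapses act 0.5 ms after the
presynaptic threshold crossing.  With strictly zero latency a ring of
mutually inhibiting fast oscillators settles into antiphase clusters
instead of the experimentally grounded single-volley gamma rhythm; a
sub-millisecond latency (well inside physiological axonal plus synaptic
delays, and standard in the interneuron-ring modelling literature this
model descends from) restores the synchronous state.  Afferent fibre events
and gap junctions are not delayed.

## Connectivity

Within each subnetwork a cell receives a synapse from a neighbour at
distance d with probability p₀·exp(−d²/2σ²) (zero beyond d_max), where p₀
is scaled so the expected in-degree hits its target; the Gaussian governs
only whether a synapse exists, never its strength.  σ is not independently
constrained; the defaults (σ_FS = 30 cells, d_max = 50; σ_P = 5 cells,
d_max = 8) make the stated in-degree targets attainable with p₀ < 1.
Cross-subnetwork projections and fibre fan-ins sample uniformly at random.

Mean in-degrees — FS→FS 60, P→FS 63, P→P 100, FS→P 22, plus per-cell fibre
fan-ins of 50 constant + 50 theta (FS) and 150 constant + 25 theta (P) —
were chosen so the synapse-type census of the full network reproduces the
anatomical census the model is calibrated to (FS→FS 4.24%, P→FS 4.47%,
P→P 28.09%, FS→P 6.30%, ext→FS 7.09%, ext→P 49.80%).  The realized census
matches each entry within 0.3 percentage points averaged over 10 wiring
seeds.  The FS theta fan-in is twice the P theta fan-in, reflecting the
stronger hippocampal projection onto interneurons.

## Inputs

* **Heterogeneous DC drive** (FS-ring experiments): each cell draws a mean
  drive from N(I_µ, (cv_cells·I_µ)²) once, then redraws its amplitude every
  100 ms from N(cell mean, (cv_time·cell mean)²); cv_time is fixed at 0.05
  while I_µ and cv_cells are swept.
* **Poisson fibre pools**: two pools of 400 fibres each.  Spikes are
  Bernoulli-thinned per integration step (p = r·dt, at most one spike per
  window).  The constant pool fires at 10 Hz per fibre; the theta pool at
  r(t) = 10·(1 + a·sin 2πf_θt) Hz, clipped at zero, with default a = 1 and
  f_θ = 4 Hz (theta of the anaesthetized-rodent range).  All fibres are
  mutually independent; one global sinusoid drives the whole theta pool.
* **Theta reference**: the same raw sinusoid, with phase defined as the
  sine argument — theta peak at +π/2, trough at −π/2.

Unitary conductances were calibrated once against the single-cell
frequency/input curves and population targets: FS cells respond to summed
afferent rates of 0.5–1.5 kHz with a strong initial rise then a flattening
rate (tens of Hz), P cells are silent below ≈1 kHz and respond steeply
above — so identical relative theta modulation of the input moves P rates
proportionally far more than FS rates, reproducing the stronger theta
modulation of pyramidal spiking despite the FS cells receiving the stronger
theta projection.  Defaults: AMPA/NMDA on FS 1.8e-3/2.25e-5, on P
6.4e-3/1.36e-4; GABA on FS 0.1, on P 0.08 (mS/cm²).  The P afferents leave
unconnected pyramidal cells firing a ~1–2 Hz background; the FS→P
conductance is strong enough that the theta-varying FS barrage visibly
modulates the pyramidal membrane impedance (see below).

## Integration

Fixed-step exponential Euler at dt = 0.025 ms: the membrane relaxes each
step toward the instantaneous steady state of its total conductance load
(channels evaluated at current gate values; synaptic gates; gap junctions
using previous-step voltages), and each gate relaxes exponentially toward
its voltage-dependent target.  This is the NEURON-style update for HH
systems; a convergence test checks that halving dt moves single-cell spike
times by < 0.1 ms.  Spikes are upward crossings of 0 mV with a 1 ms
refractory, linearly interpolated within the step.  Isolated single-cell
integration (tests, f–I curves) uses classical RK4.

A run starts with all cells uncoupled under their afferent input (initial
voltages jittered ±5 mV); recurrent synapses and gap junctions are inserted
at t_connect = 100 ms, and analyses start at t_analysis = 300 ms so the
connected network has settled.  Runs are bitwise reproducible given the
seed; wiring, drive and fibre randomness use independent spawned streams.

## Simulated LFP

The LFP is the negative summed pyramidal membrane potential, recorded at
1 kHz and low-pass filtered at 100 Hz with a zero-phase FIR filter
(symmetric kernel, FFT convolution, transition band < 20% of the cutoff).
The sign flip maps the intracellular sum onto the extracellular sign
convention.  A control variant uses the summed synaptic transmembrane
currents of the P cells with identical filtering.

## Statistics

* **Network coherence κ**: mean zero-lag coherence over all unordered cell
  pairs of binary spike trains binned at 1 ms.  A pair with an empty train
  contributes 0 (the measure's 0/0 case, resolved to the uncoupled value).
* **Volley peak height H**: population spike histogram at 1 ms bins; peaks
  are discrete-derivative sign changes (plateau apexes attributed to their
  first bin) at or above a threshold — 20% of the FS population, 2.5% of
  the P population; H is the mean peak height, 0 if no peaks.
* **Theta modulation**: the population histogram is folded over complete
  theta periods.  r² is the squared Pearson correlation of the folded
  profile with the raw theta signal.  The modulation score M re-bins the
  profile into 10 coarse phase bins (removing gamma-rate structure) and
  reports (max − min)/(2·mean) — the relative amplitude of a theta
  oscillation in the activity; for a profile c·(1 + a·sin φ) it returns a
  up to the analytic re-binning attenuation sinc(1/10) ≈ 0.984.
* **Cross-frequency coupling**: the LFP is band-passed to 30–80 Hz
  (zero-phase FIR); its Hilbert amplitude is combined with the raw-theta
  phase into z(t) = A_γ(t)·e^(iφ_θ(t)).  Half a filter length is discarded
  at each end before statistics.  Coupling strength is |mean z|; the polar
  histogram uses 16 phase × 20 amplitude bins with a bin edge at phase 0;
  peak/trough amplitude sets come from π/4-wide windows *centred* on ±π/2.
  Gamma-distribution fits of amplitude samples use maximum likelihood
  (location fixed at 0).
* **Surrogates**: because the theta reference is a perfect sinusoid, a
  circular time shift of the amplitude series leaves the norm of any
  theta-locked component unchanged and is useless as a null.  Surrogates
  therefore permute 50 ms blocks of the amplitude series — long enough to
  preserve the gamma envelope's local autocorrelation, short enough
  (a fifth of a theta period) to scramble phase alignment.  Significance is
  declared above the surrogate 99th percentile.
* **Peak-frequency track**: short-time Fourier transform (Hann window,
  default 250 ms, 10 ms hop); per slice either the argmax frequency within
  the gamma band (the plotted track) or the power-weighted spectral
  centroid.  The experiment summaries correlate the centroid (150 ms
  window) with the theta reference: on short desk-scale segments the
  frequency-grid-quantized argmax cannot resolve the few-hertz theta-phasic
  shift that the centroid detects reliably.

## Mechanism notes

Gamma arises in the FS ring by mutual shunting inhibition (ING): with
homogeneous drive nearly every cell fires once per population volley.
Shunting reversal sustains coherence at drive heterogeneities where the
hyperpolarizing reversal has already collapsed, because the depolarizing
IPSP component pulls weakly driven cells toward threshold instead of
silencing them.  The FS rhythm is imposed on the P cells through the FS→P
shunt; pyramidal gamma amplitude falls when the FS barrage is strong
because the added conductance lowers the P membrane impedance — hence, with
theta-modulated FS input, gamma amplitude is highest near the theta
*trough* and lowest near the peak, while the gamma *frequency* follows the
FS drive and is highest near the peak.

## Scale profiles and what the tests show

The default experiment profile is a half-linear-scale network (50 FS cells,
12 × 12 P torus, in-degrees scaled accordingly, identical per-cell afferent
statistics), which reproduces every qualitative result of the full model at
desk-scale runtimes; the full profile differs only in size.  Simulated
durations per experiment: ring robustness 1.3 s per grid cell, gamma
imposition 2.3 s, cross-frequency analyses 4.3 s (16 theta periods).
The synthetic afferents emulate rate-modulated, mutually independent
hippocampal and cortical fibres; they do not model correlated input,
non-sinusoidal theta, or conduction-distance effects, so passing tests
support the network-level mechanism, not quantitative fidelity to any
in-vivo recording.

## Known limitations

* The NMDA conductance lacks Mg²⁺ voltage dependence by design.
* The LFP proxy ignores extracellular space and dendritic geometry; the
  current-based variant is provided as a control.
* The explicit (previous-step) gap-junction coupling is first-order
  accurate; at the default dt and conductances the dt-halving test bounds
  the error.
* Percentile-based surrogate significance uses 200 permutations; the p99
  estimate is itself noisy at that count.
* The significance procedure for gamma-fit parameter differences between
  peak and trough windows is a bootstrap comparison of fitted parameters;
  it is a pragmatic choice, not a published recipe.
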