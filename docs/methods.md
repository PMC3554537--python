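# Model and methods

`palisade` simulates the early post-traumatic reorganization of a cortical
sheet: deafferentation silences part of the network, homeostatic synaptic
plasticity (HSP) — the effective action of glial TNF-alpha signaling,
optionally confined to astrocytic microdomains — rescales synaptic
conductances to restore pyramidal firing, and the rescaled network generates
paroxysmal population bursts that the analysis layer detects and counts.

## Network

Neurons occupy a `side x side` square lattice (default 80x80 = 6400; the
desk-scale preset uses 40x40). Every 5th site in row-major order is an
inhibitory interneuron (IN, 20%); the rest are pyramidal cells (PY, 80%).
Connectivity is footprint-limited: a neuron may receive synapses only from
the `(2a) x (2a)` block of sites centered on it (default a = 5, a 10x10
block). An even-sided block cannot be centered on a site, so offsets
`[-a, a-1]` are used in each dimension; footprints are clipped at lattice
edges (no wrap-around — the model's boundary analyses are meaningless on a
torus). Each candidate pair connects independently with probability
`p_exc = 55/79` (PY presynaptic) or `p_inh = 12/20` (IN presynaptic). These
defaults are back-derived so an interior PY neuron receives on average 55
excitatory and 12 inhibitory synapses; incoming PY->PY synapses are capped at
75 per neuron by random pruning (the cap essentially never binds at default
probabilities). When the footprint is rescaled, connection probabilities are
renormalized by the ratio of interior candidate counts so the expected
in-degree is footprint-size invariant; a renormalized probability above 1 is
a configuration error.

## Neuron model

One-compartment Morris-Lecar dynamics in the class-I (SNIC-onset) regime,
with the canonical parameter set (C = 20 uF/cm^2, g_Na = 4, g_K = 8, g_L = 2
mS/cm^2, E_Na = 120, E_K = -84, E_L = -60 mV, V1 = -1.2, V2 = 18, V3 = 12,
V4 = 17.4 mV, phi = 1/15 ms^-1); the fast inward conductance is labeled
"sodium" with instantaneous activation. PY neurons carry a phenomenological
spike-frequency adaptation current `g_AHP z (V - E_K)` with `g_AHP = 0.5
mS/cm^2`; the gate `z` jumps by 0.05 per spike (clipped at 1) and decays with
`tau_z = 200 ms`. IN neurons share membrane parameters but have `g_AHP = 0`.
Spikes are upward crossings of 0 mV with a latch so one suprathreshold
excursion counts once.

Integration is fixed-step: forward Euler for V, exponential Euler for the
gating variables (which therefore remain in [0, 1] for any step size). The
reference single-neuron default is dt = 0.05 ms; network presets use dt =
0.1 ms, at which halving dt changes the 10-s network spike count by under 2%
(tested). The network kernel replaces the three gating transcendentals with
linear interpolation into 0.05-mV lookup tables; the interpolation error is
below 1e-6 and the kernel trajectory is tested against the reference stepper.

## Synapses

Conductances rise instantaneously at a presynaptic spike and decay
exponentially: AMPA tau = 5 ms, GABA tau = 10 ms. PY->PY synapses add an
NMDA component modeled as the difference of slow (100 ms) and fast (5 ms)
exponential traces, normalized so a single event's NMDA peak is
`nmda_ratio = 0.25` of the AMPA peak; no magnesium-block voltage dependence
is modeled. Excitatory transmission is attenuated by release depletion:
`D -> (1 - d) D` per presynaptic spike with `d = 0.5`, recovering as
`dD/dt = (1 - D)/tau_D`, `tau_D = 1000 ms`. `D` depends only on the
presynaptic train and is held per presynaptic neuron; GABA synapses have
D = 1 fixed. Initial peak conductances: PY->PY 0.25, IN->PY 0.25, PY->IN
0.09, IN->IN 0.25 mS/cm^2. Strong depression together with strong recurrent
excitation is what gives the post-traumatic network its discrete-burst
character: a population discharge depletes transmission and terminates, and
the next event must wait for recovery of D (hundreds of ms), so bursts arrive
at tenths of Hz rather than as continuous firing.

Every neuron also receives an afferent ("rest of the cortex") excitatory
conductance driven by an independent homogeneous Poisson process, 100 Hz when
intact, with tau = 5 ms and reversal 0 mV. The per-type peak conductances
(PY 2.17, IN 3.56 mS/cm^2) are the output of the calibration operation:
alternating bisection on the two conductances until the intact network fires
at PY 5 Hz and IN 10 Hz on a reduced lattice. Calibrated values are frozen in
the defaults; the 40x40 intact network reproduces the target rates within
the stated +/-1 / +/-2 Hz.

## Trauma

Deafferentation multiplies the afferent Poisson rate by 0.1 (100 -> 10 Hz)
for a fraction `f_d` of neurons (PY and IN alike), the "trauma volume".
Focal trauma deafferents the smallest left-anchored block of whole lattice
columns holding at least `ceil(f_d N)` neurons; diffuse trauma picks a
uniform random subset of exactly that size. A severed-connectivity control
removes every synapse whose endpoints differ in deafferentation status.

## Homeostatic plasticity and microdomains

Each synapse onto a PY neuron carries a scaling factor `s` (initially 1,
clipped to [0, 5]) multiplying its initial peak conductance. Glutamatergic
conductances follow

    ds/dt = kappa [ max(0, 1 - u/r_t) - max(0, v/r_t - 1) ]

and GABA conductances the same with opposite sign; `r_t = 5 Hz` is the PY
target rate. The rectified-linear form is our concrete reading of the
conditional up/down logic (upregulation only when the presynaptic
neighborhood is below target — the permissive, glia-driven arm; downregulation
only when the postsynaptic cell is above target): it is the simplest form
with one rate constant per arm and a fixed point exactly at the target.
The drives by scheme:

| scheme                 | u (up)                   | v (down)            |
|------------------------|--------------------------|---------------------|
| `local` (baseline)     | domain presynaptic mean  | postsynaptic rate   |
| `global`               | global PY mean           | global PY mean      |
| `global_up_local_down` | global PY mean           | postsynaptic rate   |
| `global_up_no_down`    | global PY mean           | (dropped)           |

The presynaptic mean weights each presynaptic PY partner equally, not per
synapse. Firing rates are exponential moving averages with `tau_rate = 1 s`,
unbiased for stationary trains; scaling factors are updated every 100 ms of
simulated time. `kappa = 0.1 s^-1` is deliberately accelerated relative to
biological scaling (hours) so the post-traumatic steady state is reached in
tens of simulated seconds; since the HSP timescale remains two orders above
the burst and membrane dynamics, this compresses the equilibration phase
without changing the steady state's character. Each PY neuron's incoming
synapses are exactly partitioned into M microdomains (random round-robin,
sizes differing by at most 1), or — in the segregated two-domain scheme —
split by the presynaptic neuron's deafferentation status. A domain with no
glutamatergic synapse senses no activity and is frozen. Only synapses onto
PY neurons are scaled.

## Burst detection and sampling

Time is partitioned into non-overlapping 100-ms bins. A bin is paroxysmal if
at least `f_min = 0.5` of the recorded neurons fired in it and those active
neurons averaged more than `r_min = 15 Hz`; consecutive paroxysmal bins merge
into one event so the burst rate does not scale with event duration. The
"average rate" is taken over the neurons active in the bin — this makes the
two-part criterion non-redundant. The thresholds are mandatory configuration
fields; the defaults were calibrated against the simulated rasters, where
asynchronous bins have ~0.3 of neurons active at a conditional mean near
12 Hz while paroxysmal bins have over half active at 15-20+ Hz, so the joint
criterion separates the two modes cleanly at desk scale. Recording subsets:
focal runs use 5 adjacent full rows across the lattice midline (perpendicular
to the trauma boundary, the axis along which discharges propagate, 400
neurons at full scale); diffuse runs use a centered 20x20 block. Spatial
profiles average PY rates over a 5-cell half-width mid-lattice strip;
cross-covariance uses correlation-coefficient normalization on binned counts
over sampled pairs.

## Run protocol and problem sizes

A run executes: build -> intact settle (2 s) -> deafferentation at t = 0 ->
HSP evolution until the network PY rate stays within 0.75 Hz of target for
two consecutive 10-s windows (or a configured maximum) -> a recorded
measurement window (>= 50 s) with HSP still active -> analysis. All
randomness derives from one run seed; identical configurations reproduce
identical outputs.

Default problem sizes: structural statistics run on the full 80x80 lattice;
dynamical experiments run on a 40x40 lattice with 50-s measurement windows
(the paper-scale 80x80 preset is available through the configuration); the
trend test-suite sweeps run on a 24x24 lattice with three replicate seeds per
condition, sizes chosen so the full suite completes on one desktop CPU core.
At 24x24 all qualitative orderings reported by the trend tests (burst-rate
flatness under the local scheme, the global scheme's higher trauma threshold,
monotone decrease with microdomain count, suppression by input segregation
and by boundary severing) match their 40x40 counterparts.

## What the generator does and does not emulate

All spike data are generated by the model itself; there is no external data.
The synthetic network captures footprint-limited random connectivity and the
80/20 cell-type mix, but not cortical layers, distance-dependent connection
profiles, conduction delays, or synaptic stochasticity (transmission is
deterministic by design). The trauma model reduces afferent drive only; it
does not model cell death, rewiring, extracellular potassium, or astrocyte
biochemistry — microdomains act purely through the scaling rule. Passing
tests therefore demonstrate the internal consistency of this mechanism and
the direction of its effects, not quantitative agreement with biological
burst rates.

## Numerical and design choices

- Eq. parameters not fixed by the model's published description (membrane
  constants, synaptic conductances, burst thresholds, kappa) live in one
  versioned parameter module; the calibration operation documents how the
  afferent drive was set.
- The resting state is located by scanning dV/dt on a 1-mV grid and root
  polishing; class-I Morris-Lecar has three fixed points and the lowest is
  the rest point.
- Depression uses the multiplicative per-spike update with exponential
  recovery; its periodic-drive fixed point has the closed form
  `D* = (1 - e^(-T/tau_D)) / (1 - (1-d) e^(-T/tau_D))`, which the tests
  verify by iteration.
- The engine aggregates per-synapse conductances into per-neuron sums per
  receptor class (exact for shared time constants) and holds D per
  presynaptic neuron (exact, since D depends only on the presynaptic train).
- Ties and degenerate inputs: empty microdomains are inactive; zero-variance
  trains are skipped in covariance with a log count; a network with no
  bursts reports NaN intra-burst statistics, flagged by `n_bursts = 0`.

## Known limitations

- The homeostatic loop at accelerated kappa can hunt around the target
  (relaxation oscillations of the population rate on the ~10-s scale) for
  some volumes; the steady-state detector plus a long measurement window
  averages over this.
- At desk scale the segregated and severed conditions suppress bursting
  completely rather than partially; at full 80x80 scale richer intermediate
  behavior is expected.
- Intra-burst firing intensity is tied to the homeostatic operating point,
  so burst-shape statistics are meaningful as orderings across conditions,
  not as absolute rates.
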