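# palisade

Simulation and analysis of paroxysmal activity in a deafferented cortical
network model with spatially localized homeostatic synaptic plasticity (HSP),
including its functional segregation into astrocytic microdomains.

After brain trauma, neurons that lose their long-range (afferent) input fall
silent, and homeostatic mechanisms — in part glial TNF-α signaling — scale
synaptic conductances up to restore firing. The same compensation that
restores mean rates can tip the network into epileptiform population bursts.
`palisade` is for computational neuroscientists who want to study this
trade-off: it simulates a 2D lattice of Morris–Lecar neurons under
deafferentation, applies one of four HSP schemes whose upregulating
(glia-like) arm can be confined to microdomains of each neuron's synaptic
input, and quantifies the resulting interictal-like discharges.

## Model

- **Network.** An `N = L×L` lattice (80×80 by default; 40×40 desk scale),
  80% pyramidal (PY) / 20% inhibitory (IN) neurons, with synapses drawn
  independently inside a neuron-centered 10×10 *synaptic footprint*; an
  interior PY receives on average 55 PY and 12 IN synapses (≤ 75 PY→PY).
- **Dynamics.** Class-I Morris–Lecar membranes
  (`C V̇ = −g_Na m∞(V)(V−E_Na) − g_K w (V−E_K) − g_L(V−E_L) − g_AHP z (V−E_K) − I_syn`)
  with spike-frequency adaptation on PY cells; AMPA, NMDA (dual-exponential)
  and GABA_A conductances; short-term depression `D → (1−d)D` per presynaptic
  spike; Poisson afferent drive at 100 Hz (intact).
- **Trauma.** A fraction `f_d` of neurons (the *trauma volume*) has its
  afferent rate cut to 10% — as a contiguous block (*focal*) or a random
  subset (*diffuse*).
- **HSP.** Per-synapse scaling factors on PY inputs follow
  `ṡ = κ [max(0, 1 − u/r_t) − max(0, v/r_t − 1)]` (opposite sign for GABA),
  where the upregulating drive `u` is the mean rate of the presynaptic PY
  partners in the synapse's microdomain and the downregulating drive `v` is
  the postsynaptic rate (`local` scheme; `global`, `global_up_local_down`
  and `global_up_no_down` variants replace these with the network mean).
  Microdomains partition each PY neuron's inputs randomly into `M` groups,
  or into two groups by presynaptic deafferentation status ("segregated",
  mimicking palisading astrocytes at the trauma boundary).
- **Analysis.** Paroxysmal bursts are 100-ms bins in which ≥ 50% of recorded
  neurons fire at an average above threshold (consecutive bins merge);
  plus intra-burst statistics, cross-covariance, spatial rate profiles,
  boundary-neuron sets and a severed-connectivity control.

See `docs/methods.md` for parameter values and numerical details.

## Worked example

```python
from palisade.config import FullConfig
from palisade.run import run_simulation, set_path

cfg = FullConfig()                                   # all defaults embedded
for k, v in {"network.side_length": 40, "sim.dt_ms": 0.1,
             "trauma.pattern": "focal", "trauma.f_d": 0.5,
             "hsp.scheme": "local", "run.measure_ms": 50_000.0,
             "run.seed": 42}.items():
    cfg = set_path(cfg, k, v)

rec = run_simulation(cfg)
m = rec.metrics
print(f"burst rate      {m['burst_rate_hz']:.2f} Hz  (n={m['n_bursts']})")
print(f"PY rate         {m['py_rate_hz']:.2f} Hz")
print(f"scaling factor  from deafferented {m['s_mean_from_deaff']:.2f}, "
      f"from intact {m['s_mean_from_intact']:.2f}")
```

Output (one 40×40 focal run, half the network deafferented, local HSP):

```
burst rate      0.32 Hz  (n=16)
PY rate         4.59 Hz
scaling factor  from deafferented 3.30, from intact 1.03
```

Half the network was deafferented at t = 0; HSP drove the network-mean PY
rate back to the 5-Hz target (4.59 Hz measured over 50 s), multiplied the
conductances of synapses *from* deafferented neurons by ≈ 3.3 while leaving
those from intact neurons near 1, and the rescaled network produced
interictal-like bursts every ~3 s. With the two-domain segregated scheme the
same protocol yields a much lower burst rate — the package's central effect.

The same protocols are scriptable from the shell:

```bash
palisade run --seed 42 --out out/run42
palisade sweep --axis hsp.M=1,5,25 --replicates 3 --out out/msweep
```

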