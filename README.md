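# scnsim

A multiscale model of a single pacemaker neuron of the suprachiasmatic
nucleus (SCN), the hypothalamic master circadian clock. The package is for
computational chronobiologists and neurophysiologists who want to simulate,
perturb and analyze the coupling between circadian gene expression,
intracellular calcium, membrane electrophysiology and neuropeptide
signaling in one cell, on the circadian (hours) timescale.

## The model

Four coupled layers form a deterministic 20-ODE system:

1. **Core clock** — the 16-state Per/Cry/Bmal1 gene regulatory network
   (interlocked negative and positive transcriptional feedback loops,
   without the Rev-Erb branch). The Per transcription rate is dynamic:

   `v_sP(t) = v_sP0 + C_T * CB / (K_c + CB)`

   where CB is phosphorylated CREB, closing the loop from electrical
   activity back onto gene expression.

2. **Calcium** — a two-pool model: cytosolic Ca²⁺ exchanges with a
   ryanodine-sensitive store (Hill pump `v2`, calcium-induced calcium
   release `v3`, leak `k_f`), a constant IP₃-store release, and
   clock-gated membrane fluxes (influx saturating in cytosolic BMAL1,
   efflux rate in cytosolic CRY).

3. **Electrophysiology** — an algebraic (quasi-static) layer evaluated at
   every time point: phenomenological circadian conductances
   (`g_K`, `g_Ca`, `g_KCa`, AMPA/NMDA `g_ex`, GABA_A), Nernst reversal
   potentials, a divalent-corrected Goldman–Hodgkin–Katz resting
   potential (solved implicitly), membrane resistance, and the leaky
   integrate-and-fire firing-rate code

   `f_r = 1 / ( tau_m * ln[(R*I* − V_reset)/(R*I* − theta)] )`,
   `f_r = 0` when `R*I* <= theta`,

   with `I* = Σ g_r E_r + I_app`, `R* = 1/Σ g_r`, `tau_m = C_m R*`.

4. **Signaling** — VIP released as a saturating function of firing rate
   (autocrine), GABA released as a function of VIP, and a Ca²⁺/VIP-driven
   kinase that phosphorylates CREB.

The model free-runs at ≈23.4 h in constant darkness and reproduces the
canonical phase map of SCN rhythms relative to the cytosolic calcium peak
(defined as circadian time CT 1.5): Per mRNA and firing peak in the
subjective day, the BK current and inhibitory drive at night.

Built-in perturbation experiments: IP₃-store and ryanodine-store
blockade, nimodipine (L-type channel block), graded GABA reduction or
application, VIP blockade or constitutive application, scaling of the
effective cytosolic calcium, constant current injection, and a
hyperpolarizing voltage clamp.

## Worked example

```python
from scnsim import SimulationConfig, simulate
from scnsim.experiments import trajectory_metrics

traj = simulate(SimulationConfig(duration_h=600.0, transient_h=300.0))
metrics = trajectory_metrics(traj, ("M_P", "Ca", "f_r", "I_KCa"))
for name, m in metrics.items():
    print(f"{name:6s} period {m.period_h:6.2f} h  peak CT {m.peak_CT:5.2f}  "
          f"peak {m.peak:8.3f}  trough {m.trough:8.3f}")
```

prints

```
M_P    period  23.41 h  peak CT  8.52  peak    4.124  trough    0.010
Ca     period  23.41 h  peak CT  1.50  peak    0.193  trough    0.121
f_r    period  23.41 h  peak CT  8.72  peak    9.885  trough    6.225
I_KCa  period  23.41 h  peak CT 21.90  peak  139.902  trough   68.258
```

i.e. a 23.4-h free-running rhythm in which Per mRNA (nM) peaks at CT 8.5,
cytosolic calcium (µM) anchors CT 1.5 with a ~1.6-fold day/night
contrast, the firing rate (Hz) peaks in the subjective day, and the BK
current (pA) peaks at night.

The same run from a shell, plus a perturbation:

```bash
scnsim simulate --perturbation nimodipine --out out/nimodipine
scnsim suite --perturbation vip_block --perturbation ca_scale:1.5 --out out/suite
```

Each run writes a trajectory CSV (time, the 20 state variables, all
membrane snapshot quantities), a metrics JSON and a run log with every
resolved parameter. Perturbed runs report percent changes of peak,
trough and amplitude against the control.

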