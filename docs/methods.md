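# Methods

## Scope and assumptions

`scnsim` models one SCN pacemaker neuron in constant darkness on the
circadian timescale. Three assumptions shape the whole design:

* **Quasi-static membrane.** Spike generation (milliseconds) is far faster
  than circadian state changes (hours), so the electrophysiology layer is
  purely algebraic: at each instant, conductances, reversal potentials, the
  resting potential and the firing rate are functions of the slow state.
  Channel activation/inactivation gating is not modelled.
* **Autocrine signaling.** The cell is alone: the VIP and GABA
  concentrations acting on its membrane equal the concentrations it
  releases. Network synchronization is out of scope.
* **Determinism.** The model has no stochastic terms; trajectories are
  bitwise repeatable at fixed solver settings. The only randomness in the
  package is the optional noise of the synthetic test-oscillation
  generator, which is seed-controlled.

## State and units

The 20 state variables, in canonical order: cytosolic calcium `Ca` and
store calcium `Ca_store` (µM); the 16 gene-network species (three mRNAs
`M_P`, `M_C`, `M_B` and thirteen protein/complex species, nM);
phosphorylated CREB `CB` and `VIP` (nM). Time is in hours for all ODEs.
The electrophysiology layer uses nS (conductance), mV (potential),
pA (current), GΩ (resistance) and nF (capacitance), so the membrane time
constant `tau_m = R* C_m` is in seconds and firing rates in Hz.

## The four layers

**Core clock.** The standard interlocked-loop mammalian circadian gene
network: nuclear BMAL1 activates Per and Cry transcription (Hill
coefficient 4), the cytosolic PER/CRY complex shuttles into the nucleus
(import rate `k_1 = 0.45 /h`) and sequesters nuclear BMAL1 into an
inactive complex; BMAL1 represses its own transcription (Hill
coefficient 2). Per-transcription activation threshold `K_AP = 0.6 nM`.
The Rev-Erb branch is omitted; it is not needed for sustained
oscillation. All other rate constants are the classical nominal values;
the stand-alone network then free-runs at ≈23.8 h. The Per transcription
rate is not constant but `v_sP = v_sP0 + C_T·CB/(K_c + CB)` with
`v_sP0 = 1 nM/h`, `C_T = 1.6 nM/h`, `K_c = 0.15 nM` — the single point
where signaling feeds back onto the clock. The network is self-sustained:
with the drive frozen at its mean the oscillation persists; its
low-drive oscillation threshold sits near `v_sP ≈ 0.95 nM/h`.

**Calcium.** Two-pool dynamics

```
dCa/dt       = v_o(B_C) + v_1·β − v_2(Ca) + v_3(Ca, Ca_store)
               + k_f·Ca_store − k(C_C)·Ca^v
dCa_store/dt = v_2 − v_3 − k_f·Ca_store
```

with Hill store uptake `v_2` (Vmax 149.5 µM/h, K 5 µM, exponent 2.2) and
calcium-induced calcium release `v_3` gated by store filling (K 3 µM,
exponent 6) and cytosolic activation (K 0.67 µM, exponent 4.2). The
IP₃-store release `v_1·β = 1.5e-4 µM/h` is constant and negligible by
construction (its blockade is a null experiment). Membrane influx
saturates in cytosolic BMAL1 (`v_vo = 0.09 µM/h`, lumped K 4.5 nM^4.5,
exponent 4.5) and the efflux rate coefficient in cytosolic CRY
(`v_kk = 3.3 /(µM·h)`, exponent 0.1); the efflux term is `k·Ca²` — the
quadratic exponent is the unit-consistent reading of the efflux
coefficient's µM⁻¹h⁻¹ dimension, and puts quasi-steady calcium at
0.12–0.19 µM, matching the nominal initial condition scale. On the
control attractor calcium peaks once per cycle in the subjective day
(the CT 1.5 anchor) with a realized day/night contrast of ≈1.6×.
`ca_scale` multiplies the calcium value passed to downstream consumers
(calcium reversal potential, NMDA conductance, kinase) and deliberately
does not touch the internal store dynamics, mimicking manipulation of
the effective free-calcium signal.

**Electrophysiology.** Seven conductances enter the
leaky-integrate-and-fire reduction: constant `g_Na = 36 nS`;
`g_K(M_P) = 9.7 + 10·M_P/(10 + M_P) nS` (day peak);
`g_Ca(M_P)` Hill with exponent 2.2 (day peak, the L-type target of
nimodipine); `g_KCa(C_C) = 3/(1 + 0.16·C_C) nS` (night peak — the BK
conductance rises as CRY falls); AMPA + NMDA excitatory conductance,
where the AMPA branch saturates in |I_Na| (in nA — the only
non-degenerate unit reading of its saturation constant 574.05) and the
NMDA branch falls with calcium (negative cooperativity −1);
`g_GABA = 12.3 nS`; and leak `g_L = 1/R`. Reversal potentials measured
at room temperature (E_K −97, E_Na 45, E_L −29 mV) are rescaled to 37 °C
by the absolute-temperature ratio (×1.0508). E_GABA is the chloride
Nernst potential of the GABA-gated chloride balance
(`Cl_in` 10–18 mM, day peak), realized at −65…−48 mV: inhibitory, and
weakest (least negative) when GABA is absent, which is what makes GABA
removal disinhibitory. E_Ca uses the table value `Ca_ex = 5 µM`
(the text's 5 mM variant would put E_Ca near +139 mV, far outside the
physiological 50–70 mV band this quantity is calibrated to).

The resting potential solves the divalent-corrected GHK flux balance

```
P_K(K_i − K_o e⁻ᵘ) + P_Na(Na_i − Na_o e⁻ᵘ) + P_Cl(Cl_o − Cl_i e⁻ᵘ)
  + 4 P_Ca (Ca_i − Ca_o e⁻²ᵘ)/(1 + e⁻ᵘ) = 0 ,   u = VF/RT
```

by bracketed root finding on [−150, 50] mV; with P_Ca → 0 this reduces
exactly to the monovalent GHK equation, and with a single ion to the
Nernst potential. Internal K⁺ and Na⁺ are fixed by Nernst inversion at
the nominal reversal potentials. The potassium permeability
`P_K = 1.9/(1 + B_C²)` peaks at night, producing V_rest ∈ [−51, −41] mV
peaking in the subjective day. Membrane resistance follows
`R = V_R·K_R/(|V_rest| − K_R)` (V_R 0.41 GΩ, K_R 34 mV), the saturating
form that yields R ≈ 0.8–2 GΩ peaking with V_rest; its denominator is
floored at 2 mV so transient depolarizations saturate instead of
diverging.

Firing threshold and reset sit 20 and 4 mV above the cell's reference
resting level, for which the (temperature-corrected) passive resting
potential E_L = −30.5 mV is used. Anchoring them to this fixed operating
point — rather than to the instantaneous GHK value — is a deliberate
design choice: a threshold riding the oscillating V_rest makes the
spiking margin inherit the inverted V_rest rhythm and the firing rate
peak at night, contradicting the day-peaked firing of SCN neurons. With
the fixed anchor the day-peaked L-type conductance dominates the drive
`R*I*`, the firing rate peaks in the subjective day (CT ≈ 8.7), and
L-type blockade collapses the day peak while sparing the night trough —
the nimodipine phenotype. Sub-threshold drive returns `f_r = 0`
(a silent neuron, never an exception), and VIP release then sees zero
drive.

**Signaling.** VIP: production `0.5·f^1.9/(15 + f^1.9) nM/h`, depletion
`0.5·VIP^0.2 /h`. Kinase rate `v_k = 5·Ca/(2.9 + Ca) + 2·VIP/(2 + VIP)`
nM/h (calcium in µM, VIP in nM; the VIP saturation constant is treated
as 2 nM). CREB is a Michaelian phospho/dephospho cycle over a conserved
total:

```
dCB/dt = v_k·(CB_T − CB)/(K_D + CB_T − CB) − V_dCB·CB/(K_D + CB)
```

with `K_D = 0.08 nM` from the parameter table and two constants the
sources do not pin down, fixed here by calibration (below):
`CB_T = 0.12 nM` (the scale of the nominal initial phospho-CREB) and
`V_dCB = 0.6 nM/h`. VIP blockade zeroes VIP only where it enters GABA
release and kinase activation, leaving the VIP ODE running; VIP
application adds +1 nM at exactly those two entry points.

## Calibration

Most parameters are table values taken as printed. Three constants are
genuinely free in this realization and were calibrated against the
model's *control-run* targets only — the free-running period near
23.6 h, firing within the physiological 2–9 Hz band and peaking in the
subjective day, phospho-CREB at the nominal 0.1 nM scale, and sustained
(non-runaway) oscillation under saturated VIP drive:

* `C_m = 8 nF`. The capacitance is explicitly a tuned quantity for
  centering the firing band; the table's 5 nF leaves firing at 20–30 Hz
  in this realization, which saturates VIP release and expels the clock
  from the circadian regime.
* `CB_T = 0.12 nM`, `V_dCB = 0.6 nM/h`. Larger CREB pools let
  constitutive VIP push Per transcription past the gene network's
  high-drive oscillatory boundary (`v_sP ≳ 1.7 nM/h`), where the clock
  degenerates to a fast (~17 h) high-Per relaxation cycle.

No constant was adjusted against perturbation outcomes; the perturbation
catalog is pure prediction of the calibrated model.

## Numerics

* Integrator: `scipy.integrate.solve_ivp` with the adaptive explicit
  low-order RK23 pair, `rtol = 1e-6`, `atol = 1e-9`. Output is sampled
  on a fixed 10-minute report grid regardless of internal steps, which
  keeps the quasi-static membrane assumption explicit; halving the grid
  moves the estimated control period by < 0.05 h.
* Default horizon 60 days with the first 10 discarded before metric
  computation; the attractor is reached well within the discard window
  (the slow store leak, τ ≈ 1000 h, does not produce secular drift —
  store exchange equilibrates through the much faster pump/release
  terms).
* The state is clipped at zero inside the right-hand side to absorb
  integrator undershoot; `CB` is clipped to its conserved total.
* Degenerate inputs: the GHK solver rejects all-zero permeabilities;
  reciprocal-power laws (NMDA, E_Ca) floor calcium at 1e-9 µM; the
  firing-rate logarithm returns 0 for any sub-threshold or numerically
  degenerate argument; the GABA-gated chloride term takes its analytic
  limit `v_Cl2` at GABA = 0.
* Non-negative-state and positivity validation happens at the module
  boundaries (each layer rejects negative concentrations).

## Rhythm metrics

Peaks are detected with `scipy.signal.find_peaks` (minimum separation
6 h, prominence 10 % of the range) and refined with three-point
parabolic interpolation, so peak times resolve below the 10-minute grid.
Period is the mean peak-to-peak interval (≥ 5 cycles recommended);
phase is reported in circadian time anchored to the calcium peak:
`CT = (1.5 + 24·Δt/period) mod 24`, averaged circularly over cycles.
Peak and trough are means of per-cycle extrema; amplitude is half the
peak-to-trough range; a series is arrhythmic when its amplitude falls
below 1 % of its mean (configurable), or when fewer than two peaks
exist. Percent changes are signed, relative to the control run. For
currents, phases are computed on |I| (inward currents are negative);
extrema are reported signed.

The synthetic-oscillation generator (cosine with optional seeded white
noise) is the independent oracle for these metrics: period, phase offset
and amplitude recovery are tested against generator parameters. It
emulates only stationary single-component rhythms — no damping, drift,
waveform asymmetry or colored noise — so metric tests certify the
estimator on clean oscillations, not its robustness to messy
experimental recordings.

## Perturbation semantics

All perturbations are constitutive (applied for the whole run, resolved
at simulation start): `ip3_block` (v₁ := 0), `ryanodine_block`
(v₃ := 0), `nimodipine` (g_Ca := 0), `gaba_reduce(p%)` / `gaba_add(nM)`
(scale/offset on released GABA before the chloride equation),
`vip_block` / `vip_add(1 nM)` (at the two VIP entry points),
`ca_scale(0.5–1.5)`, `current_inject` (additive term in I*), and
`voltage_clamp` (firing drive frozen at zero and calcium held at its
initial value; the reported firing rate is zero). Under the clamp the
calcium, firing, VIP and CREB rhythms are abolished; the gene network
itself, being self-sustained and still above its oscillatory threshold
at the clamped drive, retains a low-amplitude Per rhythm.

## Known limitations

* The VIP→CREB→Per gain chain is weaker than in the original
  implementation this model family derives from: perturbation percent
  changes (ryanodine, nimodipine, GABA and VIP experiments) have the
  correct signs and ordering but smaller magnitudes, and the
  calcium-scaling period response (+0.33 h at 1.5×, monotone) is
  shallower than the reported maximum.
* The realized firing band (≈6–10 Hz) spans the upper part of the
  physiological 2–9 Hz range; its relative day/night swing is smaller
  than observed, which in turn compresses trough-referenced percent
  changes.
* The day/night calcium contrast is ≈1.6× against the ~2× experimental
  figure.
* No ryanodine→BK-current route exists: the BK conductance follows CRY,
  not calcium, so store blockade barely moves the firing peak.
* Single cell only: no network coupling, no light input or entrainment,
  no stochastic gene expression, no excitatory GABA responses.
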