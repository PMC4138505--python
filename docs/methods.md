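# Methods

## The model

`purksim` simulates a reduced-morphology cerebellar Purkinje neuron: one
cylindrical soma (22 × 22 μm) plus 40 dendritic compartments, 20 "smooth"
(proximal-type, climbing-fiber targets) and 20 "spiny" (distal-type,
parallel-fiber targets).  The reduction does not conserve membrane area, so
dendritic capacitance is scaled by a correction factor C_d = 3.80
(smooth C_m = 0.8·C_d, spiny C_m = 1.5·C_d μF/cm²); the dendritic maximal
conductances in the shipped table already include the same factor.

Membrane currents:

* **Soma** — fast/mid/slow TEA-class K⁺ currents (m³h, m⁴, m⁴), a BK-type
  Ca²⁺-and-voltage-gated K⁺ current (m³z²h), a P-type Ca²⁺ current carried
  by a GHK flux at fixed concentrations ([Ca]ᵢ = 100 nM, [Ca]ₒ = 2 mM,
  295 K), a hyperpolarization-activated cation current I_h, leak, an
  electrogenic 3:2 Na⁺/K⁺ pump, and a 13-state Markov resurgent Na⁺
  current (closed chain C1–C5, open state O, open-blocked state OB,
  inactivated chain I1–I6).  Gate steady states printed as `1/exp(x)` are
  read as Boltzmann sigmoids `1/(1+exp(x))`, the only bounded reading; the
  somatic time constants are native seconds, converted to ms.
* **Dendrites** (identical densities in both zones) — T-, E- and P-type
  Ca²⁺ currents with E_Ca fixed at +135 mV, A-, M-, D-type and
  delayed-rectifier K⁺ currents, BK and K2 Ca²⁺-gated K⁺ currents
  (m·z²), I_h, leak, and — in the smooth zone only — an SK-type Ca²⁺-gated
  K⁺ conductance whose maximal value is switched by climbing-fiber input
  (see below).  Rates are α/β pairs in 1/ms with the temperature factor
  mt = 3^((T−37)/10), T = 36 °C.  Channel-specific printed update factors
  (E-type m ×4, h ×10; D-type m ×10, h ×k with k = 0.1) enter the
  exponential-Euler exponent as `rate_scale`.

The slow D-type inactivation (k = 0.1) is the nominal clamp on dendritic
excitability; the Na⁺/K⁺ pump with its lagged Na⁺ accumulation generates
the quiescent mode (below).

## Intracellular ion systems

Three Ca²⁺ shell systems (depth 0.1 μm):

* soma: d[Ca]/dt = −10⁴·I_Ca/(2F·depth) − β[Ca], β = 1/ms, floored at
  100 nM;
* spiny: d[Ca]/dt = chan − kt·[Ca]/([Ca]+kd) + (y−[Ca])/τ_r with
  kt = kd = 4·10⁻⁵, τ_r = 2 ms, fixed set point y = 4·10⁻⁵ mM, and chan
  clamped at ≥ 0 (outward Ca²⁺ current cannot deplete the shell);
* smooth: same structure (kt = kd = 10⁻⁴) but with a *floating* set point
  y that accumulates Ca²⁺ influx — dy/dt = |I_Ca|·u/(4·g·d·F) + (z−y)/τ_m,
  anchored at z = 2.4·10⁻⁴ mM.  The printed grouping of the influx term
  does not pin its units; the factor u = `y_influx_scale` (default 10⁵) is
  this package's calibrated reading, chosen once so that the set point
  creeps on the seconds scale during firing without destabilising the fast
  Ca²⁺ spiking, and it is a configuration field, not code.

Two per-compartment trigger switches implement the climbing-fiber gating:
**w** is set to 1 whenever the inward Ca²⁺ current magnitude exceeds
0.06 mA/cm² and decays with f = 100 ms; while w > 0.1 the set-point pair
(g, τ_m) switches from (10⁵, 100 ms) to (10⁴, 1000 ms), i.e. ten-fold
faster accumulation with ten-fold slower relaxation.  **r** is set to 1
whenever the compartment's CF synaptic current exceeds 3 nA and decays
with s = 1000 ms; while r > 0.1 the smooth-dendrite SK maximal conductance
takes the protocol value (0.62–0.88 S/cm²), otherwise 10⁻⁷ S/cm².  Both
switches are evaluated per compartment on instantaneous values.

Somatic Na⁺: i_pump = d_pump/(1+exp(40−[Na]ᵢ)) with d_pump = 0.04 mA/cm²;
the Na⁺ branch is 3·i_pump and the K⁺ branch −2·i_pump, so one net charge
leaves per cycle.  [Na⁺]ᵢ integrates the *lagged* (τ = 5 s FIFO at the
integration step) sum of resurgent-channel influx and pump efflux with
the cylinder factor 4·10⁴/(d·F) (mM/ms from mA/cm², d in μm), floored at
10 mM; E_Na is floored at +70 mV.  The delay buffer is warm-started with
the initial net current to avoid a spurious 5 s transient.  Longitudinal
Na⁺ diffusion ships as a config toggle, default off.

## Synapses

Both synapse types are peak-normalised dual exponentials (τ₁ = 0.5 ms,
τ₂ = 1.2 ms, reversal 0 mV), advanced by exact two-state exponential decay
with event impulses snapped to the integration grid.  CF input makes 17
synchronous 1 μS contacts on the 17 most proximal smooth compartments at
1 Hz; PF input makes one 0.0005 μS homogeneous-Poisson contact per spiny
compartment (default mean 100 Hz), one independent seeded stream per
synapse derived from a master seed.

## Integration

25 μs steps.  Per step: (1) synaptic conductances; (2) exponential-Euler
gate updates at the frozen voltage; (3) exact matrix-exponential
propagation of the Markov occupancies at the frozen voltage (a
scaling-and-squaring Padé exponential — unconditionally stable like an
implicit solve and, unlike any first-order step, accurate at the scheme's
stiffest rates of ~150/ms); (4) a backward-Euler tridiagonal solve of the
cable with all ohmic currents conductance-linearised at the new gate
values and the GHK, pump currents entering explicitly; (5) explicit
updates of the Ca²⁺ shells, floating set points, w/r switches and the
lagged pump/Na⁺ state from the new currents.  The default run settles 2 s
before the protocol window; traces are sampled at 1 ms with somatic spikes
(upward −20 mV crossings, 2 ms refractory, peak-aligned) and dendritic
Ca²⁺ spikes (≥ 3 ms sustained above −30 mV on the mid smooth compartment,
rejecting brief Na⁺-spike invasion) recorded at full rate.

A step-halving check (dt vs dt/2 over 1 s of the full model) and a
dense-vs-tridiagonal solver comparison are part of the test suite.

## Geometry and topology calibration

The published description fixes compartment counts, the soma cylinder,
R_a = 35.4 Ω·cm and the C_d scaling, but not the dendritic segment
dimensions — they are the model's calibration surface and live in
configuration.  Two structural choices were made here:

* **Split topology (default).**  The cable is an unbranched path with the
  soma interior: the smooth equivalent cable on one side, the spiny on the
  other (`geometry.topology = "split"`; the single chain
  soma → smooth → spiny remains available as `"chain"`).  The three
  headline behaviours impose incompatible electrotonic demands on a single
  chain: ~99 Hz tonic pacemaking needs a substantial dendritic load; that
  load cannot sit in the SK-bearing smooth zone, because with 0.62–0.72
  S/cm² of CF-gated SK any appreciable smooth-zone Ca²⁺ baseline silences
  the cell outright; and PF input must reach the soma without being
  filtered by the thin smooth cable.  Splitting the equivalent dendrites
  across the soma separates the three constraints.
* **Shipped dimensions.**  Smooth 12 × 0.32 μm, spiny 6 × 1.78 μm.  The
  thin smooth cable keeps CF-evoked Ca²⁺ spikes regenerative and the SK
  baseline benign; the thick spiny cable supplies the load that sets the
  ~99 Hz tonic rate and the substrate for PF amplification.

## What the simulated protocols do and do not show

At the shipped defaults the model reproduces, with no synaptic input, a
repeating firing/quiescence cycle of ~21 s (tonic ~88–100 Hz, quiescence
~8–10 s) driven by lagged Na⁺ accumulation and electrogenic pumping; PF
input raises the tonic rate to ~150 Hz; CF input at 1 Hz with
g_sk = 0.62 S/cm² lowers it to ~50 Hz with a complex spike and an
after-pause (~45 ms) at every CF event; and under CF input the quiescent
mode persists as long (~8–10 s) silences punctuated by CF-driven complex
spikes that fail to restart firing.

Known limitations, all consequences of the printed channel set interacting
with the calibration trade-offs above:

* **Intrinsic bursting is attenuated.**  The dendritic membrane is not
  self-oscillatory at any D-type inactivation level (verified on isolated
  compartments), so dendritic Ca²⁺ spikes require strong soma–dendrite
  coupling — which drags the tonic rate far below 99 Hz through a
  per-spike CaP → shell-Ca → BK feedback.  The shipped calibration favours
  the quantitative rate and cycle targets; intrinsic Ca²⁺ spikes do not
  regenerate, the trimodal sequence reduces to tonic → quiescent, and the
  k-parameter's control of the tonic length is not expressed.
* **One-second CF toggling is not reproduced.**  Persistent ~1 s up/down
  states require either intrinsic bistability (the Markov Na⁺ scheme's
  resting persistent current destabilises every rest state found across
  geometry and g_ih sweeps; rest is only stable with the pump engaged,
  whose 5 s lag forces ~10–20 s cycles — the pump silences) or a Ca²⁺
  memory outlasting the CF period (the switch lifetimes f·ln10 ≈ 230 ms
  and the τ_m reversion cap that memory at ~0.5 s).  The toggle protocol
  therefore yields CF-punctuated firing with pump silences rather than
  1 Hz alternation, and the I_h-mask/SK-rescue ordering of toggling is
  correspondingly not expressed.
* **PF and CF effects combine additively.**  The CF+PF tonic rate
  (~120 Hz) overshoots the published ~80 Hz because nothing in this
  calibration compresses the PF increment while SK is engaged.

The synthetic protocols emulate deafferented-slice conditions (no basket
or stellate inhibition, no plasticity); passing tests demonstrate internal
consistency of the implementation and the calibrated behaviours above, not
fidelity to any particular biological recording.

## Problem sizes

Default test and acceptance runs use 65 s of simulated time for the
intrinsic pattern (two full repeats), 12–15 s per synaptic condition with
three Poisson seeds where PF input is involved, and 45 s for the
toggle-protocol statistics; at 25 μs steps these complete in minutes on
one CPU via the compiled kernel.
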