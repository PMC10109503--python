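# Methods

## Scope and model structure

The package simulates a single deep dorsal-horn wide-dynamic-range (WDR)
projection neuron receiving direct input from one Aδ-fiber and one
C-fiber, each fanned out over 20 synapses with per-synapse conduction
delays (no interneuron, no network). A windup protocol delivers 15
electrical stimulations 1 s apart starting at 1 s; each stimulation
produces one presynaptic event per fiber. Every C-fiber synapse carries
a postsynaptic ASIC1a population gated by the pH of its own synaptic
cleft, which acidifies at each presynaptic activation.

Three subsystems are co-simulated at a fixed step (0.025 ms by
default): the three-compartment neuron, the aggregated synaptic
conductance kernels, and the 20 cleft/ASIC units (cleft ODE sub-stepped
at ≤ 0.005 ms). Gating variables use exact-exponential (exponential
Euler) updates; compartment voltages use exponential Euler with
external synaptic currents held constant over a step.

## ASIC1a gating

Two parameter sets reproduce the two classes of native ASIC current
recorded in deep spinal laminae ("type 1" → homomeric ASIC1a, "type 2"
→ ASIC1a/ASIC2 heteromer):

| variant | n_m | pH½,m | n_h | pH½,h | α |
|---|---|---|---|---|---|
| homomeric | 1.5 | 6.46 | 4.6 | 7.3 | 1.3 |
| heteromeric | 1.94 | 6.03 | 3.82 | 6.74 | 1.0 |

`m∞ = 1/(1+10^{n_m(pH−pH½,m)})`, `h∞ = α/(1+10^{−n_h(pH−pH½,h)})`,
`I = g·m·h·(V−E)` with E = +50 mV and a 10% calcium fraction.
Activation is instantaneous (its time constant is orders of magnitude
below the seconds-scale windup dynamics); inactivation relaxes with
`τ_h(pH)`: homomeric `49.196·e^{−34.632(pH−7.144)²} + 0.95·pH − 3.77` s
(biased Gaussian plus affine part), heteromeric
`42.862·e^{−5.375|pH−6.6|} + 1.645` s. Alternative `τ_h` forms (affine
and piecewise-affine fits) are available as configuration. `τ_h` fits
are validated on pH ∈ [4, 9]; outside that range a 1 ms positivity
floor applies if range checking is disabled. The `mittx` mode locks the
open fraction `m·h` at 1 independently of pH, emulating the
constitutively activating coral-snake toxin. No resting pH shift is
applied anywhere.

## Synaptic cleft acidification

The conserved variable is the buffered total proton concentration
`H_T = H(1 + B₀/(H+K_d))` with
`dH_T/dt = q(t) − (H − H₀)/τ`, `B₀ = 22 mM`, `K_d = 10^{−6.3} M`,
`H₀ = 10^{−7.4} M`, `q = 0.3 mM/ms` for 1 ms per presynaptic
activation (membrane crossing −30 mV), `τ = 0.1 ms`. Internally
concentrations are in mM and time in ms; pH = −log₁₀(H in M). The free
concentration is recovered from `H_T` by a cancellation-safe quadratic
formula (the naive root loses all precision because `K_d + B₀ − H_T` is
ten orders of magnitude larger than the root). Although τ is 0.1 ms,
it acts on the tiny free-proton deviation; the effective recovery time
constant of the total pool is `τ(1 + B₀/K_d) ≈ 4 s`, so 1 Hz pulsing
accumulates to a quasi-steady acid shift of ≈ 0.22 pH units with the
default parameters. Each C synapse owns its cleft (the per-synapse
trigger and ASIC population make this the natural granularity); a
single shared cleft is available as a configuration flag. Explicit
sub-stepping at 0.005 ms is accurate to < 1e−4 pH units against a
100-fold finer reference because the stiff rate multiplies a small
deviation; the test suite checks this directly.

Alternative validated cleft parameter sets `(q, τ)` = (1 mM/ms,
0.01 ms) and (0.05 mM/ms, 1 ms) produce drastically different pH time
courses but the same qualitative windup phenomenology; a grid-search
utility maps the validity zones (pH floor over a 100-stimulation train,
windup AUC and last-stimulus count within tolerances of the reference
run). The published thresholds for those tolerances are not printed
legibly in the source material, so the defaults (pH ≥ 7.0, ±25% AUC,
±30% count) are interpretive and configurable.

## Host WDR neuron

The host neuron is a calibrated re-creation using canonical
Hodgkin–Huxley forms, not a copy of any published parameter file; only
its behavioral targets are normative (small first-stimulus response,
monotone windup with a plateau, windup abolished without NK1, and the
ASIC/calcium orderings below). Geometry: dendrite 400×1 µm, soma
30×30 µm, axon initial segment 50×1 µm, specific capacitance
2.4 µF/cm², leak 0.1 mS/cm² at −65 mV, axial coupling 2 nS
(dendrite–soma) and 25 nS (soma–axon). Channels: Traub-type Na/K-dr on
soma and axon; on the dendrite a steep low-threshold L-type calcium
conductance (V½ = −45 mV, k = 3 mV, first-power activation,
Cav1.3-like), a calcium-activated nonspecific cation conductance
(CaAN, E = 0 mV) with slow activation (τ = 2 s) and fourth-order Hill
calcium dependence (K_d = 1.25 µM), and calcium-activated potassium
conductances at the published tuned densities (2 mS/cm² soma,
2.5 mS/cm² dendrite) with second-order Hill dependence. Calcium pools
are per-compartment with first-order extrusion (τ = 600 ms dendrite,
250 ms soma); the dendritic pool receives the designated 10% calcium
fractions of the NMDA, NK1 and ASIC currents plus a weakly weighted
(0.1) contribution of the dendritic L-type flux — the pool stands for
the perisynaptic shell sensed by CaAN/KCa rather than bulk calcium.

The dendrite is deliberately electrotonically remote: synaptic volleys
saturate it locally (driving-force-limited), while sustained currents
of a few tens of pA — NK1, ASIC, CaAN — move its baseline by
millivolts. Windup then works as follows. The NK1 conductance
(3 pS/synapse, τ_rise = 150 ms, τ_decay = 3 s) summates across the
1 Hz train and is the only control-condition quantity that accumulates
between stimuli; its growing depolarization, amplified by the steep
L-type window current, raises the sustained dendritic calcium seen by
CaAN, whose high-order slow activation converts that graded signal
into a progressively recruited depolarizing conductance and a growing
post-discharge. Removing NK1 leaves the per-stimulus response flat —
windup is abolished. A sustained ASIC current acts on the same pathway
(this is why its effect mimics and exceeds NK1's): moderate
conductances push CaAN recruitment and potentiate windup, while the
calcium carried by larger ASIC currents reaches the higher-K_d
dendritic KCa (12 µM), whose hyperpolarizing conductance overwhelms
the depolarization — the bell shape. The soma's KCa (K_d 0.6 µM,
saturating) provides within-burst adaptation and sets the firing-rate
ceiling.

Kd values of the lumped calcium sensors are expressed in the model's
effective pool concentration (resting 0.05 µM, windup range ~0.5–8 µM)
and are calibration parameters, not measured affinities.

## Latency-window analysis

Windows are half-open: Aβ [0, 20), Aδ [20, 90), C [90, 350),
post-discharge [350, 1000) ms after the stimulation artifact;
latencies ≥ 1000 ms are labeled `other`. The windup curve counts C +
post-discharge spikes per stimulus. AUC is the trapezoidal area of the
counts above the first-stimulus baseline with negative excess clipped
to zero (area-above-baseline convention; signed area available via a
flag). Percent inhibition of a drug condition is
`100(1 − drug/control)` computed from the total count and from the
AUC; zero control denominators yield NaN rather than an exception.
Conduction delays place monosynaptic responses inside their windows:
Aδ delays uniform on [20, 60) ms, C on [120, 260) ms, drawn once from
the configuration seed; the shipped reference scenario fixes this draw
(seed 0) as part of the model, so repeated runs are bit-identical.

## Synthetic recordings

The generator emulates the statistical structure of in vivo windup
recordings, not their biophysics: expected C-window counts follow
`μ_i = N1 + (Nmax − N1)(1 − e^{−(i−1)/κ})` (defaults N1 = 4,
Nmax = 25, κ = 3 stimuli over a 16-stimulation train, placing the
plateau near stimuli 13–16 and the first-stimulus count below 10);
realized counts are Poisson (negative-binomial optional); C latencies
are truncated log-normal inside [90, 350) ms; post-discharge and Aδ
activity are configurable fractions/rates; paired drug conditions
scale expectations by a programmed inhibition fraction with fresh
noise. Passing tests on these surrogates demonstrates that the
pipeline recovers programmed effects at realistic counts and noise —
they say nothing about spike sorting, electrode artifacts, or
non-Poisson burst structure in real recordings.

## Numerical choices and limitations

* Engine step 0.025 ms; halving it changes the 16-s control spike
  count by at most one spike at the shipped parameters.
* The exact-exponential ASIC h update is step-size independent at
  fixed pH; the engine updates pH per engine step.
* Spike detection: upward 0 mV crossings on the axonal compartment
  with a 2 ms lockout.
* A divergence guard aborts any simulation whose voltages leave
  ±200 mV, reporting the offending time.
* Simulations are deterministic given the configuration; the
  configuration hash and seed are recorded in each run's manifest.
* The host neuron is a behavioral re-creation: figure-level
  comparisons with the recorded data are qualitative (orderings and
  curve shapes), never trace-exact. In vivo inhibition magnitudes
  (~44–60%) depend on the unknown in vivo ASIC conductance and are
  deliberately out of scope; the pipeline-recovery tests instead use
  programmed inhibitions.
* The KCa-blocked scenarios remove a major stabilizing conductance and
  fire tonically; they are used only for ordering comparisons.
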