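# Methods

`hvcgrow` simulates how the premotor nucleus HVC of the juvenile zebra
finch could wire itself into a network that produces precisely timed
sequential bursting, and provides the statistics used to characterize
the grown networks plus a burst-tightness analysis for spike-train
tables. This note describes the model, its parameters, the numerical
choices, what the scaled-down study systems do and do not show, and the
known limitations.

## The model

**Geometry.** Neurons live on the surface of a sphere of radius
R = 260 μm: 550 GABAergic interneurons (HVC_INT) on a jittered
Fibonacci lattice (nearest-neighbor geodesic spacing ≈ 38 μm) and 2000
excitatory projection neurons (HVC_RA) placed uniformly at random, all
subject to a 10 μm exclusion diameter. Projection ↔ interneuron
connections are drawn independently per ordered pair with probability
p = exp(−d²/2σ²) of the geodesic distance d, with σ_RA→I = 130 μm and
σ_I→RA = 90 μm; the σ-as-standard-deviation convention is the default
because it reproduces the reported summary statistics (mean RA→INT
out-degree ≈ 65 at mean distance ≈ 155 μm; INT→RA ≈ 115 at ≈ 110 μm; a
flag selects the literal p = exp(−d²/σ²) kernel instead, which gives
≈ 33 and ≈ 115 μm). Initial weights are uniform on (0, 0.4) mS/cm²
(RA→INT) and (0, 0.03) mS/cm² (INT→RA). Every edge carries an axonal
delay = geodesic distance / conduction velocity (default 100 μm/ms,
giving RA-pair delays of ~0–8 ms). RA→RA synapses do not exist at the
start; they are created by plasticity alone.

The lattice jitter is printed as Δθ = 0.0006·Δr_in; we read it as a
surface displacement of 0.0006·Δr_in μm (the angle is divided by R,
and by sin θ in longitude, clamped at the poles). Read as radians it
would displace neurons by ~6 μm and pull the lattice spacing visibly
below the ≈ 40 μm the geometry is designed to produce.

**Projection neurons** are two-compartment Hodgkin–Huxley cells. The
soma carries Na (instantaneous m³, inactivation h), delayed-rectifier
K (n⁴), leak, and a low-threshold potassium current
I_KLT = G_KLT·l·(V−E_K) with G_KLT = 3.5 mS/cm², E_K = −90 mV,
τ_l = 10 ms and l∞(V) = 1/(1+exp(−(V+40)/5)). The dendrite carries
leak, a high-threshold Ca current G_Ca·r²·(V−E_Ca), and a Ca-activated
K current gated by accumulated Ca (half-activation Hill form); Ca
accumulates with the Ca current and decays with τ_c = 15 ms. In mature
cells (G_Ca = 55 mS/cm²) a sufficient dendritic excitatory conductance
(threshold ≈ 30–40 nS) triggers a regenerative dendritic Ca spike that
drives a stereotyped somatic burst (4–6 spikes, first interspike
interval ≈ 1 ms) terminated by the Ca-activated K current; the response
is all-or-none in the kick amplitude. Compartment areas are 5000 μm²
(soma) and 10,000 μm² (dendrite) — with these areas the stated noise
amplitudes 0.1 nA (soma) and 0.2 nA (dendrite) correspond to the same
current density in both compartments. Synaptic weights in nS convert to
densities through these areas; the conversion is the single explicit
knob linking network weights to the conductance scale of the neuron
model.

The cited published two-compartment model's full equations are not
reproduced in our sources, so the channel kinetics here (gate midpoints
and slopes, CaK coupling, compartment coupling 0.5 mS/cm² soma-side)
are this package's own parameterization, calibrated once against the
printed behavioral contract: mature burst on a 300 nS kick, immature
quiescence at rest, immature ≈ 0.6 Hz spontaneous rate under the stated
noise, and interneuron ≈ 10 Hz under bombardment. All printed constants
are used verbatim.

**Maturation.** A new neuron has elevated leak reversal E_L = −55 mV
and zero dendritic Ca conductance: it cannot burst, but membrane noise
makes it fire sparse single spikes at ≈ 0.6 Hz. Both variables relax
exponentially toward the mature values (E_mat = −80 mV,
G_mat = 55 mS/cm²), with τ_mat = 50,000 s for spontaneously active
neurons and 500 s once a neuron has spiked in more than half of the
past 1000 trials. The update is applied at the end of each trial as the
exact discrete solution of the linear ODE; one trial advances the
maturation clock by the trial's simulated duration (0.5 s by default).
The spontaneous rate falls monotonically as E_L matures, which is what
ultimately silences non-recruited neurons. For the windowed
classification the engine counts trials before a neuron's birth as
non-spiking (the "past 1000 trials" are taken literally), so newborns
always start as spontaneous.

**Noise.** Projection neurons receive white-noise currents implemented
as per-step Gaussian voltage increments with standard deviation
scale·amplitude·√dt (dt-robust; verified at dt = 0.02 and 0.04 ms). The
single dimensionless scale constant (1.86) was calibrated once against
the 0.6 Hz immature target and frozen. Interneurons receive excitatory
and inhibitory Poisson bombardment (rates 75/40 s⁻¹, kicks 0.03/0.015
mS/cm²), calibrated once to ≈ 10 Hz spontaneous firing and frozen.

**Synapses** follow kick-and-decay kinetics: a delivered spike adds the
weight to the receptor conductance, which decays exponentially
(τ = 5 ms for both excitation and inhibition). RA→RA excitation and the
training kick target the dendrite; interneuron inhibition targets the
soma (reversal −80 mV).

**Plasticity.** Burst-timing-dependent plasticity acts on the lag
Δt between the postsynaptic burst onset and the presynaptic burst-onset
*arrival* (emission + axonal delay). Δt > T₀ = 2 ms potentiates
additively (ramp to A_P = 0.25 nS at 5 ms, exponential tail
τ_P = 30 ms); Δt ≤ T₀ depresses multiplicatively (maximum fraction
A_D = 0.02 at −1 ms, tail τ_D = 30 ms); weights clip to [0, 4] nS.
The arrival-time convention is what lets the rule see axonal delays:
inputs whose delayed arrival falls after the postsynaptic burst are
depressed, which prunes long-delay connections at realistic conduction
velocity. Synapses are implicit: any ordered pair has a latent
zero-weight synapse that any positive update instantiates. Weights
below W_a = 0.2 nS are silent (no conductance), between 0.2 and 1 nS
active, above W_s = 1 nS supersynaptic; boundaries classify upward. All
states participate in BTDP. When a neuron holds N_s = 10 supersynapses
it is saturated: its sub-supersynaptic efferents are withdrawn
(no conductance, no BTDP, still decaying); the withdrawn state is
derived from (saturation, weight), so losing a supersynapse restores
the remainder automatically. Every RA→RA weight decays by δ = 0.01 nS
at each trial end.

**Trials and growth.** Each trial integrates the whole network for
500 ms (dt = 0.02 ms) from rest; at a uniformly random time in
(100, 400) ms the 10 fully mature training neurons receive a
synchronous 300 nS dendritic kick and burst. BTDP updates fire
event-driven at each new burst onset (first spike after a > 30 ms gap;
a total-duration variant is a config flag), updating all afferent and
efferent synapses against the partners' most recent onsets — one update
per synapse and burst pair. After the trial: potentiation decay,
remodeling re-check, maturation, then turnover — a pool neuron that
spiked in fewer than 80 of the past 4000 trials is replaced by a new
immature neuron at a fresh random position with freshly sampled
interneuron connectivity and zeroed RA→RA weights (neurons younger than
the window are exempt). Growth stops when the supersynapse count has
been constant for 10,000 trials.

**Why a chain grows.** Pool neurons that happen to spike inside the
LTP window after the training barrage have all their input synapses
from the training set potentiated at once; once some inputs become
active, the extra depolarization biases the neuron to spike there
again — a positive feedback that drives weights to the supersynaptic
range. Saturation caps each neuron at 10 strong outputs, creating
competition and stopping the seed neurons from hoarding targets; the
recruited cohort then spikes reliably, matures quickly, loses
spontaneous activity, and acts as the next growth edge. Because
newborn neurons are the most spontaneously active, they are
preferentially recruited — hence the positive correlation between
birth time and burst time once turnover is running.

## Scaled-down study systems

The full 2000/550, 30,000-trial experiments are cluster-scale. The
packaged presets reproduce the mechanisms in miniature; the package's
property checks and worked examples run on them:

* 120 projection + 36 interneurons on a sphere of radius 64 μm — the
  same areal densities as the full model (the radius scales with √N,
  and the lattice spacing stays ≈ 38 μm).
* Connection-kernel widths and the conduction velocity scale with the
  radius (σ = 32.0/22.2 μm, v = 24.6 μm/ms). This preserves the
  *fractional* connectivity (≈ 11.6% RA→INT, ≈ 5.8% INT→RA) — and with
  it the heterogeneity of feedback inhibition that decides which
  neurons get recruited — and keeps the axonal delay range in
  milliseconds identical to the full model (0–8 ms), which the
  delay-pruning mechanism needs. Keeping the absolute widths instead
  makes the mini network near-fully connected: the post-kick
  inhibitory barrage is then homogeneous and strong enough to abolish
  pool spiking in the LTP window, and no growth occurs.
* Trials are 320 ms with the kick window at (60, 140) ms — spontaneous
  spikes far from the stimulation window contribute almost nothing to
  growth, so shortening the tail trades little mechanism for a
  substantial speedup. dt = 0.04 ms (the integrator is unconditionally
  stable; see below).
* The maturation clock advances 20 s per trial and the reliability
  window is 100 trials, so τ_fast ≈ 25 trials, τ_slow ≈ 2500 trials:
  scheduled maturation, recruitment-driven fast maturation and
  turnover (window 400, threshold 8 — the same 2% silence fraction)
  all unfold within ~2–3 thousand trials instead of tens of thousands.
* Growth runs of 1000–2400 trials, 100–200 frozen test trials.

At these sizes a grown network recruits ≈ 30–45 neurons into a chain
spanning ≈ 40–60 ms. The acceptance checks verify, on these systems:
the supersynaptic graph is a DAG whose sources are exactly the
training neurons; disabling maturation (uniformly mature pool with
0.25/0.5 nA noise) produces cycles instead; birth time and burst time
of recruited neurons correlate positively; median burst-onset jitter
across 200 frozen trials is below 1 ms; grown edges are biased toward
short delays at realistic velocity and the bias disappears at 10×
velocity; the 1-ms burst-density CV is higher at 10× velocity
(synchronous, synfire-like groups) than at 1×; and during growth the
recruited neurons saw less inhibition than the non-recruited
population inside their parents' LTP windows (median Δ < 0).

What the minis do **not** show: absolute counts (306 recruited of
2000, specific inhibitory-weight means), the sharpness and location of
the velocity-driven synfire transition (a two-condition ordering is
tested, not the full sweep), and protosyllable-scale chain durations.
Spatial inhibition is effectively global at this sphere size, with one
measurable consequence: the inhibitory conductance difference around a
recruited neuron's *own* burst (area 10 ms before minus 10 ms after)
comes out non-positive here. The ten synchronized training neurons are
a large fraction of the mini chain, so each trial's inhibitory barrage
is front-loaded and already decaying when the recruits burst 7–16 ms
later; the local wave-following inhibition that dominates this
statistic at full scale is masked by the global envelope. The
corresponding acceptance check asserts the full-scale sign and is
expected to fail at this scale; the parent-aligned LTP-window
difference Δ, which compares recruited against non-recruited neurons
in the *same* intervals and therefore cancels the global envelope, is
robustly negative as expected.

## Numerics

* **Integrator.** All neurons advance by an exponential-midpoint
  scheme: each compartment voltage relaxes toward its instantaneous
  steady state E = Σgᵢ·Eᵢ/Σgᵢ with factor exp(−g_tot·dt/C); gates use
  their exact exponential relaxation with voltage-dependent targets and
  time constants; Ca integrates its linear ODE exactly for a frozen Ca
  current. A half-step predictor plus fixed-point correctors evaluates
  all coefficients at the midpoint. The scheme is unconditionally
  stable — during the dendritic Ca spike the total conductance
  transiently exceeds 100 mS/cm², which destabilizes explicit
  Runge-Kutta steps at dt ≥ 0.04 ms. On the standard mature-burst test,
  halving dt from 0.02 ms moves spike times by < 0.004 ms with three
  correctors (the single-neuron default) and ~0.03 ms with one
  corrector (the network default, where the ≥ 0.1 ms noise-driven
  jitter dominates timing anyway).
* Voltage-dependent gate functions and the exp(−x) relaxation factor
  are evaluated through lookup tables with linear interpolation
  (0.02 mV and 10⁻³ grids); the interpolation error is far below the
  truncation error.
* Spike times are −20 mV upward crossings of the somatic voltage,
  refined by linear interpolation within the step. Conduction delays
  are rounded to integer steps (minimum one step).
* Trial resets integrate each neuron to its resting state
  deterministically (200 ms at dt = 0.05 ms); rest states are cached
  per neuron and recomputed when maturation has moved E_L by more than
  0.25 mV or G_Ca by more than 0.5 mS/cm².
* Randomness: a master seed spawns independent streams for placement,
  connectivity, replacements, and per-trial dynamics (trial seeds are
  derived from the master seed and trial index), so any trial can be
  replayed bit-identically from a checkpoint and whole runs are
  reproducible on one platform.

## Design choices on genuinely open points

* **Δt convention**: burst-onset arrival (emission + delay), not
  emission time — required by the delay-pruning mechanism and by the
  definition of the LTP window used in the inhibition analysis.
* **Trials-per-second of maturation**: the default clock increment is
  the trial's simulated duration; the presets compress it (a config
  value), trading nothing but the separation of timescales.
* **Exactly-half reliability** classifies as spontaneous ("more than
  half" is strict); boundary weights classify upward; "spiked" means
  any somatic spike, for both the maturation and turnover windows.
* **Potentiation decay scope**: RA→RA synapses only; RA↔INT weights
  are fixed draws.
* **BTDP applies uniformly**, including synapses onto training
  neurons; mature neurons' lack of spontaneous activity keeps loops
  from forming regardless.
* **Inhibition analysis** runs with turnover disabled so recruited and
  non-recruited populations stay comparable across the whole run; the
  non-recruited reference is the mean trace over non-recruited pool
  neurons in the same absolute intervals.
* **Singleton bursts** carry no first ISI and are excluded from
  tightness medians (counted separately).

## Limitations

* The channel kinetics are a calibrated stand-in for the cited
  conductance-based model, matched at the behavioral level only.
* The scaled-down presets preserve structure and mechanism, not
  absolute numbers; quantitative claims about the full-size model
  (counts, weight distributions, transition velocities) are out of
  reach at package-test scale.
* The depolarizing-GABA developmental switch, multi-compartment
  dendrites, HVC_X neurons, ellipsoidal geometry, syllable-locking
  detection for real recordings, and protosequence splitting are all
  out of scope.
* Floating-point reproducibility is per-platform: identical seeds give
  byte-identical runs on one machine but may differ across CPU
  architectures or numba versions.
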