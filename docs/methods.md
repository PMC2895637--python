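# Methods

`ca3net` simulates a small recurrent network abstraction of hippocampal area
CA3 in which place-cell sequences are written into the recurrent synapses by
spike-timing dependent plasticity (STDP) during theta-rhythmic exploration,
and read back out as fast, ripple-like replay when cholinergic tone drops.
This note documents the model, its parameters, the numerical choices, and
the places where the design was genuinely open.

## Network and neuron model

The network holds 100 excitatory Izhikevich units, fully recurrently
connected without self-connections (a sparse variant with exactly 15
presynaptic partners per cell is available via `sparse=True`). Each unit
follows

    v' = 0.04 v^2 + 5 v + 140 − u + I,      u' = a (b v − u),

with regular-spiking constants a = 0.02, b = 0.2, c = −65, d = 6 and a spike
threshold of v = 30. Integration is forward Euler on a 1-ms grid with two
0.5-ms half-steps for `v` and one full step for `u`, and the reset is applied
*before* the update: any unit above threshold at the start of a step is
recorded as having fired in that step and reset (v ← c, u ← u + d). Under
this exact scheme the smallest 1-ms current pulse that fires a resting cell
(v = −70, u = −14) is 16.4 — the excitability anchor that calibrates every
current in the model.

Each neuron carries an integer axonal delay drawn uniformly from
{1, …, D} ms with D = 5 by default; a spike emitted at t reaches *all* of
that neuron's targets at t + D_i. Synaptic transmission is a 1-ms
rectangular current pulse of magnitude w/Φ (see neuromodulation below);
simultaneous arrivals sum linearly. Weights live in [0, w_max] with
w_max = 1, so during learning (Φ = 1) a single synapse is far below the 16.5
needed to fire a resting cell — recurrent input biases spike timing but
cannot cause firing on its own.

## Theta-coded drive and phase precession

A global theta variable θ(t) = (1 + cos 2πft)/2 oscillates in [0, 1] at
f = 8 Hz. Every cell receives, per millisecond:

* inhibition ~ Normal(−15 θ, 2) — weakest at mid-cycle (phase π), which is
  where noise firing and in-field bursting concentrate;
* excitatory noise ~ Uniform(0, 0.8), which alone produces the target
  spontaneous rate of ≈0.1 Hz per neuron.

Place fields of 80 cm diameter sit every `offset` cm on a circular route
traversed at 10 cm/s. Each field is split into eight equal segments, and
each segment is assigned a theta phase window in *reverse* order: a cell is
stimulated late in the cycle when its field is entered and progressively
earlier as the field is traversed — stepwise phase precession, which
theta-compresses the behavioural sequence into each 125-ms cycle. While the
animal is in a cell's current window, that cell draws an independent
Normal(I_ext = 5, σ_ext = 22.5) current each millisecond; draws are not
clipped at zero (the large σ_ext relative to I_ext is the point — firing is
by stochastic threshold crossing, and the negative tail is part of the
statistics). Cells sharing a field therefore fire with the same mean phase
but not in the same milliseconds.

**Window geometry.** The default (`window_mode="partition"`) divides the
full cycle into eight π/4-wide windows whose centres run from π/8 (earliest)
to 15π/8 (latest); this uses both the π/4 width and the π/8–15π/8 range
directly. Two alternative readings are selectable: eight 7π/32 windows
squeezed inside [π/8, 15π/8] (`span8`), or seven π/4 windows in that span
with the last two segments sharing the earliest window (`span7`). The choice
shifts the in-field rate by only a few percent.

With the defaults, a lone cell fires at ≈10.8 Hz averaged over its field —
bursts of 2–3 spikes near the field centre (mid-cycle, minimal inhibition)
and single spikes at entry and exit, i.e. ≈16 Hz at the centre segments and
≈6–7 Hz at the edges. We note the commonly quoted in-field mean for such
cells is ~15 Hz; the shape of the rate profile, not its exact mean, is what
drives the plasticity results below.

## Plasticity

All three rules are additive STDP with hard bounds, a lax nearest-neighbour
pairing scheme, and presynaptic timing taken at terminal *arrival*
(spike + axonal delay). For an isolated pairing with lag
s = t_post − t_pre_arrival:

    s > 0 :  Δw = A+ · exp(−s/τ+)
    s ≤ 0 :  Δw = A− · exp( s/τ−)

so exact coincidence yields the full A− — maximal depression. The rules are
(amplitudes as fractions of w_max, times in ms):

| rule | name                  | A+   | A−     | τ+ | τ− | τ++ | ε |
|------|-----------------------|------|--------|----|----|-----|---|
| A    | pair, BCM type        | 0.02 | −0.01  | 20 | 50 | —   | 0 |
| B    | triplet, BCM type     | 0.02 | −0.01  | 20 | 50 | 20  | 1 |
| C    | pair, non-BCM type    | 0.02 | −0.021 | 20 | 20 | —   | 0 |

Rule B adds, to each potentiation increment, ε times a trace of the most
recent *realised* weight decrease at the synapse, decaying with τ++ — the
triplet effect in which potentiation suppresses recent depression. The trace
stores the post-clip, post-modulation decrease (the actual weight change, as
the trace is defined in terms of the weight decrease, not the nominal
increment), is overwritten on each new decrease, and is not consumed by use.

Pairing is "lax nearest neighbour": each side keeps only the time of its
most recent event; a pre arrival pairs with the most recent post spike
(including one in the same millisecond — a coincident pair is a single s = 0
depression and nothing else), a post spike pairs with the most recent
strictly earlier arrival. Traces reset on every own-side event and are not
consumed, so one arrival can partner several spikes of a post burst. At
w_init = 0.01 w_max, about 64 isolated pairings at s = 5 ms traverse the
full weight range for rules A/B (the closed-form ceiling of the printed
"~60 pairings").

The BCM distinction is emergent: under independent Poisson firing, rules
A/B drift from depression at low rates to potentiation at high rates
(potentiation dominates at short lags because A+ e^{−s/τ+} > |A−| e^{−s/τ−}
for small s), while rule C (larger |A−|, equal time constants) drifts
non-positively. `analysis.rate_response_curve` measures this directly.

**Theta-modulated plasticity.** Three schemes multiply the increments by
phase-dependent factors: `none` (identity), `theta` (m+ = 1 − θ, m− = θ:
potentiation full and depression suppressed where bursts occur), and
`inverse` (the swap). The functional forms could not be fixed uniquely from
the available material; this assignment is the one consistent with the
observed scheme phenomenology (strongest auto-associative weights and
background potentiation under `theta` with rule B; rule C able to form
bidirectional weights only when depression is silenced at the burst phase).
The scheme lives behind a single interface (`plasticity.modulation_factors`
and the kernel's scheme code) so alternative forms are a one-line change.
During recall the theta oscillator is off and modulation is identity;
increments remain scaled by Φ.

## Neuromodulation, learning and recall

An abstract acetylcholine level Φ switches regimes: recurrent currents are
scaled by 1/Φ and plasticity increments by Φ. Learning runs at Φ = 1 (weak
recurrence, full plasticity); recall at Φ ∈ {0.05, 0.083, 0.111} (strong
recurrence, suppressed — but not zero — plasticity). Φ = 0 is accepted as a
frozen-plasticity control, with the recurrent gain left at its learning
value. During recall, theta inhibition is switched off entirely (σ_inh with
it), the noise current stays on, place-field drive is absent, and a
superthreshold pulse I_cue = 30 is injected into the cue set for exactly one
millisecond at t = 0.

Three learning presets define the study conditions (all 100 cells, 10 laps,
10 cm/s):

* **hetero** — 100 fields offset 10 cm (10-m route), 1 cell/field; cue: 1
  neuron at Φ = 0.05, 600-ms epochs;
* **auto** — 10 non-overlapping fields offset 80 cm (8-m route), 10
  cells/field; cue: 5 of 10 at Φ = 0.083, 20-ms observation window;
* **dual** — 20 fields offset 10 cm (2-m route), 5 cells/field; cue: 3 of 5
  at Φ = 0.111, 150-ms epochs.

Default modulation schemes follow the representative conditions: `none` for
hetero, `theta` for auto and dual. Recall epoch durations (600/100/150 ms)
comfortably contain the replay events they measure.

## Measurements

* **Weight structure** — foreground = synapses onto the 1–3 next fields
  (sequence paradigms) and/or same-field synapses (associative paradigms);
  background = the remaining off-diagonal synapses. Means are compared with
  a two-sided Mann–Whitney U (asymptotic normal approximation with tie
  correction; thousands of synapses per group).
* **Sequence fidelity** — each cell's first spike against the first spike in
  any cell of the *next* field: before/same-time/after (after includes
  silence). The route is circular, so on a cued sweep the cells just behind
  the cue are necessarily "after"; this bounds attainable fidelity below
  100%.
* **Pattern completion** — uncued same-pattern cells firing within 20 ms of
  the cue are accurate; any off-pattern spike in the window is an error.
* **Sweep duration** — cue to the last *first*-spike over all neurons, i.e.
  the time for the replay to span the full learned pattern. (The raw last
  spike of an epoch would instead measure re-entrant second-loop echo plus
  noise stragglers.)
* **Effective replay speed** — route length divided by the interval from the
  cue-evoked spike to the first cued-field spike occurring after every other
  field has fired (first-return definition on the circular route).
* **Field expansion** — per-lap circular-mean theta phase of spikes emitted
  in the entry and exit segments; potentiated feed-forward input shifts the
  entry phase earlier across laps.

## Numerical and design choices

* One global 1-ms grid; all ties (coincident spikes, same-time
  classifications) are resolved at that resolution.
* Within a step the order is: spike detection/reset → delivery → drive →
  plasticity → integration; recurrent currents use the weights from before
  that step's plasticity updates.
* The hot loop is a single numba-compiled kernel shared by learning, recall,
  background-only and scripted-spike modes; the scripted mode forces spikes
  from a schedule (bypassing the membrane) so plasticity tests exercise the
  production event path. A pure-Python synapse engine
  (`plasticity.process_spike_event`) mirrors the kernel semantics
  event-for-event and is cross-checked against an offline brute-force
  pairing oracle to 1e-12 relative tolerance.
* Noise-spike plasticity is not special-cased: all spikes drive pairing, in
  learning and recall alike (recall increments are suppressed by Φ).
* Raster buffers are preallocated from a 50-Hz-per-neuron ceiling; overflow
  raises rather than silently truncating.
* Weight snapshots are taken once per lap.

## Problem sizes used in the shipped checks

The packaged regeneration script runs the full presets: 10-lap learning for
all three paradigms, 100 recall epochs for hetero and auto, 20 for dual,
five independent auto learning runs for the weight average, 2000 s of
background simulation, and 20 field traversals for the single-cell rate.
The test suite reuses single 10-lap learned networks across its recall
checks and asserts stochastic quantities with ±20% bands.

## Known limitations

* Quantitative offsets against the reference values it aims to reproduce:
  the single-cell in-field mean is ≈10.8 Hz rather than ~15; the hetero
  replay sweep runs ≈290 ms (≈32 m/s) rather than ~400 ms (~25 m/s) because
  saturated +2/+3-field connections let the wave skip ahead; the dual replay
  speed is ≈60 m/s rather than ~80; and the triplet rule's auto-associative
  equilibrium sits at ≈0.87 w_max rather than ~0.7. The qualitative
  structure — which rules potentiate what, saturation, completion without
  errors, self-terminating ~33-ms dual events — reproduces throughout.
* Conductance-based synapses, dendritic structure, explicit interneurons,
  gamma sub-cycles, reverse replay, synaptic scaling and metaplasticity are
  out of scope by design.
* The phenomenological drive *imposes* phase precession; it does not explain
  it, and passing tests say nothing about biophysical precession mechanisms.
* With repeated or overlapping memories the BCM-type rules' background
  potentiation (no inherent competition) would eventually saturate the
  network; only single-episode encoding is modelled.
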