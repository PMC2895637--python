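# ca3net

A spiking recurrent network model of hippocampal area CA3 that learns and
replays place-cell sequences, for computational neuroscientists studying how
spike-timing dependent plasticity (STDP) interacts with theta-coded neural
dynamics.

During exploration, hippocampal place cells fire at progressively earlier
phases of the ~8 Hz theta rhythm as their place field is traversed (phase
precession), compressing the behavioural sequence of fields into a repeated
within-cycle spike sequence. `ca3net` drives 100 Izhikevich neurons with a
phenomenological model of this process and lets additive STDP act on every
recurrent synapse. Depending on the coding regime, the same learning rule
writes different structure into the weight matrix:

* cells driven in *sequence* (one cell per field, overlapping fields)
  develop **asymmetric** connections — each cell strengthens its synapses
  onto the cells for the next few fields (hetero-association);
* cells driven *together* (several cells per field) develop **symmetric**
  bidirectional connections (auto-association) — provided the rule
  potentiates at short inter-spike intervals, the signature of BCM-like
  rate-coded Hebbian learning;
* with both codes at once (dual coding), both structures form side by side.

Dropping an abstract acetylcholine level Φ then switches the network from
learning to recall: recurrent synapses are rescaled by 1/Φ, plasticity by Φ,
theta inhibition stops, and a single-millisecond suprathreshold cue evokes
sharp-wave-ripple-like replay — sequence prediction along the learned route
and/or pattern completion of a partially cued ensemble.

## Model core

Neurons follow the Izhikevich model (1-ms grid, Euler with half-steps
for v, reset before update; spike at v ≥ 30):

    v' = 0.04 v² + 5v + 140 − u + I        u' = a(bv − u)
    if v ≥ 30:  v ← c,  u ← u + d          (a, b, c, d) = (0.02, 0.2, −65, 6)

Spikes reach their targets after per-neuron axonal delays uniform on
{1…5} ms. With s = t_post − t_pre-arrival, each pairing under the lax
nearest-neighbour scheme changes the synapse by

    Δw = A₊ e^(−s/τ₊)                        s > 0
    Δw = A₋ e^(s/τ₋)                         s ≤ 0   (s = 0: maximal depression)

plus, for the triplet rule, ε·|last weight decrease|·e^(−s₊₊/τ₊₊) on each
potentiation. Three rule parameterisations are built in (pair/triplet BCM
type, pair non-BCM type), three theta-modulation schemes, and hard bounds
w ∈ [0, w_max] with w_init = 0.01 w_max. See `docs/methods.md` for the full
account.

## Worked example

Learn a dual-coded route (20 overlapping 80-cm fields on a 2-m circular
track, five cells per field, ten laps) with the triplet rule, then cue three
of the five cells of one field at low acetylcholine:

```python
from ca3net import (dual_protocol, run_learning, run_recall, RecallProtocol,
                    weight_summary, classify_sequence_recall, effective_speed)
from ca3net.drive import PlaceMap

proto = dual_protocol(rule="B")          # 20 fields x 5 cells, 10 laps
learned = run_learning(proto, seed=1)
pm = PlaceMap.from_route(proto.route)

ws = weight_summary(learned.w_final, pm, "dual")
print(f"foreground mean w = {ws.foreground_mean:.3f}")
print(f"background mean w = {ws.background_mean:.3f}")

cue = tuple(pm.cells_of_field(4)[:3])    # 3 of the 5 cells of field 4
recall = run_recall(learned.w_final, learned.delays, learned.conn,
                    RecallProtocol(cue_ids=cue, phi=0.111, duration_ms=150),
                    seed=2)
first = recall.spikes.groupby("neuron_id").time_ms.min()
print(f"replay sweep      = {first.max()} ms to span all {len(first)} cells")
print(f"effective speed   = {effective_speed(recall.spikes, proto.route, pm, 4):.1f} m/s")
```

Output:

```
foreground mean w = 0.881
background mean w = 0.018
replay sweep      = 38 ms to span all 100 cells
effective speed   = 55.6 m/s
```

The foreground synapses (same field or 1–3 fields ahead on the route) have
been driven near the upper bound while background synapses stay close to
their initial 0.01; the 1-ms cue then triggers a self-terminating replay
event that sweeps the entire learned route in a few tens of milliseconds —
an order of magnitude faster than the ~20 s behavioural traversal, on the
timescale of sharp-wave ripples.

A command-line front end wraps the same machinery:

```sh
ca3net learn --preset hetero --rule B --seed 1 --out runs/hetero
ca3net recall --archive runs/hetero --phi 0.05 --epochs 5
ca3net analyze --archive runs/hetero --plot runs/hetero/summary.png
ca3net reproduce fig6-dual --epochs 100
```

Archives are plain delimited text (raster CSV, dense weight matrices, YAML
config echo) and round-trip losslessly.

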