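"""Learning and recall protocols: the three encoding paradigms and the
cue-evoked recall paradigm, plus a scripted-spike harness.

Presets (all at 10 cm/s, 10 laps, 100 cells, axonal delays on {1..5} ms):

* ``hetero``: 100 overlapping 80-cm fields offset by 10 cm (10-m circular
  route), one cell per field — pure sequence (temporal) code.
* ``auto``: 10 non-overlapping 80-cm fields offset by 80 cm (8-m route),
  ten cells per field — repeated presentation of orthogonal rate-coded
  patterns.
* ``dual``: 20 overlapping 80-cm fields offset by 10 cm (2-m route), five
  cells per field — simultaneous rate and temporal code.

During learning the cholinergic level is Phi = 1: recurrent currents are weak
(w <= w_max = 1, versus the ~16.5 needed to fire a resting cell) and
plasticity runs at full gain.  During recall Phi drops, theta inhibition is
switched off, place-field drive is absent, noise stays on, and a one-step
superthreshold pulse (I_cue = 30) is delivered to a small cue set; recurrent
currents scaled by 1/Phi then propagate activity through the learned weights.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from . import kernel
from .drive import (DriveConfig, NoiseConfig, PlaceMap, RouteConfig,
                    ThetaConfig, WINDOW_MODES)
from .neuron import (
    DEFAULT_PARAMS,
    NeuronParams,
    draw_delays,
    full_connectivity,
    resting_state,
    sparse_connectivity,
)
from .plasticity import MOD_SCHEMES, STDPConfig, get_rule

__all__ = [
    "LearningProtocol",
    "RecallProtocol",
    "SimResult",
    "hetero_protocol",
    "auto_protocol",
    "dual_protocol",
    "single_cell_protocol",
    "run_learning",
    "run_background",
    "run_recall",
    "run_scripted",
]

_MOD_CODE = {"none": kernel.MOD_NONE, "theta": kernel.MOD_THETA, "inverse": kernel.MOD_INVERSE}
_WIN_CODE = {"partition": kernel.WIN_PARTITION, "span8": kernel.WIN_SPAN8, "span7": kernel.WIN_SPAN7}

# Per-neuron spike-capacity ceiling used to size raster buffers (Hz).
_RATE_CEILING_HZ = 50.0


@dataclass(frozen=True)
class LearningProtocol:
    """Full specification of one theta-coded learning run."""

    route: RouteConfig
    stdp: STDPConfig
    modulation: str = "none"
    theta: ThetaConfig = ThetaConfig()
    noise: NoiseConfig = NoiseConfig()
    drive: DriveConfig = DriveConfig()
    neuron: NeuronParams = DEFAULT_PARAMS
    d_max: int = 5
    sparse: bool = False          # 15 presynaptic inputs per neuron if True
    n_sparse_inputs: int = 15
    window_mode: str = "partition"
    phi: float = 1.0
    paradigm: str = "custom"      # 'hetero' | 'auto' | 'dual' | ...

    def __post_init__(self):
        if self.modulation not in MOD_SCHEMES:
            raise ValueError(f"unknown modulation scheme {self.modulation!r}")
        if self.window_mode not in WINDOW_MODES:
            raise ValueError(f"unknown window_mode {self.window_mode!r}")
        if self.d_max < 1:
            raise ValueError("d_max must be >= 1")

    @property
    def n_neurons(self) -> int:
        return self.route.n_cells

    @property
    def duration_ms(self) -> int:
        return self.route.n_laps * self.route.lap_time_ms


@dataclass(frozen=True)
class RecallProtocol:
    """Cue-evoked recall: theta inhibition off, noise on, low ACh."""

    cue_ids: tuple[int, ...]
    phi: float
    duration_ms: int
    i_cue: float = 30.0
    noise: NoiseConfig = NoiseConfig()
    neuron: NeuronParams = DEFAULT_PARAMS
    stdp: STDPConfig | None = None   # plasticity still runs, scaled by phi
    plasticity_on: bool = True

    def __post_init__(self):
        if len(self.cue_ids) == 0:
            raise ValueError("cue set must not be empty")
        if not self.phi > 0:
            raise ValueError("phi must be > 0 during recall")


@dataclass
class SimResult:
    """Spike raster, weight matrices and bookkeeping from one run."""

    spikes: pd.DataFrame            # columns: time_ms, neuron_id
    w_initial: np.ndarray
    w_final: np.ndarray
    snapshots: np.ndarray           # (n_snapshots, n, n); per lap for learning
    snapshot_times: np.ndarray
    delays: np.ndarray
    conn: np.ndarray
    config: dict
    seed: int


def hetero_protocol(rule: str = "B", modulation: str = "none", **overrides) -> LearningProtocol:
    route = RouteConfig(n_fields=100, offset_cm=10.0, cells_per_field=1,
                        n_laps=overrides.pop("n_laps", 10))
    return LearningProtocol(route=route, stdp=get_rule(rule),
                            modulation=modulation, paradigm="hetero", **overrides)


def auto_protocol(rule: str = "B", modulation: str = "theta", **overrides) -> LearningProtocol:
    route = RouteConfig(n_fields=10, offset_cm=80.0, cells_per_field=10,
                        n_laps=overrides.pop("n_laps", 10))
    return LearningProtocol(route=route, stdp=get_rule(rule),
                            modulation=modulation, paradigm="auto", **overrides)


def dual_protocol(rule: str = "B", modulation: str = "theta", **overrides) -> LearningProtocol:
    route = RouteConfig(n_fields=20, offset_cm=10.0, cells_per_field=5,
                        n_laps=overrides.pop("n_laps", 10))
    return LearningProtocol(route=route, stdp=get_rule(rule),
                            modulation=modulation, paradigm="dual", **overrides)


def single_cell_protocol(n_laps: int = 20, **overrides) -> LearningProtocol:
    """One isolated place cell on a 160-cm route: 8 s in-field, 8 s out,
    per lap.  Used for drive-statistics diagnostics."""
    route = RouteConfig(n_fields=1, offset_cm=160.0, cells_per_field=1,
                        n_laps=n_laps)
    return LearningProtocol(route=route, stdp=get_rule("A"),
                            paradigm="single", **overrides)


def _build_topology(proto: LearningProtocol, seed: int):
    rng = np.random.default_rng(seed)
    n = proto.n_neurons
    delays = draw_delays(n, proto.d_max, rng)
    if proto.sparse:
        conn = sparse_connectivity(n, proto.n_sparse_inputs, rng)
    else:
        conn = full_connectivity(n)
    w = np.where(conn, proto.stdp.w_init, 0.0)
    return delays, conn, w


def _empty_sched():
    return np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64)


def _spike_frame(spike_t, spike_id) -> pd.DataFrame:
    return pd.DataFrame({"time_ms": spike_t, "neuron_id": spike_id})


def run_learning(
    proto: LearningProtocol,
    seed: int,
    snapshots_per_lap: bool = True,
    record_spikes: bool = True,
) -> SimResult:
    """Simulate one full theta-coded learning run and return raster + weights."""
    ss = np.random.SeedSequence(seed)
    topo_seed, drive_seed = [int(s) for s in ss.generate_state(2) >> 1]
    delays, conn, w = _build_topology(proto, topo_seed)
    place = PlaceMap.from_route(proto.route)
    n = proto.n_neurons
    duration = proto.duration_ms
    lap = proto.route.lap_time_ms
    if snapshots_per_lap:
        snap_times = np.array(
            [k * lap - 1 for k in range(1, proto.route.n_laps + 1)], dtype=np.int64
        )
    else:
        snap_times = np.array([duration - 1], dtype=np.int64)
    w_initial = w.copy()
    rest = resting_state(proto.neuron)
    v0 = np.full(n, rest.v)
    u0 = np.full(n, rest.u)
    max_spikes = int(n * duration / 1000.0 * _RATE_CEILING_HZ) + 10_000
    if not record_spikes:
        max_spikes = 1
    field_start = np.array(
        [proto.route.field_start_cm(f) for f in range(proto.route.n_fields)]
    )
    sched_t, sched_id = _empty_sched()
    np_params = proto.neuron
    spike_t, spike_id, overflow, snaps, _, _ = kernel.simulate(
        duration, conn, delays, w,
        np_params.a, np_params.b, np_params.c, np_params.d, np_params.v_thresh,
        v0, u0,
        True, proto.theta.inhibition_gain, proto.theta.sigma_inh,
        proto.theta.frequency_hz,
        proto.noise.i_noise,
        True, proto.drive.i_ext, proto.drive.sigma_ext,
        place.field_of.astype(np.int64), field_start,
        proto.route.diameter_cm, proto.route.speed_cm_s, proto.route.length_cm,
        _WIN_CODE[proto.window_mode],
        True,
        proto.stdp.a_plus * proto.stdp.w_max, proto.stdp.a_minus * proto.stdp.w_max,
        proto.stdp.tau_plus, proto.stdp.tau_minus,
        max(proto.stdp.tau_plusplus, 1.0), proto.stdp.eps, proto.stdp.w_max,
        _MOD_CODE[proto.modulation], proto.phi,
        np.empty(0, dtype=np.int64), 0.0, -1,
        False, sched_t, sched_id,
        drive_seed, max_spikes, snap_times,
    )
    if overflow and record_spikes:
        raise RuntimeError("spike buffer overflow; raise _RATE_CEILING_HZ")
    return SimResult(
        spikes=_spike_frame(spike_t, spike_id),
        w_initial=w_initial, w_final=w, snapshots=snaps,
        snapshot_times=snap_times, delays=delays, conn=conn,
        config={"kind": "learning", "paradigm": proto.paradigm,
                "rule": proto.stdp.rule_id, "modulation": proto.modulation,
                "phi": proto.phi, "n_laps": proto.route.n_laps,
                "n_fields": proto.route.n_fields,
                "cells_per_field": proto.route.cells_per_field,
                "offset_cm": proto.route.offset_cm,
                "diameter_cm": proto.route.diameter_cm,
                "window_mode": proto.window_mode, "d_max": proto.d_max,
                "sparse": proto.sparse},
        seed=seed,
    )


def run_background(
    duration_ms: int,
    seed: int,
    n_neurons: int = 100,
    theta: ThetaConfig = ThetaConfig(),
    noise: NoiseConfig = NoiseConfig(),
    neuron: NeuronParams = DEFAULT_PARAMS,
    d_max: int = 5,
    w_frac: float = 0.01,
) -> SimResult:
    """Background-only run: theta inhibition + noise, no place-field drive,
    weights held at ``w_frac * w_max``.  Diagnoses the spontaneous rate."""
    ss = np.random.SeedSequence(seed)
    topo_seed, drive_seed = [int(s) for s in ss.generate_state(2) >> 1]
    rng = np.random.default_rng(topo_seed)
    delays = draw_delays(n_neurons, d_max, rng)
    conn = full_connectivity(n_neurons)
    w = np.where(conn, w_frac, 0.0)
    rest = resting_state(neuron)
    v0 = np.full(n_neurons, rest.v)
    u0 = np.full(n_neurons, rest.u)
    max_spikes = int(n_neurons * duration_ms / 1000.0 * 5.0) + 10_000
    sched_t, sched_id = _empty_sched()
    snap_times = np.array([duration_ms - 1], dtype=np.int64)
    spike_t, spike_id, overflow, snaps, _, _ = kernel.simulate(
        duration_ms, conn, delays, w,
        neuron.a, neuron.b, neuron.c, neuron.d, neuron.v_thresh,
        v0, u0,
        True, theta.inhibition_gain, theta.sigma_inh, theta.frequency_hz,
        noise.i_noise,
        False, 0.0, 0.0,
        np.zeros(n_neurons, dtype=np.int64), np.zeros(1),
        1.0, 1.0, 1.0, kernel.WIN_PARTITION,
        False, 0.02, -0.01, 20.0, 50.0, 1.0, 0.0, 1.0,
        kernel.MOD_NONE, 1.0,
        np.empty(0, dtype=np.int64), 0.0, -1,
        False, sched_t, sched_id,
        drive_seed, max_spikes, snap_times,
    )
    if overflow:
        raise RuntimeError("spike buffer overflow in background run")
    return SimResult(
        spikes=_spike_frame(spike_t, spike_id),
        w_initial=w.copy(), w_final=w, snapshots=snaps,
        snapshot_times=snap_times, delays=delays, conn=conn,
        config={"kind": "background", "duration_ms": duration_ms,
                "n_neurons": n_neurons},
        seed=seed,
    )


def run_recall(
    weights: np.ndarray,
    delays: np.ndarray,
    conn: np.ndarray,
    proto: RecallProtocol,
    seed: int,
) -> SimResult:
    """One recall epoch on a (copy of a) learned weight matrix.

    Theta inhibition is off, the noise current stays on, the recurrent gain
    is 1/phi, and the cue pulse is applied at t = 0.  Plasticity remains
    active (scaled by phi) unless explicitly disabled.
    """
    n = weights.shape[0]
    cue = np.asarray(proto.cue_ids, dtype=np.int64)
    if cue.min() < 0 or cue.max() >= n:
        raise ValueError("cue ids out of range")
    w = weights.copy()
    rest = resting_state(proto.neuron)
    v0 = np.full(n, rest.v)
    u0 = np.full(n, rest.u)
    stdp = proto.stdp if proto.stdp is not None else get_rule("B")
    plast_on = proto.plasticity_on
    max_spikes = int(n * proto.duration_ms) + 1000  # recall can be dense
    sched_t, sched_id = _empty_sched()
    snap_times = np.array([proto.duration_ms - 1], dtype=np.int64)
    np_params = proto.neuron
    spike_t, spike_id, overflow, snaps, _, _ = kernel.simulate(
        proto.duration_ms, conn, delays, w,
        np_params.a, np_params.b, np_params.c, np_params.d, np_params.v_thresh,
        v0, u0,
        False, 0.0, 0.0, 8.0,
        proto.noise.i_noise,
        False, 0.0, 0.0,
        np.zeros(n, dtype=np.int64), np.zeros(1),
        1.0, 1.0, 1.0, kernel.WIN_PARTITION,
        plast_on,
        stdp.a_plus * stdp.w_max, stdp.a_minus * stdp.w_max,
        stdp.tau_plus, stdp.tau_minus,
        max(stdp.tau_plusplus, 1.0), stdp.eps, stdp.w_max,
        kernel.MOD_NONE, proto.phi,
        cue, proto.i_cue, 0,
        False, sched_t, sched_id,
        seed, max_spikes, snap_times,
    )
    if overflow:
        raise RuntimeError("spike buffer overflow in recall run")
    return SimResult(
        spikes=_spike_frame(spike_t, spike_id),
        w_initial=weights.copy(), w_final=w, snapshots=snaps,
        snapshot_times=snap_times, delays=delays, conn=conn,
        config={"kind": "recall", "phi": proto.phi, "i_cue": proto.i_cue,
                "cue_ids": list(map(int, proto.cue_ids)),
                "duration_ms": proto.duration_ms},
        seed=seed,
    )


def run_scripted(
    schedule: Sequence[tuple[int, int]],
    n_neurons: int,
    delays: np.ndarray,
    conn: np.ndarray,
    stdp: STDPConfig,
    duration_ms: int | None = None,
    w_initial: np.ndarray | None = None,
    modulation: str = "none",
    theta_on: bool = False,
    phi: float = 1.0,
    seed: int = 0,
) -> SimResult:
    """Force spikes at scheduled (time_ms, neuron_id) pairs, bypassing the
    membrane dynamics, and let plasticity process exactly those events.

    The scheduled times must be non-negative integers (1-ms grid).
    """
    sched = sorted((int(t), int(j)) for t, j in schedule)
    for t, j in sched:
        if t < 0 or not (0 <= j < n_neurons):
            raise ValueError("schedule entry out of range")
    for t, j in schedule:
        if float(t) != int(t):
            raise ValueError("schedule must be on the 1-ms grid")
    if duration_ms is None:
        duration_ms = (sched[-1][0] + int(delays.max()) + 1) if sched else 1
    sched_t = np.array([t for t, _ in sched], dtype=np.int64)
    sched_id = np.array([j for _, j in sched], dtype=np.int64)
    if w_initial is None:
        w = np.where(conn, stdp.w_init, 0.0)
    else:
        w = w_initial.copy()
    w_init_copy = w.copy()
    v0 = np.zeros(n_neurons)
    u0 = np.zeros(n_neurons)
    snap_times = np.array([duration_ms - 1], dtype=np.int64)
    spike_t, spike_id, overflow, snaps, _, _ = kernel.simulate(
        duration_ms, conn, delays.astype(np.int64), w,
        0.02, 0.2, -65.0, 6.0, 30.0,
        v0, u0,
        theta_on, 0.0, 0.0, 8.0,
        0.0,
        False, 0.0, 0.0,
        np.zeros(n_neurons, dtype=np.int64), np.zeros(1),
        1.0, 1.0, 1.0, kernel.WIN_PARTITION,
        True,
        stdp.a_plus * stdp.w_max, stdp.a_minus * stdp.w_max,
        stdp.tau_plus, stdp.tau_minus,
        max(stdp.tau_plusplus, 1.0), stdp.eps, stdp.w_max,
        _MOD_CODE[modulation], phi,
        np.empty(0, dtype=np.int64), 0.0, -1,
        True, sched_t, sched_id,
        seed, len(sched) + 1, snap_times,
    )
    return SimResult(
        spikes=_spike_frame(spike_t, spike_id),
        w_initial=w_init_copy, w_final=w, snapshots=snaps,
        snapshot_times=snap_times, delays=delays, conn=conn,
        config={"kind": "scripted", "n_events": len(sched)},
        seed=seed,
    )
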