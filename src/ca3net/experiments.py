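"""End-to-end experiment routines: learning followed by recall epochs, with
the summary statistics reported by the measurement battery.

These functions compose the protocol, drive and analysis layers into the
standard study conditions (the three presets and the background/drive
diagnostics) and return plain scalars, so that figure reproduction and
result regeneration are single calls.  All randomness is derived from the
``seed`` argument.
"""

from __future__ import annotations

import numpy as np

from . import analysis, protocols
from .drive import PlaceMap
from .neuron import minimal_firing_pulse

__all__ = [
    "excitability_threshold",
    "single_cell_infield_rate",
    "background_rate",
    "hetero_experiment",
    "auto_experiment",
    "dual_experiment",
    "hetero_sigma_trend",
]


def _subseeds(seed: int, n: int) -> list[int]:
    return [int(s) for s in np.random.SeedSequence(seed).generate_state(n) >> 1]


def excitability_threshold(resolution: float = 0.1) -> float:
    """Minimal single 1-ms current pulse that fires a resting neuron."""
    return minimal_firing_pulse(resolution=resolution)


def single_cell_infield_rate(seed: int, n_traversals: int = 20) -> float:
    """Mean in-field firing rate (Hz) of one place cell under default drive.

    The cell sits on a 160-cm route with one 80-cm field, so each lap holds
    8 s inside the field (one second per segment) and 8 s outside.
    """
    proto = protocols.single_cell_protocol(n_laps=n_traversals)
    res = protocols.run_learning(proto, seed=seed)
    route = proto.route
    t = res.spikes.time_ms.to_numpy()
    pos = (route.speed_cm_s * t / 1000.0) % route.length_cm
    n_infield = int((pos < route.diameter_cm).sum())
    infield_time_s = n_traversals * route.diameter_cm / route.speed_cm_s
    return n_infield / infield_time_s


def background_rate(seed: int, duration_s: float = 2000.0, n_neurons: int = 100) -> float:
    """Spontaneous firing rate (Hz per neuron) under theta inhibition and
    noise alone, with weights held at their initial value."""
    res = protocols.run_background(int(duration_s * 1000), seed=seed,
                                   n_neurons=n_neurons)
    return len(res.spikes) / (n_neurons * duration_s)


def _recall_epochs(learned, proto_factory, cue_factory, n_epochs, seed):
    """Run recall epochs from a learned result; yields (epoch raster, cue)."""
    rng = np.random.default_rng(seed)
    epoch_seeds = _subseeds(seed, n_epochs)
    for ep in range(n_epochs):
        cue = cue_factory(rng)
        proto = proto_factory(cue)
        yield protocols.run_recall(
            learned.w_final, learned.delays, learned.conn, proto,
            seed=epoch_seeds[ep],
        ), cue


def hetero_experiment(
    seed: int,
    rule: str = "B",
    modulation: str = "none",
    n_laps: int = 10,
    n_epochs: int = 100,
    phi: float = 0.05,
    duration_ms: int = 600,
) -> dict:
    """Hetero-associative learning followed by single-neuron-cue recall.

    Returns the mean percentage of neurons whose first spike is not
    classified erroneous, the mean sequential-sweep duration (cue to last
    first-spike over all neurons), the mean effective recall speed on the
    10-m route, and the learned foreground/background weight means.
    """
    learn_seed, recall_seed = _subseeds(seed, 2)
    proto = protocols.hetero_protocol(rule=rule, modulation=modulation,
                                      n_laps=n_laps)
    learned = protocols.run_learning(proto, seed=learn_seed,
                                     record_spikes=False)
    pm = PlaceMap.from_route(proto.route)
    ws = analysis.weight_summary(learned.w_final, pm, "hetero")
    n = proto.n_neurons

    def proto_factory(cue):
        return protocols.RecallProtocol(cue_ids=cue, phi=phi,
                                        duration_ms=duration_ms,
                                        stdp=proto.stdp)

    fid, sweeps, speeds = [], [], []
    for res, cue in _recall_epochs(
        learned, proto_factory,
        lambda rng: (int(rng.integers(n)),), n_epochs, recall_seed,
    ):
        rep = analysis.classify_sequence_recall(res.spikes, pm)
        fid.append(100.0 * rep.fraction_non_erroneous)
        first = res.spikes.groupby("neuron_id").time_ms.min()
        if len(first) == n:
            sweeps.append(float(first.max()))
        sp = analysis.effective_speed(res.spikes, proto.route, pm,
                                      cue_field=int(pm.field_of[cue[0]]))
        if sp is not None:
            speeds.append(sp)
    return {
        "fidelity_pct": float(np.mean(fid)) if fid else float("nan"),
        "sweep_ms": float(np.mean(sweeps)) if sweeps else float("nan"),
        "speed_m_s": float(np.mean(speeds)) if speeds else float("nan"),
        "n_complete": len(sweeps),
        "foreground_mean": ws.foreground_mean,
        "background_mean": ws.background_mean,
        "p_value": ws.p_value,
    }


def auto_experiment(
    seed: int,
    rule: str = "B",
    modulation: str = "theta",
    phi: float = 0.083,
    n_epochs: int = 100,
    n_weight_seeds: int = 5,
    n_laps: int = 10,
    window_ms: int = 20,
) -> dict:
    """Auto-associative learning followed by 5-of-10 partial-cue recall.

    Reports the mean percentage of uncued same-pattern cells completing
    within the observation window, the total off-pattern spike count in
    that window, and the within-pattern weight (fraction of w_max) averaged
    over ``n_weight_seeds`` independent learning runs.
    """
    seeds = _subseeds(seed, n_weight_seeds + 1)
    recall_seed, learn_seeds = seeds[0], seeds[1:]
    proto = protocols.auto_protocol(rule=rule, modulation=modulation,
                                    n_laps=n_laps)
    pm = PlaceMap.from_route(proto.route)
    within_fracs = []
    learned = None
    for ls in learn_seeds:
        res = protocols.run_learning(proto, seed=ls, record_spikes=False)
        ws = analysis.weight_summary(res.w_final, pm, "auto")
        within_fracs.append(ws.foreground_mean / proto.stdp.w_max)
        if learned is None:
            learned = res

    n_fields = proto.route.n_fields
    cpf = proto.route.cells_per_field

    def cue_factory(rng):
        fidx = int(rng.integers(n_fields))
        cells = pm.cells_of_field(fidx)
        return tuple(int(c) for c in rng.choice(cells, cpf // 2, replace=False))

    def proto_factory(cue):
        return protocols.RecallProtocol(cue_ids=cue, phi=phi,
                                        duration_ms=max(100, window_ms + 30),
                                        stdp=proto.stdp)

    completion, errors = [], 0
    for res, cue in _recall_epochs(learned, proto_factory, cue_factory,
                                   n_epochs, recall_seed):
        pattern = set(int(c) for c in
                      pm.cells_of_field(int(pm.field_of[cue[0]])))
        rep = analysis.classify_pattern_completion(
            res.spikes, set(cue), pattern, window_ms=window_ms)
        completion.append(100.0 * rep.accurate_fraction)
        errors += rep.erroneous_count
    return {
        "completion_pct": float(np.mean(completion)) if completion else float("nan"),
        "erroneous_spikes": int(errors),
        "within_weight_frac": float(np.mean(within_fracs)),
        "within_weight_sd": float(np.std(within_fracs)),
    }


def dual_experiment(
    seed: int,
    rule: str = "B",
    modulation: str = "theta",
    phi: float = 0.111,
    n_epochs: int = 20,
    n_laps: int = 10,
    duration_ms: int = 150,
) -> dict:
    """Dual-coded learning followed by 3-of-5 partial-cue recall.

    Reports the mean sweep duration (cue to last first-spike), the mean
    effective recall speed on the 2-m route, and the fidelity fractions.
    """
    learn_seed, recall_seed = _subseeds(seed, 2)
    proto = protocols.dual_protocol(rule=rule, modulation=modulation,
                                    n_laps=n_laps)
    learned = protocols.run_learning(proto, seed=learn_seed,
                                     record_spikes=False)
    pm = PlaceMap.from_route(proto.route)
    n_fields = proto.route.n_fields

    def cue_factory(rng):
        fidx = int(rng.integers(n_fields))
        cells = pm.cells_of_field(fidx)
        return tuple(int(c) for c in rng.choice(cells, 3, replace=False))

    def proto_factory(cue):
        return protocols.RecallProtocol(cue_ids=cue, phi=phi,
                                        duration_ms=duration_ms,
                                        stdp=proto.stdp)

    sweeps, speeds, fid = [], [], []
    n = proto.n_neurons
    for res, cue in _recall_epochs(learned, proto_factory, cue_factory,
                                   n_epochs, recall_seed):
        first = res.spikes.groupby("neuron_id").time_ms.min()
        if len(first) == n:
            sweeps.append(float(first.max()))
        sp = analysis.effective_speed(res.spikes, proto.route, pm,
                                      cue_field=int(pm.field_of[cue[0]]))
        if sp is not None:
            speeds.append(sp)
        fid.append(100.0 * analysis.classify_sequence_recall(
            res.spikes, pm).fraction_non_erroneous)
    return {
        "sweep_ms": float(np.mean(sweeps)) if sweeps else float("nan"),
        "speed_m_s": float(np.mean(speeds)) if speeds else float("nan"),
        "fidelity_pct": float(np.mean(fid)) if fid else float("nan"),
        "n_complete": len(sweeps),
    }


def hetero_sigma_trend(
    seed: int,
    sigmas: tuple[float, ...] = (12.5, 22.5, 32.5, 42.5, 52.5),
    n_laps: int = 1,
    rule: str = "B",
) -> dict:
    """Mean forward-neighbour weight after a fixed (short) exposure, as a
    function of the external-drive spread sigma_ext.

    Since sigma_ext controls the in-field firing rate, the weight reached
    before saturation tracks the rate of synaptic weight change.
    """
    from .drive import DriveConfig

    out = {}
    seeds = _subseeds(seed, len(sigmas))
    for s, sub in zip(sigmas, seeds):
        proto = protocols.hetero_protocol(
            rule=rule, n_laps=n_laps, drive=DriveConfig(i_ext=5.0, sigma_ext=s))
        res = protocols.run_learning(proto, seed=sub, record_spikes=False)
        n = proto.n_neurons
        f = np.arange(n)
        ahead = (f[None, :] - f[:, None]) % n
        out[s] = float(res.w_final[ahead == 1].mean())
    return out
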