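"""Measurement battery: weight-structure summaries, recall-fidelity
classifiers, place-field expansion curves, effective recall speed, and the
stochastic-rate (BCM) response diagnostic.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .drive import PlaceMap, RouteConfig, ThetaConfig
from .plasticity import STDPConfig, SynapseState, process_spike_event

__all__ = [
    "WeightSummary",
    "FidelityReport",
    "ExpansionCurve",
    "foreground_mask",
    "weight_summary",
    "classify_sequence_recall",
    "classify_pattern_completion",
    "expansion_curve",
    "effective_speed",
    "rate_response_curve",
]


@dataclass(frozen=True)
class WeightSummary:
    foreground_mean: float
    background_mean: float
    foreground: np.ndarray
    background: np.ndarray
    u_statistic: float
    p_value: float


@dataclass(frozen=True)
class FidelityReport:
    """Recall-fidelity counts.

    For sequence paradigms, per-neuron first spikes are classified against
    the first spike in any cell of the *next* field: ``before`` (accurate),
    ``same_time`` (indifferent), ``after`` (erroneous — includes silence).
    For pattern completion, ``accurate_fraction`` is the fraction of uncued
    same-pattern cells firing inside the observation window and
    ``erroneous_count`` the number of spikes by off-pattern cells in it.
    """

    before: int = 0
    same_time: int = 0
    after: int = 0
    accurate_fraction: float = float("nan")
    erroneous_count: int = 0

    @property
    def n_classified(self) -> int:
        return self.before + self.same_time + self.after

    @property
    def fraction_before(self) -> float:
        return self.before / self.n_classified

    @property
    def fraction_same(self) -> float:
        return self.same_time / self.n_classified

    @property
    def fraction_after(self) -> float:
        return self.after / self.n_classified

    @property
    def fraction_non_erroneous(self) -> float:
        return 1.0 - self.fraction_after


@dataclass(frozen=True)
class ExpansionCurve:
    """Per-lap circular-mean firing phase at field entry and exit."""

    entry_phase: np.ndarray  # radians in [0, 2*pi); NaN where no spikes
    exit_phase: np.ndarray


def foreground_mask(
    place_map: PlaceMap, paradigm: str, n_ahead: int = 3
) -> np.ndarray:
    """Boolean (pre, post) mask of the paradigm's foreground synapses.

    Sequence paradigms ('hetero', 'dual') take synapses onto cells of the
    1..n_ahead next fields on the route as foreground; associative paradigms
    ('auto', 'dual') add same-field synapses.  Self-connections are excluded
    everywhere.
    """
    if paradigm not in ("hetero", "auto", "dual"):
        raise ValueError(f"unknown paradigm {paradigm!r}")
    f = np.asarray(place_map.field_of)
    n_fields = place_map.n_fields
    ahead = (f[None, :] - f[:, None]) % n_fields
    mask = np.zeros((len(f), len(f)), dtype=bool)
    if paradigm in ("hetero", "dual"):
        mask |= (ahead >= 1) & (ahead <= n_ahead)
    if paradigm in ("auto", "dual"):
        mask |= ahead == 0
    np.fill_diagonal(mask, False)
    return mask


def weight_summary(
    w: np.ndarray, place_map: PlaceMap, paradigm: str, n_ahead: int = 3
) -> WeightSummary:
    """Foreground vs background weight means with a two-sided Mann-Whitney U.

    Uses the asymptotic normal approximation with tie correction (sample
    sizes here run to thousands of synapses).
    """
    fg_mask = foreground_mask(place_map, paradigm, n_ahead)
    offdiag = ~np.eye(w.shape[0], dtype=bool)
    bg_mask = offdiag & ~fg_mask
    if not fg_mask.any() or not bg_mask.any():
        raise ValueError("foreground/background partition is degenerate")
    fg = w[fg_mask]
    bg = w[bg_mask]
    if np.ptp(np.concatenate([fg, bg])) == 0.0:
        # all weights tied: no evidence of separation
        u, p = 0.5 * len(fg) * len(bg), 1.0
        return WeightSummary(float(fg.mean()), float(bg.mean()), fg, bg, u, p)
    res = stats.mannwhitneyu(fg, bg, alternative="two-sided", method="asymptotic")
    return WeightSummary(
        foreground_mean=float(fg.mean()),
        background_mean=float(bg.mean()),
        foreground=fg,
        background=bg,
        u_statistic=float(res.statistic),
        p_value=float(res.pvalue),
    )


def _first_spikes(raster: pd.DataFrame, n_cells: int) -> np.ndarray:
    """First spike time per cell; NaN for silent cells."""
    first = np.full(n_cells, np.nan)
    if len(raster):
        g = raster.groupby("neuron_id")["time_ms"].min()
        first[g.index.to_numpy()] = g.to_numpy()
    return first


def classify_sequence_recall(
    raster: pd.DataFrame,
    place_map: PlaceMap,
    exclude: set[int] | None = None,
    wrap: bool = True,
) -> FidelityReport:
    """First-spike ordering fidelity for sequence recall.

    Each cell's first spike is compared with the first spike in *any* cell
    of the next field on the route: earlier counts as before (accurate),
    equal (at the 1-ms grid) as same-time, later or absent as after
    (erroneous).  If the next field never fires, a cell that fired counts as
    before and a silent cell as after.  Cells in ``exclude`` (e.g. the cued
    cells themselves) are left out of the tally.

    With ``wrap=True`` (the default, matching the circular route) the last
    field's successor is field 0 — on a cued recall sweep the cells just
    behind the cued field are therefore necessarily classified erroneous.
    ``wrap=False`` leaves the last field without a successor.
    """
    n = place_map.n_cells
    n_fields = place_map.n_fields
    first = _first_spikes(raster, n)
    field_first = np.full(n_fields, np.inf)
    for fidx in range(n_fields):
        cells = place_map.cells_of_field(fidx)
        vals = first[cells]
        if np.isfinite(vals).any():
            field_first[fidx] = np.nanmin(vals)
    before = same = after = 0
    exclude = exclude or set()
    f = np.asarray(place_map.field_of)
    for cell in range(n):
        if cell in exclude:
            continue
        if not wrap and f[cell] == n_fields - 1:
            nxt = np.inf
        else:
            nxt = field_first[(f[cell] + 1) % n_fields]
        mine = first[cell]
        if math.isnan(mine):
            after += 1
        elif mine < nxt:
            before += 1
        elif mine == nxt:
            same += 1
        else:
            after += 1
    return FidelityReport(before=before, same_time=same, after=after)


def classify_pattern_completion(
    raster: pd.DataFrame,
    cued: set[int],
    pattern: set[int],
    window_ms: int = 20,
    cue_time: int = 0,
) -> FidelityReport:
    """Pattern-completion fidelity in a fixed window after the cue.

    Accurate recall = uncued cells of the cued pattern firing within
    ``window_ms`` of the cue; every spike by a cell outside the pattern in
    that window counts as erroneous.
    """
    if not cued <= pattern:
        raise ValueError("cue set must be a subset of the pattern")
    uncued = pattern - cued
    win = raster[
        (raster.time_ms >= cue_time) & (raster.time_ms <= cue_time + window_ms)
    ]
    fired = set(win.neuron_id.unique())
    n_acc = len(uncued & fired)
    err = int((~win.neuron_id.isin(list(pattern))).sum())
    return FidelityReport(
        accurate_fraction=n_acc / len(uncued) if uncued else float("nan"),
        erroneous_count=err,
    )


def _circular_mean(phases: np.ndarray) -> float:
    if len(phases) == 0:
        return float("nan")
    return float(stats.circmean(phases, high=2.0 * np.pi, low=0.0))


def expansion_curve(
    raster: pd.DataFrame,
    route: RouteConfig,
    place_map: PlaceMap,
    theta_cfg: ThetaConfig = ThetaConfig(),
) -> ExpansionCurve:
    """Per-lap mean theta phase of spikes in the entry and exit segments.

    Spikes are attributed to laps by time; a spike counts toward a cell's
    entry (exit) phase when the animal is in the first (last) of the eight
    segments of that cell's field.  The phase advance of the entry curve
    across laps is the signature of place-field expansion against the
    direction of motion.
    """
    n_laps = route.n_laps
    lap_ms = route.lap_time_ms
    entry = np.full(n_laps, np.nan)
    exit_ = np.full(n_laps, np.nan)
    if not len(raster):
        return ExpansionCurve(entry, exit_)
    t = raster.time_ms.to_numpy()
    cells = raster.neuron_id.to_numpy()
    f = np.asarray(place_map.field_of)[cells]
    pos = (route.speed_cm_s * t / 1000.0) % route.length_cm
    dist = (pos - f * route.offset_cm) % route.length_cm
    infield = dist < route.diameter_cm
    seg = np.floor(8.0 * dist / route.diameter_cm).astype(int)
    phase = (2.0 * np.pi * t / theta_cfg.period_ms) % (2.0 * np.pi)
    lap = np.minimum(t // lap_ms, n_laps - 1)
    for k in range(n_laps):
        in_lap = lap == k
        entry[k] = _circular_mean(phase[in_lap & infield & (seg == 0)])
        exit_[k] = _circular_mean(phase[in_lap & infield & (seg == 7)])
    return ExpansionCurve(entry, exit_)


def effective_speed(
    raster: pd.DataFrame,
    route: RouteConfig,
    place_map: PlaceMap,
    cue_field: int,
    cue_time: int = 0,
) -> float | None:
    """Effective propagation speed of a recall event, in m/s.

    Defined as route length divided by the interval between the first
    cue-evoked spike in the cued field and the first subsequent spike in
    that same field after the activity has propagated the full loop (i.e.
    after every other field has fired at least once).  Returns None if the
    activity never completes the loop.
    """
    if not len(raster):
        return None
    f = np.asarray(place_map.field_of)
    t = raster.time_ms.to_numpy()
    cells = raster.neuron_id.to_numpy()
    in_cue_field = f[cells] == cue_field
    cue_spikes = t[in_cue_field & (t >= cue_time)]
    if len(cue_spikes) == 0:
        return None
    t0 = cue_spikes.min()
    # loop completion: latest first-spike among the other fields
    t_loop = -np.inf
    for fidx in range(place_map.n_fields):
        if fidx == cue_field:
            continue
        ts = t[(f[cells] == fidx) & (t > t0)]
        if len(ts) == 0:
            return None
        t_loop = max(t_loop, ts.min())
    ret = t[in_cue_field & (t > t_loop)]
    if len(ret) == 0:
        return None
    dt_s = (ret.min() - t0) / 1000.0
    return (route.length_cm / 100.0) / dt_s


def rate_response_curve(
    cfg: STDPConfig,
    rates_hz: list[float],
    duration_s: float = 10.0,
    n_repeats: int = 20,
    delay_ms: int = 1,
    seed: int = 0,
) -> np.ndarray:
    """Mean weight drift (per second, at mid-range weight) under independent
    Poisson pre- and post-synaptic firing at equal rate.

    The diagnostic distinguishes BCM-compatible rules (drift turns positive
    as rate grows) from competitive rules (drift non-positive, decreasing).
    """
    rng = np.random.default_rng(seed)
    drifts = np.zeros(len(rates_hz))
    for ri, r in enumerate(rates_hz):
        if r == 0:
            drifts[ri] = 0.0
            continue
        acc = 0.0
        for _ in range(n_repeats):
            n_ms = int(duration_s * 1000)
            p = r / 1000.0
            pre = np.flatnonzero(rng.random(n_ms) < p) + delay_ms  # arrivals
            post = np.flatnonzero(rng.random(n_ms) < p)
            events = sorted(
                [(int(tt), "pre") for tt in pre] + [(int(tt), "post") for tt in post]
            )
            syn = SynapseState(w=0.5 * cfg.w_max)
            i = 0
            while i < len(events):
                tt, kind = events[i]
                if (
                    i + 1 < len(events)
                    and events[i + 1][0] == tt
                    and events[i + 1][1] != kind
                ):
                    process_spike_event(syn, "both", tt, cfg=cfg)
                    i += 2
                else:
                    process_spike_event(syn, kind, tt, cfg=cfg)
                    i += 1
            acc += (syn.w - 0.5 * cfg.w_max) / duration_s
        drifts[ri] = acc / n_repeats
    return drifts
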