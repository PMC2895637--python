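"""Shared fixtures: learned networks (session-scoped, reused across tests)
and the brute-force nearest-neighbour pairing oracle."""

from __future__ import annotations

import math

import numpy as np
import pytest

from ca3net import protocols
from ca3net.plasticity import STDPConfig


@pytest.fixture(scope="session")
def hetero_learned():
    """Full hetero-associative learning run (100 fields, 10 laps, rule B)."""
    proto = protocols.hetero_protocol(rule="B")
    return proto, protocols.run_learning(proto, seed=11, record_spikes=False)


@pytest.fixture(scope="session")
def auto_learned():
    """Auto-associative learning run (10 patterns, 10 laps, triplet rule)."""
    proto = protocols.auto_protocol(rule="B")
    return proto, protocols.run_learning(proto, seed=12, record_spikes=False)


@pytest.fixture(scope="session")
def dual_learned():
    """Dual-coded learning run (20 fields x 5 cells, 10 laps, triplet rule)."""
    proto = protocols.dual_protocol(rule="B")
    return proto, protocols.run_learning(proto, seed=13, record_spikes=False)


def nn_pairing_oracle(
    pre_spikes,
    post_spikes,
    d_pre: int,
    cfg: STDPConfig,
    w0: float,
) -> float:
    """Offline brute-force recomputation of the lax nearest-neighbour STDP
    weight trajectory for a single synapse.

    Enumerates all pairings directly from the spike lists — each presynaptic
    *arrival* (spike + axonal delay) against the most recent post spike at
    or before it, each post spike against the most recent strictly earlier
    arrival (skipped entirely if an arrival coincides with it) — then
    applies the resulting increments in time order with hard clipping and
    the depression trace for the triplet boost.  Independent of the
    event-driven simulation path.
    """
    arrivals = sorted(int(t) + d_pre for t in pre_spikes)
    posts = sorted(int(t) for t in post_spikes)
    arr_set = set(arrivals)
    increments = []  # (time, kind, lag)
    for a in arrivals:
        earlier_posts = [p for p in posts if p <= a]
        if earlier_posts:
            increments.append((a, "dep", max(earlier_posts) - a))
    for p in posts:
        if p in arr_set:
            continue  # coincident pair handled as pure depression
        earlier_arr = [a for a in arrivals if a < p]
        if earlier_arr:
            increments.append((p, "pot", p - max(earlier_arr)))
    increments.sort()
    w = w0
    dep_mag, dep_time = 0.0, None
    for t, kind, lag in increments:
        if kind == "dep":
            dw = cfg.a_minus * cfg.w_max * math.exp(lag / cfg.tau_minus)
            new_w = min(max(w + dw, 0.0), cfg.w_max)
            if w - new_w > 0:
                dep_mag, dep_time = w - new_w, t
            w = new_w
        else:
            dw = cfg.a_plus * cfg.w_max * math.exp(-lag / cfg.tau_plus)
            if cfg.eps > 0 and dep_time is not None:
                dw += cfg.eps * dep_mag * math.exp(-(t - dep_time) / cfg.tau_plusplus)
            w = min(max(w + dw, 0.0), cfg.w_max)
    return w


def scripted_two_neuron(pre_spikes, post_spikes, d_pre, cfg, d_post=1, w0=None):
    """Run the event-driven simulator on a scripted two-neuron train and
    return the final weight of the 0 -> 1 synapse."""
    schedule = [(t, 0) for t in pre_spikes] + [(t, 1) for t in post_spikes]
    conn = np.array([[False, True], [True, False]])
    delays = np.array([d_pre, d_post], dtype=np.int64)
    w_initial = None
    if w0 is not None:
        w_initial = np.where(conn, w0, 0.0)
    res = protocols.run_scripted(schedule, 2, delays, conn, cfg,
                                 w_initial=w_initial)
    return res.w_final[0, 1]
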