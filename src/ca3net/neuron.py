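"""Izhikevich point-neuron dynamics, axonal delays and recurrent connectivity.

The network consists of simple two-variable Izhikevich units.  The membrane
potential ``v`` and recovery variable ``u`` evolve under

    v' = 0.04 v^2 + 5 v + 140 - u + I
    u' = a (b v - u)

with a reset applied *before* the update in each 1-ms step: any unit whose
``v`` exceeds the spike threshold at the start of the step is flagged as
having fired, and reset to ``v <- c``, ``u <- u + d``.  ``v`` is advanced
with two 0.5-ms forward-Euler half-steps per millisecond and ``u`` with a
single 1-ms step, the scheme of the original Izhikevich reference
implementation.

Spikes emitted by neuron *i* at time ``t`` arrive at all of its postsynaptic
targets at ``t + D_i`` where ``D_i`` is an integer axonal delay drawn
uniformly from ``{1, ..., D}`` ms.
"""

from __future__ import annotations

import heapq
import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "NeuronParams",
    "NeuronState",
    "DEFAULT_PARAMS",
    "resting_state",
    "izhikevich_step",
    "minimal_firing_pulse",
    "draw_delays",
    "full_connectivity",
    "sparse_connectivity",
    "SpikeBuffer",
    "collect_synaptic_current",
]


@dataclass(frozen=True)
class NeuronParams:
    """Dimensionless Izhikevich constants for a regular-spiking pyramidal cell."""

    a: float = 0.02
    b: float = 0.2
    c: float = -65.0
    d: float = 6.0
    v_thresh: float = 30.0


DEFAULT_PARAMS = NeuronParams()


@dataclass(frozen=True)
class NeuronState:
    v: float
    u: float
    fired: bool = False


def resting_state(params: NeuronParams = DEFAULT_PARAMS) -> NeuronState:
    """Stable fixed point of the subthreshold dynamics at zero input.

    Solves ``0.04 v^2 + 5 v + 140 - u = 0`` with ``u = b v``; the lower root
    is the stable one (v = -70, u = -14 for the default parameters).
    """
    b = params.b
    # 0.04 v^2 + (5 - b) v + 140 = 0
    disc = (5.0 - b) ** 2 - 4.0 * 0.04 * 140.0
    if disc < 0:
        raise ValueError("no real resting potential for these parameters")
    v = (-(5.0 - b) - math.sqrt(disc)) / (2.0 * 0.04)
    return NeuronState(v=v, u=b * v, fired=False)


def izhikevich_step(
    state: NeuronState, params: NeuronParams, i_total: float
) -> NeuronState:
    """Advance one neuron by a single 1-ms step under input current ``i_total``.

    Reset-before-update ordering: a threshold crossing left over from the
    previous step is registered (``fired=True``) and reset first; the
    dynamics are then integrated for 1 ms.
    """
    if not math.isfinite(i_total):
        raise ValueError("non-finite input current")
    v, u = state.v, state.u
    fired = v >= params.v_thresh
    if fired:
        v = params.c
        u = u + params.d
    # two 0.5-ms half-steps for v, one full step for u
    v += 0.5 * (0.04 * v * v + 5.0 * v + 140.0 - u + i_total)
    v += 0.5 * (0.04 * v * v + 5.0 * v + 140.0 - u + i_total)
    u += params.a * (params.b * v - u)
    return NeuronState(v=v, u=u, fired=fired)


def minimal_firing_pulse(
    params: NeuronParams = DEFAULT_PARAMS,
    resolution: float = 0.1,
    lo: float = 0.0,
    hi: float = 40.0,
    horizon_ms: int = 20,
) -> float:
    """Smallest single 1-ms current pulse that fires a resting neuron.

    Scans pulse amplitudes on a grid of ``resolution``, integrating from the
    resting fixed point and asking whether a spike occurs within
    ``horizon_ms`` of the pulse.
    """
    rest = resting_state(params)

    def fires(amp: float) -> bool:
        s = rest
        for t in range(horizon_ms):
            s = izhikevich_step(s, params, amp if t == 0 else 0.0)
            if s.fired or s.v >= params.v_thresh:
                return True
        return False

    n = int(round((hi - lo) / resolution))
    for k in range(n + 1):
        amp = lo + k * resolution
        if fires(amp):
            return round(amp, 10)
    raise ValueError("no firing pulse found in scan range")


def draw_delays(
    n_neurons: int, d_max: int, rng: np.random.Generator
) -> np.ndarray:
    """Integer axonal delays, uniform on ``{1, ..., d_max}`` ms, one per neuron."""
    if d_max < 1:
        raise ValueError("d_max must be >= 1")
    return rng.integers(1, d_max + 1, size=n_neurons).astype(np.int64)


def full_connectivity(n_neurons: int) -> np.ndarray:
    """Boolean adjacency (pre -> post): all-to-all without self-connections."""
    conn = np.ones((n_neurons, n_neurons), dtype=bool)
    np.fill_diagonal(conn, False)
    return conn


def sparse_connectivity(
    n_neurons: int, n_inputs: int, rng: np.random.Generator
) -> np.ndarray:
    """Each postsynaptic neuron receives exactly ``n_inputs`` distinct
    presynaptic partners, drawn without replacement and excluding itself."""
    if not 1 <= n_inputs <= n_neurons - 1:
        raise ValueError("n_inputs must be in [1, n_neurons - 1]")
    conn = np.zeros((n_neurons, n_neurons), dtype=bool)
    for post in range(n_neurons):
        candidates = np.delete(np.arange(n_neurons), post)
        pres = rng.choice(candidates, size=n_inputs, replace=False)
        conn[pres, post] = True
    return conn


class SpikeBuffer:
    """Queue of pending spike deliveries ``(arrival_time_ms, presynaptic id)``.

    Each scheduled event is delivered exactly once, at the arrival time; an
    attempt to pop the buffer past an undelivered event signals a scheduling
    bug upstream.
    """

    def __init__(self) -> None:
        self._heap: list[tuple[int, int]] = []

    def __len__(self) -> int:
        return len(self._heap)

    def schedule(self, arrival_time: int, pre_id: int) -> None:
        heapq.heappush(self._heap, (int(arrival_time), int(pre_id)))

    def pop_due(self, t: int) -> list[int]:
        """Presynaptic ids of all events arriving exactly at time ``t``."""
        if self._heap and self._heap[0][0] < t:
            raise RuntimeError(
                f"undelivered spike event at t={self._heap[0][0]} < {t}"
            )
        due = []
        while self._heap and self._heap[0][0] == t:
            due.append(heapq.heappop(self._heap)[1])
        return due


def collect_synaptic_current(
    buffer: SpikeBuffer, t: int, weights: np.ndarray, phi: float
) -> np.ndarray:
    """Per-neuron recurrent current from spikes arriving at time ``t``.

    Each arrival on synapse i->j contributes ``w_ij / phi`` to neuron j for
    this one step (1-ms rectangular pulse model).  ``phi`` is the abstract
    cholinergic level: low acetylcholine disinhibits the recurrent collaterals,
    scaling every synaptic current up by ``1/phi``.
    """
    if not phi > 0:
        raise ValueError("phi must be > 0")
    current = np.zeros(weights.shape[1], dtype=float)
    for pre in buffer.pop_due(t):
        current += weights[pre] / phi
    return current
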