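"""Additive STDP with lax nearest-neighbour pairing and a triplet trace.

Three rules are implemented, addressable by their conventional labels:

    =====  =======================  ======  ========  =====  =====  ======  ===
    label  name                     A+      A-        tau+   tau-   tau++   eps
    =====  =======================  ======  ========  =====  =====  ======  ===
    A      pair-based BCM type       0.02   -0.01      20     50     --      0
    B      triplet-based BCM type    0.02   -0.01      20     50     20      1
    C      pair-based non-BCM type   0.02   -0.021     20     20     --      0
    =====  =======================  ======  ========  =====  =====  ======  ===

(A+/A- as fractions of w_max; time constants in ms.)

For an isolated pairing with lag ``s = t_post - t_pre_arrival`` (presynaptic
times are *arrival* times at the terminal, i.e. spike time plus axonal delay):

    s > 0:   dw = A+ * exp(-s / tau+)          (potentiation)
    s <= 0:  dw = A- * exp( s / tau-)          (depression)

so exactly coincident firing lands in the depression branch and elicits the
full A- — maximal depression, as measured in hippocampal slices.  The triplet
term adds, to each potentiation increment, ``eps * |last weight decrease at
the synapse| * exp(-s++ / tau++)`` where ``s++`` is the time since that
decrease; this captures the observed suppression of depression by closely
following potentiation in spike-triplet protocols.

Pairing is "lax nearest neighbour": each presynaptic arrival pairs only with
the most recent postsynaptic spike and each postsynaptic spike pairs only
with the most recent presynaptic arrival; the pairing traces are reset (not
accumulated) on every same-side event and are not consumed by use.

Every increment is further scaled by the theta-modulation factor of the
active scheme and by the cholinergic level Phi, and the weight is clipped to
[0, w_max] after every update (hard bounds).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

__all__ = [
    "STDPConfig",
    "RULES",
    "get_rule",
    "SynapseState",
    "pair_delta",
    "triplet_boost",
    "modulate",
    "modulation_factors",
    "process_spike_event",
    "MOD_SCHEMES",
]

# Times earlier than this sentinel mean "no event yet".
_NO_EVENT = -1e9

MOD_SCHEMES = ("none", "theta", "inverse")


@dataclass(frozen=True)
class STDPConfig:
    """Constants of one additive STDP rule (amplitudes as fractions of w_max)."""

    rule_id: str
    a_plus: float
    a_minus: float  # negative
    tau_plus: float
    tau_minus: float
    tau_plusplus: float = 0.0  # triplet trace time constant; unused if eps == 0
    eps: float = 0.0
    w_max: float = 1.0
    w_init_frac: float = 0.01

    def __post_init__(self):
        if not (self.a_plus > 0 > self.a_minus):
            raise ValueError("require a_plus > 0 > a_minus")
        if self.eps < 0:
            raise ValueError("eps must be >= 0")

    @property
    def w_init(self) -> float:
        return self.w_init_frac * self.w_max


RULES: dict[str, STDPConfig] = {
    "A": STDPConfig("A", 0.02, -0.01, 20.0, 50.0),
    "B": STDPConfig("B", 0.02, -0.01, 20.0, 50.0, tau_plusplus=20.0, eps=1.0),
    "C": STDPConfig("C", 0.02, -0.021, 20.0, 20.0),
}


def get_rule(rule_id: str, w_max: float = 1.0, **overrides) -> STDPConfig:
    """Rule by Table label ('A'/'B'/'C'), optionally rescaled/overridden."""
    try:
        base = RULES[rule_id]
    except KeyError:
        raise ValueError(f"unknown STDP rule {rule_id!r}; expected one of A, B, C")
    return replace(base, w_max=w_max, **overrides)


@dataclass
class SynapseState:
    """Weight plus the pairing traces of one synapse.

    ``t_pre_last`` is the last presynaptic *arrival* time; ``dep_mag`` /
    ``dep_time`` record the magnitude and time of the most recent realised
    weight decrease (the triplet trace).
    """

    w: float
    t_pre_last: float = _NO_EVENT
    t_post_last: float = _NO_EVENT
    dep_mag: float = 0.0
    dep_time: float = _NO_EVENT
    _t_last_event: float = _NO_EVENT


def pair_delta(s: float, cfg: STDPConfig) -> float:
    """Unmodulated weight change for one isolated pairing at lag ``s`` ms.

    Positive lags (post after pre arrival) potentiate, non-positive lags
    depress, with s = 0 giving the full A- (maximal depression).  Returned in
    units of w_max times the configured fractions, i.e. already scaled by
    cfg amplitudes which are fractions of w_max.
    """
    if not math.isfinite(s):
        raise ValueError("non-finite pairing lag")
    if s > 0:
        return cfg.a_plus * cfg.w_max * math.exp(-s / cfg.tau_plus)
    return cfg.a_minus * cfg.w_max * math.exp(s / cfg.tau_minus)


def triplet_boost(
    dep_mag: float, dep_time: float, t_pot: float, cfg: STDPConfig
) -> float:
    """Extra potentiation from the trace of the most recent weight decrease."""
    if cfg.eps == 0.0 or dep_time <= _NO_EVENT or dep_mag == 0.0:
        return 0.0
    s_pp = t_pot - dep_time
    if s_pp < 0:
        raise ValueError("potentiation before the recorded depression")
    return cfg.eps * dep_mag * math.exp(-s_pp / cfg.tau_plusplus)


def modulation_factors(theta: float, scheme: str) -> tuple[float, float]:
    """(m_plus, m_minus) multipliers on potentiation/depression increments.

    'theta':    potentiation full and depression suppressed where inhibition
                (and theta) is minimal, i.e. where in-field bursting
                concentrates — m+ = 1 - theta, m- = theta.
    'inverse':  the roles swapped (m+ = theta, m- = 1 - theta).
    'none':     identity.
    """
    if not 0.0 <= theta <= 1.0:
        raise ValueError("theta must lie in [0, 1]")
    if scheme == "none":
        return 1.0, 1.0
    if scheme == "theta":
        return 1.0 - theta, theta
    if scheme == "inverse":
        return theta, 1.0 - theta
    raise ValueError(f"unknown modulation scheme {scheme!r}")


def modulate(dw: float, theta: float, scheme: str) -> float:
    """Apply the scheme's multiplier to a raw increment (sign selects m+/m-)."""
    m_plus, m_minus = modulation_factors(theta, scheme)
    return dw * (m_plus if dw > 0 else m_minus)


def _apply_depression(
    syn: SynapseState, s: float, t: float, m_minus: float, phi: float, cfg: STDPConfig
) -> None:
    dw = pair_delta(s, cfg) * m_minus * phi
    new_w = min(max(syn.w + dw, 0.0), cfg.w_max)
    decrease = syn.w - new_w
    if decrease > 0.0:
        syn.dep_mag = decrease
        syn.dep_time = t
    syn.w = new_w


def process_spike_event(
    syn: SynapseState,
    kind: str,
    t: float,
    theta: float = 0.0,
    scheme: str = "none",
    phi: float = 1.0,
    cfg: STDPConfig = RULES["A"],
) -> SynapseState:
    """Feed one event through the lax nearest-neighbour pairing machinery.

    ``kind`` is ``'pre'`` (presynaptic arrival), ``'post'`` (postsynaptic
    spike), or ``'both'`` for a pre arrival and post spike falling in the
    same millisecond, which must be submitted as a single combined event.

    Events must be supplied in non-decreasing time order.  A presynaptic
    arrival pairs with the most recent post spike (depression); a post spike
    pairs with the most recent pre arrival, yielding potentiation plus the
    triplet boost only at strictly positive lag — so a coincident pair
    ('both') elicits exactly one depression at full A- and no potentiation.
    Increments are scaled by the modulation factor and by phi, and the weight
    is clipped to [0, w_max].
    """
    if t < syn._t_last_event:
        raise ValueError("events must be processed in time order")
    if kind not in ("pre", "post", "both"):
        raise ValueError("event kind must be 'pre', 'post' or 'both'")
    m_plus, m_minus = modulation_factors(theta, scheme)
    if kind == "both":
        syn.t_pre_last = t
        syn.t_post_last = t
        _apply_depression(syn, 0.0, t, m_minus, phi, cfg)
    elif kind == "pre":
        syn.t_pre_last = t
        if syn.t_post_last > _NO_EVENT:
            _apply_depression(syn, syn.t_post_last - t, t, m_minus, phi, cfg)
    else:
        if syn.t_pre_last > _NO_EVENT:
            s = t - syn.t_pre_last
            if s > 0:
                dw = pair_delta(s, cfg) + triplet_boost(
                    syn.dep_mag, syn.dep_time, t, cfg
                )
                dw *= m_plus * phi
                syn.w = min(max(syn.w + dw, 0.0), cfg.w_max)
        syn.t_post_last = t
    syn._t_last_event = t
    return syn
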