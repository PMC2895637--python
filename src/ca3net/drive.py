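"""Theta-coded external input: oscillatory inhibition, noise, and the
phenomenological phase-precession drive.

A global theta variable oscillates sinusoidally in [0, 1] at 8 Hz.  Under the
phase convention used here,

    phi(t) = 2*pi*f*t  (mod 2*pi),     theta(t) = (1 + cos(phi)) / 2,

inhibition (Gaussian, mean ``-15*theta``, s.d. 2) is weakest at mid-cycle
(phi = pi), which is where noise-driven firing and in-field bursting
concentrate — the "peak of the LFP" in the firing sense.

Place fields lie on a circular route traversed at constant speed.  Each field
is divided into eight equal segments; each segment maps to a theta phase
window, in reverse order: a cell receives its excitatory drive late in the
cycle when the animal enters the field and progressively earlier as the field
is traversed (phase precession).  While inside its window, an eligible cell
draws an independent Normal(I_ext, sigma_ext) current every millisecond;
sigma_ext is large relative to I_ext and draws are deliberately unclipped, so
firing is driven by stochastic threshold crossings.

Three readings of the phase-window geometry are provided.  The default,
``'partition'``, divides the full theta cycle into eight pi/4-wide windows
whose centres run from pi/8 (earliest) to 15*pi/8 (latest) — this uses both
printed quantities, the pi/4 window width and the pi/8..15*pi/8 phase range,
exactly.  ``'span8'`` instead squeezes eight equal windows (width 7*pi/32)
inside the interval [pi/8, 15*pi/8]; ``'span7'`` places seven pi/4 windows
in that interval, the last two field segments sharing the earliest window.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "ThetaConfig",
    "NoiseConfig",
    "DriveConfig",
    "RouteConfig",
    "PlaceMap",
    "PHASE_SPAN",
    "theta_value",
    "sample_background",
    "field_position",
    "segment_to_window",
    "external_drive",
]

# Theta phase span covered by the stimulation windows ('span' readings);
# under the default 'partition' reading these are the extreme window centres.
PHASE_SPAN = (math.pi / 8.0, 15.0 * math.pi / 8.0)

WINDOW_MODES = ("partition", "span8", "span7")


@dataclass(frozen=True)
class ThetaConfig:
    """8-Hz theta inhibition: I_inh ~ Normal(-gain * theta, sigma)."""

    frequency_hz: float = 8.0
    inhibition_gain: float = 15.0
    sigma_inh: float = 2.0

    @property
    def period_ms(self) -> float:
        return 1000.0 / self.frequency_hz


@dataclass(frozen=True)
class NoiseConfig:
    """Constant excitatory noise, uniform on [0, i_noise] per neuron per ms."""

    i_noise: float = 0.8


@dataclass(frozen=True)
class DriveConfig:
    """In-window place-field excitation, Normal(i_ext, sigma_ext) per ms."""

    i_ext: float = 5.0
    sigma_ext: float = 22.5


@dataclass(frozen=True)
class RouteConfig:
    """Circular route of equidistant place fields traversed at constant speed.

    Fields of ``diameter_cm`` are placed every ``offset_cm``; the total route
    length is ``n_fields * offset_cm`` and fields overlap whenever the offset
    is smaller than the diameter.
    """

    n_fields: int
    offset_cm: float
    cells_per_field: int = 1
    diameter_cm: float = 80.0
    speed_cm_s: float = 10.0
    n_laps: int = 10

    def __post_init__(self):
        if self.n_fields < 1 or self.cells_per_field < 1:
            raise ValueError("n_fields and cells_per_field must be >= 1")
        if self.offset_cm <= 0 or self.diameter_cm <= 0 or self.speed_cm_s <= 0:
            raise ValueError("offset, diameter and speed must be positive")

    @property
    def length_cm(self) -> float:
        return self.n_fields * self.offset_cm

    @property
    def n_cells(self) -> int:
        return self.n_fields * self.cells_per_field

    @property
    def lap_time_ms(self) -> int:
        return int(round(1000.0 * self.length_cm / self.speed_cm_s))

    def field_start_cm(self, field_index: int) -> float:
        return (field_index % self.n_fields) * self.offset_cm

    def position_cm(self, t_ms: float) -> float:
        return (self.speed_cm_s * t_ms / 1000.0) % self.length_cm


@dataclass(frozen=True)
class PlaceMap:
    """Assignment of cells to place fields: cell k encodes field k // cells_per_field."""

    field_of: np.ndarray  # int array, len n_cells

    @classmethod
    def from_route(cls, route: RouteConfig) -> "PlaceMap":
        return cls(np.repeat(np.arange(route.n_fields), route.cells_per_field))

    @property
    def n_cells(self) -> int:
        return len(self.field_of)

    @property
    def n_fields(self) -> int:
        return int(self.field_of.max()) + 1

    def cells_of_field(self, f: int) -> np.ndarray:
        return np.flatnonzero(self.field_of == f)


def theta_value(t_ms: float, cfg: ThetaConfig = ThetaConfig()) -> tuple[float, float]:
    """Theta amplitude in [0, 1] and phase in [0, 2*pi) at time ``t_ms``."""
    if t_ms < 0:
        raise ValueError("t_ms must be >= 0")
    phase = (2.0 * math.pi * t_ms / cfg.period_ms) % (2.0 * math.pi)
    theta = 0.5 * (1.0 + math.cos(phase))
    return theta, phase


def sample_background(
    theta: float,
    rng: np.random.Generator,
    n_neurons: int,
    theta_cfg: ThetaConfig = ThetaConfig(),
    noise_cfg: NoiseConfig = NoiseConfig(),
) -> np.ndarray:
    """Inhibitory + noise current, drawn independently per neuron for one ms."""
    inh = rng.normal(-theta_cfg.inhibition_gain * theta, theta_cfg.sigma_inh, n_neurons)
    noise = rng.uniform(0.0, noise_cfg.i_noise, n_neurons)
    return inh + noise


def field_position(
    t_ms: float, route: RouteConfig, field_index: int
) -> float | None:
    """Fraction in [0, 1) of ``field_index``'s diameter traversed at time t,
    or None if the animal is outside that field (circular distance)."""
    pos = route.position_cm(t_ms)
    dist = (pos - route.field_start_cm(field_index)) % route.length_cm
    if dist >= route.diameter_cm:
        return None
    return dist / route.diameter_cm


def segment_to_window(
    fraction: float, window_mode: str = "partition"
) -> tuple[float, float]:
    """Theta phase window (lo, hi) stimulated at a given within-field fraction.

    The field is divided into eight equal segments; segment ordering is
    reversed in phase, so the entry segment maps to the latest window and the
    exit segment to the earliest (phase precession).  See the module
    docstring for the three ``window_mode`` readings.
    """
    if not 0.0 <= fraction < 1.0:
        raise ValueError("fraction must be in [0, 1)")
    if window_mode not in WINDOW_MODES:
        raise ValueError(f"window_mode must be one of {WINDOW_MODES}")
    lo_span, hi_span = PHASE_SPAN
    segment = int(8.0 * fraction)  # 0..7
    if window_mode == "partition":
        width = math.pi / 4.0
        hi = 2.0 * math.pi - segment * width
    elif window_mode == "span8":
        width = (hi_span - lo_span) / 8.0
        hi = hi_span - segment * width
    else:  # span7
        width = math.pi / 4.0
        hi = hi_span - min(segment, 6) * width
    return hi - width, hi


def external_drive(
    t_ms: float,
    route: RouteConfig,
    place_map: PlaceMap,
    drive: DriveConfig,
    rng: np.random.Generator,
    theta_cfg: ThetaConfig = ThetaConfig(),
    window_mode: str = "partition",
) -> np.ndarray:
    """Per-cell external excitation for one 1-ms step.

    A cell is eligible when the current position lies inside its field and the
    current theta phase lies inside the window scheduled for its field segment;
    eligible cells draw independent Normal(i_ext, sigma_ext) currents, all
    others receive zero.
    """
    _, phase = theta_value(t_ms, theta_cfg)
    current = np.zeros(place_map.n_cells)
    for cell in range(place_map.n_cells):
        frac = field_position(t_ms, route, int(place_map.field_of[cell]))
        if frac is None:
            continue
        lo, hi = segment_to_window(frac, window_mode)
        if lo <= phase < hi:
            current[cell] = rng.normal(drive.i_ext, drive.sigma_ext)
    return current
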