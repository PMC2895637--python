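"""Run configuration: YAML round-trip with strict validation.

An empty file (or empty mapping) yields the full default configuration —
100 neurons, 8-Hz theta, w_max = 1, weights initialised at 0.01 w_max.
Unknown keys are rejected by name.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .drive import WINDOW_MODES
from .plasticity import MOD_SCHEMES, RULES

__all__ = ["RecallSettings", "SeedBlock", "RunConfig", "load_config", "save_config"]

_PARADIGM_GEOMETRY = {
    # paradigm: (n_fields, offset_cm, cells_per_field, default cue size)
    "hetero": (100, 10.0, 1, 1),
    "auto": (10, 80.0, 10, 5),
    "dual": (20, 10.0, 5, 3),
}


@dataclass
class RecallSettings:
    phi: float = 0.05
    i_cue: float = 30.0
    duration_ms: int = 600
    cue_size: int = 1
    plasticity_on: bool = True

    def validate(self) -> None:
        if not self.phi > 0:
            raise ValueError("recall.phi must be > 0")
        if self.duration_ms < 1 or self.cue_size < 1:
            raise ValueError("recall.duration_ms and recall.cue_size must be >= 1")


@dataclass
class SeedBlock:
    """Seeds split by concern so, e.g., topology can be held fixed while the
    drive noise varies."""

    topology: int = 1
    drive: int = 2
    cue: int = 3

    def validate(self) -> None:
        for name in ("topology", "drive", "cue"):
            v = getattr(self, name)
            if not isinstance(v, int) or v < 0:
                raise ValueError(f"seeds.{name} must be a non-negative integer")


@dataclass
class RunConfig:
    paradigm: str = "hetero"
    rule: str = "B"
    modulation: str = "none"
    n_fields: int | None = None          # None -> paradigm preset geometry
    offset_cm: float | None = None
    cells_per_field: int | None = None
    diameter_cm: float = 80.0
    speed_cm_s: float = 10.0
    n_laps: int = 10
    d_max: int = 5
    sparse: bool = False
    n_sparse_inputs: int = 15
    window_mode: str = "partition"
    theta_frequency_hz: float = 8.0
    inhibition_gain: float = 15.0
    sigma_inh: float = 2.0
    i_noise: float = 0.8
    i_ext: float = 5.0
    sigma_ext: float = 22.5
    w_max: float = 1.0
    w_init_frac: float = 0.01
    phi_learning: float = 1.0
    recall: RecallSettings = field(default_factory=RecallSettings)
    seeds: SeedBlock = field(default_factory=SeedBlock)

    def __post_init__(self):
        self.validate()

    def validate(self) -> None:
        if self.paradigm not in (*_PARADIGM_GEOMETRY, "custom", "single"):
            raise ValueError(f"unknown paradigm {self.paradigm!r}")
        if self.rule not in RULES:
            raise ValueError(f"unknown STDP rule {self.rule!r}")
        if self.modulation not in MOD_SCHEMES:
            raise ValueError(f"unknown modulation scheme {self.modulation!r}")
        if self.window_mode not in WINDOW_MODES:
            raise ValueError(f"unknown window_mode {self.window_mode!r}")
        if self.paradigm == "custom" and (
            self.n_fields is None or self.offset_cm is None
            or self.cells_per_field is None
        ):
            raise ValueError("custom paradigm requires n_fields, offset_cm "
                             "and cells_per_field")
        if not self.w_max > 0 or not 0 <= self.w_init_frac <= 1:
            raise ValueError("w_max must be > 0, w_init_frac in [0, 1]")
        self.recall.validate()
        self.seeds.validate()

    # -- resolved geometry ------------------------------------------------
    def geometry(self) -> tuple[int, float, int]:
        if self.paradigm in _PARADIGM_GEOMETRY:
            nf, off, cpf, _ = _PARADIGM_GEOMETRY[self.paradigm]
            return (
                self.n_fields if self.n_fields is not None else nf,
                self.offset_cm if self.offset_cm is not None else off,
                self.cells_per_field if self.cells_per_field is not None else cpf,
            )
        if self.paradigm == "single":
            return 1, 2 * self.diameter_cm, 1
        return self.n_fields, self.offset_cm, self.cells_per_field

    def default_cue_size(self) -> int:
        if self.paradigm in _PARADIGM_GEOMETRY:
            return _PARADIGM_GEOMETRY[self.paradigm][3]
        return 1

    def to_learning_protocol(self):
        from .drive import DriveConfig, NoiseConfig, RouteConfig, ThetaConfig
        from .plasticity import get_rule
        from .protocols import LearningProtocol

        nf, off, cpf = self.geometry()
        route = RouteConfig(
            n_fields=nf, offset_cm=off, cells_per_field=cpf,
            diameter_cm=self.diameter_cm, speed_cm_s=self.speed_cm_s,
            n_laps=self.n_laps,
        )
        return LearningProtocol(
            route=route,
            stdp=get_rule(self.rule, w_max=self.w_max,
                          w_init_frac=self.w_init_frac),
            modulation=self.modulation,
            theta=ThetaConfig(self.theta_frequency_hz, self.inhibition_gain,
                              self.sigma_inh),
            noise=NoiseConfig(self.i_noise),
            drive=DriveConfig(self.i_ext, self.sigma_ext),
            d_max=self.d_max, sparse=self.sparse,
            n_sparse_inputs=self.n_sparse_inputs,
            window_mode=self.window_mode, phi=self.phi_learning,
            paradigm=self.paradigm,
        )

    # -- serialization ----------------------------------------------------
    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, data: dict | None) -> "RunConfig":
        data = dict(data or {})
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        if "recall" in data and data["recall"] is not None:
            sub = data["recall"]
            sub_known = {f.name for f in dataclasses.fields(RecallSettings)}
            bad = set(sub) - sub_known
            if bad:
                raise ValueError(f"unknown config key(s): recall.{sorted(bad)}")
            data["recall"] = RecallSettings(**sub)
        if "seeds" in data and data["seeds"] is not None:
            sub = data["seeds"]
            sub_known = {f.name for f in dataclasses.fields(SeedBlock)}
            bad = set(sub) - sub_known
            if bad:
                raise ValueError(f"unknown config key(s): seeds.{sorted(bad)}")
            data["seeds"] = SeedBlock(**sub)
        return cls(**data)


def load_config(path: str | Path) -> RunConfig:
    """Load and validate a YAML run config; an empty file gives defaults."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    data = yaml.safe_load(path.read_text())
    if data is not None and not isinstance(data, dict):
        raise ValueError("config file must contain a mapping")
    return RunConfig.from_dict(data)


def save_config(cfg: RunConfig, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(cfg.to_dict(), sort_keys=False))
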