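"""Run configuration: YAML-serialisable settings for the whole pipeline."""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml

from .core import M_MAX, M_MIN
from .errors import InvalidConfigError
from .synthetic import GeneratorConfig, default_historical_periods


@dataclass
class CalibrationBlock:
    m_min: int = M_MIN
    m_max: int = M_MAX
    # historical mapping periods; None means the default 9-period partition
    periods: list[tuple[int, int]] | None = None

    def validate(self) -> None:
        if not (M_MIN <= self.m_min <= self.m_max <= M_MAX):
            raise InvalidConfigError(
                f"M range [{self.m_min}, {self.m_max}] must lie within "
                f"[{M_MIN}, {M_MAX}]"
            )

    def resolved_periods(self) -> list[tuple[int, int]]:
        if self.periods is None:
            return default_historical_periods()
        return [tuple(p) for p in self.periods]


@dataclass
class ProjectionBlock:
    scenarios: list[str] | None = None  # None = all scenarios in the cube
    year0: int = 2023
    year1: int = 2100
    epsilon_frac: float = 0.01
    cell_deg: float = 0.2

    def validate(self) -> None:
        if self.year1 < self.year0:
            raise InvalidConfigError("projection years must be ordered")
        if self.epsilon_frac < 0 or self.cell_deg <= 0:
            raise InvalidConfigError("epsilon_frac >= 0 and cell_deg > 0 required")


@dataclass
class InputPaths:
    """Optional pre-supplied inputs; a set path skips the generating stage."""

    basins_csv: str | None = None
    cti_csv: str | None = None
    sm_cube_nc: str | None = None
    observed_csv: str | None = None
    calibration_csv: str | None = None

    def validate(self) -> None:
        for name, p in asdict(self).items():
            if p is not None and not Path(p).exists():
                raise InvalidConfigError(f"input path {name}={p!r} does not exist")
        if (self.basins_csv is None) != (self.cti_csv is None):
            raise InvalidConfigError("basins_csv and cti_csv must be supplied together")


@dataclass
class RunConfig:
    seed: int = 0
    generator: GeneratorConfig = field(default_factory=GeneratorConfig)
    calibration: CalibrationBlock = field(default_factory=CalibrationBlock)
    projection: ProjectionBlock = field(default_factory=ProjectionBlock)
    inputs: InputPaths = field(default_factory=InputPaths)
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        # keep the generator seeded from the run seed unless set explicitly
        self.generator.seed = int(self.seed)

    def validate(self) -> None:
        self.generator.validate()
        self.calibration.validate()
        self.projection.validate()
        self.inputs.validate()

    # -------------------------------------------------- (de)serialisation

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        gen = d.pop("generator", {}) or {}
        cal = d.pop("calibration", {}) or {}
        proj = d.pop("projection", {}) or {}
        inp = d.pop("inputs", {}) or {}
        for key in ("basin_area_km2_range", "year_range", "true_M_range",
                    "scenarios", "scenario_trend_multipliers"):
            if key in gen and gen[key] is not None:
                gen[key] = tuple(gen[key])
        cfg = cls(
            generator=GeneratorConfig(**gen),
            calibration=CalibrationBlock(**cal),
            projection=ProjectionBlock(**proj),
            inputs=InputPaths(**inp),
            **d,
        )
        return cfg

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(self.canonical_yaml())

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})

    def canonical_yaml(self) -> str:
        return yaml.safe_dump(_plain(self.to_dict()), sort_keys=True)

    def sha256(self) -> str:
        """Hash of the scientific configuration.

        Input *paths* are excluded: a run that re-reads a stage's output
        from disk is the same computation as the run that produced it, and
        must hash (and stamp its provenance headers) identically.
        """
        d = self.to_dict()
        d.pop("inputs", None)
        text = yaml.safe_dump(_plain(d), sort_keys=True)
        return hashlib.sha256(text.encode()).hexdigest()


def _plain(obj):
    """Recursively convert tuples to lists so the YAML dump is canonical."""
    if isinstance(obj, dict):
        return {k: _plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_plain(v) for v in obj]
    return obj
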