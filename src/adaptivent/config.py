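"""Run configuration: protocol constants, cohort size, seeding, I/O.

A :class:`RunConfig` aggregates everything a trial run needs; it
round-trips through YAML and has a stable content hash so that a run
manifest can prove which configuration produced which outputs.
"""

from __future__ import annotations

import hashlib
from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import yaml

from .cohort import CohortParams
from .exceptions import InvalidArgumentError

SCHEMA_VERSION = 1


@dataclass(frozen=True)
class RunConfig:
    """Full configuration of a synthetic cross-over trial run."""

    seed: int = 1
    n: int = 20
    ards_n: int = 10
    etco2_band_mmhg: float = 2.0  # protocol corridor around baseline etCO2
    etco2_tol_mmhg: float = 0.5  # loop convergence target inside the band
    window_s: float = 300.0  # endpoint averaging window
    hold_s: float = 2.5  # occlusion-maneuver length
    sampling_dt_s: float = 0.01  # 100-Hz recording grid
    max_loop_steps: int = 20
    perfect_measurement: bool = False
    outdir: str = "results"
    cohort: CohortParams = field(default_factory=CohortParams)
    schema_version: int = SCHEMA_VERSION

    def __post_init__(self) -> None:
        if self.n <= 0 or not 0 <= self.ards_n <= self.n:
            raise InvalidArgumentError("require n > 0 and 0 <= ards_n <= n")
        if self.etco2_band_mmhg <= 0 or self.etco2_tol_mmhg <= 0:
            raise InvalidArgumentError("etCO2 band/tolerance must be positive")
        if not 2.0 <= self.hold_s <= 3.0:
            raise InvalidArgumentError("hold_s must be within [2, 3] s")
        if self.window_s <= 0 or self.max_loop_steps < 1:
            raise InvalidArgumentError("invalid window or loop budget")

    def to_dict(self) -> dict:
        return asdict(self)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise InvalidArgumentError(f"unknown config keys: {sorted(unknown)}")
        if "cohort" in raw and isinstance(raw["cohort"], dict):
            cohort_raw = {
                k: tuple(v) if isinstance(v, list) else v
                for k, v in raw["cohort"].items()
            }
            raw = raw | {"cohort": CohortParams(**cohort_raw)}
        return cls(**raw)

    def content_hash(self) -> str:
        """Stable sha256 of the canonical YAML serialization."""
        canon = yaml.safe_dump(self.to_dict(), sort_keys=True)
        return hashlib.sha256(canon.encode()).hexdigest()
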