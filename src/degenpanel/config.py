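"""Run configuration: constraint fields plus workflow knobs.

A :class:`RunConfig` round-trips losslessly through YAML or JSON and is
echoed into every output file header, so a designed panel always carries
the exact configuration that produced it.  Window coordinates in config
files and on the CLI are 1-based inclusive (converted to 0-based
half-open internally).
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, fields
from pathlib import Path

import yaml

from .primers import PrimerConstraints

__all__ = ["RunConfig"]


@dataclass(frozen=True)
class RunConfig:
    """All primer constraints plus screening fractions and the RNG seed."""

    tm_opt: float = 52.0
    tm_min: float = 47.0
    tm_max: float = 57.0
    len_opt: int = 20
    len_min: int = 18
    len_max: int = 27
    max_degenerate_positions: int = 8
    max_degeneracy: int = 256
    window_start: int = 106  # 1-based inclusive
    window_end: int = 214  # 1-based inclusive
    product_min: int = 200
    product_max: int = 600
    pair_tm_max_diff: float = 5.0
    na_molar: float = 0.05
    primer_conc: float = 50e-9
    allow_degenerate_3prime: bool = True
    strict_fraction: float = 0.0
    relaxed_fraction: float = 0.10
    rng_seed: int = 0

    def constraints(self) -> PrimerConstraints:
        return PrimerConstraints(
            tm_opt=self.tm_opt,
            tm_min=self.tm_min,
            tm_max=self.tm_max,
            len_opt=self.len_opt,
            len_min=self.len_min,
            len_max=self.len_max,
            max_degenerate_positions=self.max_degenerate_positions,
            max_degeneracy=self.max_degeneracy,
            target_window=(self.window_start - 1, self.window_end),
            product_min=self.product_min,
            product_max=self.product_max,
            pair_tm_max_diff=self.pair_tm_max_diff,
            na_molar=self.na_molar,
            primer_conc=self.primer_conc,
            allow_degenerate_3prime=self.allow_degenerate_3prime,
        )

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**data)

    @classmethod
    def load(cls, path: str | Path) -> "RunConfig":
        path = Path(path)
        text = path.read_text()
        if path.suffix.lower() == ".json":
            data = json.loads(text)
        else:
            data = yaml.safe_load(text)
        if not isinstance(data, dict):
            raise ValueError(f"config file {path} does not hold a mapping")
        return cls.from_dict(data)

    def dump(self, path: str | Path) -> None:
        path = Path(path)
        if path.suffix.lower() == ".json":
            path.write_text(json.dumps(self.to_dict(), indent=2, sort_keys=True) + "\n")
        else:
            path.write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))
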