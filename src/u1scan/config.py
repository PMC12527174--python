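"""Run configuration shared by all CLI subcommands."""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import yaml

from .registers import REGISTER_PRIORITY

__all__ = ["RunConfig", "ConfigError"]


class ConfigError(ValueError):
    """Invalid run configuration, with a field-level message."""


@dataclass
class RunConfig:
    registers: tuple[str, ...] = REGISTER_PRIORITY
    mab_levels: tuple[int, ...] = (11, 10, 9)
    donor_flank: tuple[int, int] = (15, 15)
    acceptor_flank: tuple[int, int] = (15, 15)
    walk_range: tuple[int, int] = (-10, 25)
    cancer_keywords: tuple[str, ...] = ("cancer", "carcinoma", "tumor", "neoplasm")
    psi_threshold: float = 0.5
    tpm_floor: float = 0.5
    seed: int = 0
    binding_length: int = 11

    def validate(self) -> "RunConfig":
        unknown = set(self.registers) - set(REGISTER_PRIORITY)
        if unknown:
            raise ConfigError(f"registers: unknown labels {sorted(unknown)}")
        if not self.registers:
            raise ConfigError("registers: at least one register required")
        for m in self.mab_levels:
            if not 6 <= m <= self.binding_length:
                raise ConfigError(
                    f"mab_levels: {m} outside 6..{self.binding_length}"
                )
        lo, hi = self.walk_range
        if lo == 0 or hi == 0 or lo > hi:
            raise ConfigError(f"walk_range: {self.walk_range} invalid (no zero, lo <= hi)")
        for name, v in (("psi_threshold", self.psi_threshold), ("tpm_floor", self.tpm_floor)):
            if not 0 < v <= 1:
                raise ConfigError(f"{name}: {v} outside (0, 1]")
        for name, (a, b) in (("donor_flank", self.donor_flank), ("acceptor_flank", self.acceptor_flank)):
            if a < 12 or b < 12:
                raise ConfigError(f"{name}: {a}/{b} below minimum 12")
        return self

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        for key in ("registers", "mab_levels", "donor_flank", "acceptor_flank",
                    "walk_range", "cancer_keywords"):
            if key in data and isinstance(data[key], list):
                data[key] = tuple(data[key])
        return cls(**data).validate()
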