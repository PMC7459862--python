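"""Pipeline configuration: the platform parameter set with its defaults."""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path

import yaml


@dataclass(frozen=True)
class PipelineConfig:
    """Every tunable of the design/assessment pipeline.

    Defaults follow the platform's parameter sheet: primers of 18-20 bp,
    products of 200-500 bp, a 20% coverage floor, overlap-merge threshold
    10, folding at 57 °C with 20 mM Mg++ and 0 mM Na+.
    """

    primer_len_min: int = 18
    primer_len_max: int = 20
    product_min: int = 200
    product_max: int = 500
    min_coverage: float = 0.2
    overlap: int = 10
    fold_temp: float = 57.0
    mg: float = 20.0
    na: float = 0.0
    variant_min_fraction: float = 0.01
    max_degeneracy: int = 64
    max_mismatches: int = 0
    top_n: int = 30
    seed: int = 0

    def __post_init__(self) -> None:
        if self.primer_len_min > self.primer_len_max:
            raise ValueError("primer_len_min exceeds primer_len_max")
        if self.product_min > self.product_max:
            raise ValueError("product_min exceeds product_max")
        if not 0.0 <= self.min_coverage <= 1.0:
            # a floor above 1 is allowed only to express "emit nothing"
            if self.min_coverage < 0:
                raise ValueError("min_coverage must be non-negative")
        if self.overlap < 1:
            raise ValueError("overlap threshold must be >= 1")
        if self.max_degeneracy < 1:
            raise ValueError("max_degeneracy must be >= 1")

    def replace(self, **kw) -> "PipelineConfig":
        return dataclasses.replace(self, **kw)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)
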