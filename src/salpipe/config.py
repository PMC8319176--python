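"""Pipeline configuration with documented defaults and YAML round-tripping."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field

import yaml

from .compgen import DEFAULT_KEYWORD_PATTERNS
from .motifs import DEFAULT_WINDOW
from .screen import DEFAULT_PRODUCER_THRESHOLD

__all__ = ["PipelineConfig"]


def _default_bounds() -> dict:
    # wide CHNOPS search bounds (oxygen symmetric with C/H/N; S and P capped
    # at chemically sensible counts for small fragments)
    return {"C": [0, 100], "H": [0, 100], "N": [0, 100],
            "O": [0, 100], "S": [0, 4], "P": [0, 1]}


@dataclass
class PipelineConfig:
    """All tunables of the discovery pipeline, with their defaults.

    ``tolerance_ppm`` is deliberately permissive (100 ppm): fragment-ion
    deviations on Q-TOF instruments at low m/z routinely exceed the few-ppm
    precursor accuracy, and a conservative window keeps true head-group
    formulas in the candidate list.  A 25 ppm strict mode is recommended for
    precursor-level matching.
    """

    tolerance_ppm: float = 100.0
    strict_tolerance_ppm: float = 25.0
    formula_bounds: dict = field(default_factory=_default_bounds)
    rdbe_filter: bool = False
    acyl_c_range: list = field(default_factory=lambda: [10, 22])
    acyl_d_range: list = field(default_factory=lambda: [0, 3])
    acyl_hydroxyl_range: list = field(default_factory=lambda: [0, 1])
    producer_threshold: float = DEFAULT_PRODUCER_THRESHOLD
    keyword_patterns: list = field(default_factory=lambda: list(DEFAULT_KEYWORD_PATTERNS))
    motif_window: int = DEFAULT_WINDOW
    marker_columns: list = field(
        default_factory=lambda: [f"marker_{i}" for i in range(1, 11)]
    )
    mass_table_file: str | None = None
    seed: int = 0

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def bounds_tuples(self) -> dict:
        return {el: (int(lo), int(hi)) for el, (lo, hi) in self.formula_bounds.items()}
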