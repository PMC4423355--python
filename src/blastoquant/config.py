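"""Pipeline configuration.

Houses the two printed constants of the quantification scheme -- the
10% strip fraction and the five midline knots -- together with the
tunable plumbing (FastRed unmixing mode, boundary-detection amplitude,
crop margin, seed, catalogue path).  A YAML file overrides the defaults;
CLI flags override the file.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass
from pathlib import Path

import yaml

from .core import ValidationError


@dataclass
class PipelineConfig:
    strip_fraction: float = 0.10
    knot_count: int = 5
    fastred_mode: str = "subtract"  # or 'literal_invert'
    min_amplitude: float = 20.0
    crop_margin_px: int = 10
    seed: int = 0
    catalogue_path: str | None = None

    def __post_init__(self) -> None:
        if not 0 < self.strip_fraction <= 0.5:
            raise ValidationError("strip_fraction must lie in (0, 0.5]")
        if self.knot_count < 3:
            raise ValidationError("knot_count must be at least 3")
        if self.fastred_mode not in ("subtract", "literal_invert"):
            raise ValidationError(
                f"fastred_mode must be 'subtract' or 'literal_invert', "
                f"got {self.fastred_mode!r}"
            )
        if self.min_amplitude <= 0:
            raise ValidationError("min_amplitude must be positive")
        if self.crop_margin_px < 0:
            raise ValidationError("crop_margin_px cannot be negative")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = set(cls.__dataclass_fields__)
        unknown = set(raw) - known
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))

    def catalogue(self):
        from .boundaries import BoundaryCatalogue

        if self.catalogue_path:
            return BoundaryCatalogue.from_yaml(self.catalogue_path)
        return BoundaryCatalogue.default()
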