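"""Pipeline configuration: every decision threshold in one place.

Defaults reproduce the published rule set (cytotoxicity at an
observed/expected cell ratio of 0.5, genotoxicity at 2- and 3-fold
micronucleus induction, control-Gaussian standard deviations widened 3x,
2-SD cell-cycle bands with a fixed G1:G2 peak-position ratio of 2).
All of them can be overridden from a JSON file so the pipeline adapts to
other assay calibrations without code changes.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

from .errors import SchemaError, ValidationError


@dataclass(frozen=True)
class PipelineConfig:
    # CC50 exemplar selection
    cc50_ratio: float = 0.5          # observed/expected cell ratio; <= is cytotoxic
    jump_factor: float = 10.0        # MN/well fold jump flagging precipitation
    mn_floor: float = 1000.0         # absolute MN/well floor for precipitation

    # genotoxicity flagging
    positive_fold: float = 3.0       # fold >= positive_fold -> positive
    borderline_fold: float = 2.0     # borderline_fold <= fold < positive_fold -> borderline
    genotox_metric: str = "mn_per_cell"  # or "mn_cell_fraction"

    # mechanism scoring
    sd_scale: float = 3.0            # control-Gaussian SD widening factor
    mixed_threshold: float = 0.5     # both scores >= threshold -> mixed call

    # cell-cycle deconvolution
    peak_ratio: float = 2.0          # G2 peak position / G1 peak position
    band_width_sd: float = 2.0       # classification band half-width, in noise SDs
    n_bins: int = 256                # histogram bins for the fit objective
    cc_maxiter: int = 4000           # Nelder-Mead iteration cap
    cc_xatol: float = 1e-6
    cc_fatol: float = 1e-6

    # evaluation
    mixed_handling: str = "own_class"  # or "exclude"

    def __post_init__(self):
        if not 0 < self.cc50_ratio < 1:
            raise ValidationError("cc50_ratio must lie in (0, 1)")
        if self.borderline_fold >= self.positive_fold:
            raise ValidationError("borderline_fold must be below positive_fold")
        if self.genotox_metric not in ("mn_per_cell", "mn_cell_fraction"):
            raise ValidationError(f"unknown genotox_metric {self.genotox_metric!r}")
        if self.mixed_handling not in ("own_class", "exclude"):
            raise ValidationError(f"unknown mixed_handling {self.mixed_handling!r}")
        if self.peak_ratio <= 1 or self.band_width_sd <= 0 or self.n_bins < 16:
            raise ValidationError("invalid cell-cycle parameters")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_json(cls, path: str | Path) -> "PipelineConfig":
        try:
            raw = json.loads(Path(path).read_text())
        except (OSError, json.JSONDecodeError) as exc:
            raise SchemaError(f"cannot read config {path}: {exc}") from exc
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise SchemaError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)
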