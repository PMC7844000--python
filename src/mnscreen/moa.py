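"""Mechanism-of-action scoring against plate-control Gaussians.

Each plate carries dedicated aneugen (Paclitaxel) and clastogen
(Etoposide) control wells. A univariate Gaussian is fitted to the
controls' hallmark feature — kinetochore-positive micronuclei per cell
(F1) for aneugenicity, gamma-H2AX foci per nucleus (F2) for
clastogenicity — and its standard deviation is widened 3x. A genotoxic
compound's hallmark value at the CC50 exemplar is then converted into a
score in (0, 1]: values at or above the control mean are clamped to the
maximal score 1.0; below the mean the score is the Gaussian PDF at the
value divided by the PDF maximum, which reduces to the closed form
``exp(-(x - mu)^2 / (2 sigma_scaled^2))`` (normalization constants
cancel). Replicate scores are aggregated by mean.
"""

from __future__ import annotations

import math
import statistics
from dataclasses import dataclass

from . import genotox
from .errors import PipelineError, ValidationError
from .plate_io import WellRecord

HALLMARKS = ("F1_kt_mn", "F2_h2ax_foci")

ANEUGEN = "aneugen"
CLASTOGEN = "clastogen"
MIXED = "mixed"
NEGATIVE = "negative"
UNDETERMINED = "undetermined"


@dataclass(frozen=True)
class ControlGaussian:
    """Per-plate scoring distribution for one hallmark feature."""

    plate_id: str
    hallmark: str
    mu: float
    sigma_scaled: float  # sd_scale x sample SD of the control values
    n_controls: int

    def __post_init__(self):
        if self.hallmark not in HALLMARKS:
            raise ValidationError(f"unknown hallmark {self.hallmark!r}")
        if self.sigma_scaled <= 0:
            raise ValidationError("sigma_scaled must be positive")
        if self.n_controls < 2:
            raise ValidationError("need >= 2 control wells")


@dataclass(frozen=True)
class MechanismScore:
    compound_id: str
    aneugen_score: float | None
    clastogen_score: float | None
    label: str

    def __post_init__(self):
        for s in (self.aneugen_score, self.clastogen_score):
            if s is not None and not 0.0 <= s <= 1.0:
                raise ValidationError("scores must lie in [0, 1]")
        if self.label not in (ANEUGEN, CLASTOGEN, MIXED, NEGATIVE, UNDETERMINED):
            raise ValidationError(f"unknown label {self.label!r}")


def fit_control_gaussian(values: list[float], hallmark: str,
                         plate_id: str = "", sd_scale: float = 3.0
                         ) -> ControlGaussian:
    """Fit the scoring Gaussian to intra-plate control hallmark values.

    mu is the sample mean; sigma_scaled is ``sd_scale`` times the sample
    standard deviation (n-1 denominator). Constant values have no spread
    and cannot define a scoring distribution: the error suggests checking
    the controls or supplying a configured floor.
    """
    vals = [float(v) for v in values]
    if len(vals) < 2:
        raise ValidationError("need >= 2 control values to fit a Gaussian")
    if not all(math.isfinite(v) for v in vals):
        raise ValidationError("control values must be finite")
    mu = statistics.fmean(vals)
    sd = statistics.stdev(vals)
    if sd == 0:
        raise ValidationError(
            "control values have zero spread; inspect the control wells or "
            "add jitter / a configured sigma floor")
    return ControlGaussian(plate_id, hallmark, mu, sd_scale * sd, len(vals))


def mechanism_score(x: float, g: ControlGaussian) -> float:
    """Likelihood-ratio score of a hallmark value under a control Gaussian.

    Values at or above the control mean score exactly 1.0; below the mean
    the score is the PDF-over-max-PDF ratio in closed form. Always in
    (0, 1] for finite input, and invariant under a joint affine rescaling
    of the value and the control distribution (unit changes cannot alter
    scores).
    """
    if x >= g.mu:
        return 1.0
    z = (x - g.mu) / g.sigma_scaled
    return math.exp(-0.5 * z * z)


def call_label(aneugen_score: float, clastogen_score: float,
               genotox_category: str, mixed_threshold: float = 0.5) -> str:
    """Map the score pair to a mechanism label.

    Compounds without a genotoxic flag are negative regardless of scores.
    Both scores at or above ``mixed_threshold`` -> mixed; otherwise the
    larger score wins; an exact tie below the threshold is undetermined.
    """
    if genotox_category == genotox.NEGATIVE:
        return NEGATIVE
    if genotox_category == genotox.UNDETERMINED:
        return UNDETERMINED
    if aneugen_score >= mixed_threshold and clastogen_score >= mixed_threshold:
        return MIXED
    if aneugen_score > clastogen_score:
        return ANEUGEN
    if clastogen_score > aneugen_score:
        return CLASTOGEN
    return UNDETERMINED


def score_compound(replicate_wells: list[tuple[WellRecord, ControlGaussian, ControlGaussian]],
                   genotox_category: str, mixed_threshold: float = 0.5
                   ) -> MechanismScore:
    """Score a genotoxic compound from its per-replicate exemplar wells.

    Each tuple carries the replicate's exemplar well and the F1/F2
    Gaussians of the plate that well sits on. Per-replicate scores are
    averaged, then the label is assigned. Missing plate controls make the
    compound undetermined.
    """
    if not replicate_wells:
        raise PipelineError("no replicate exemplar wells to score")
    cid = replicate_wells[0][0].compound_id
    an, cl = [], []
    for well, g_f1, g_f2 in replicate_wells:
        if g_f1 is None or g_f2 is None:
            return MechanismScore(cid, None, None, UNDETERMINED)
        if g_f1.hallmark != "F1_kt_mn" or g_f2.hallmark != "F2_h2ax_foci":
            raise ValidationError("Gaussians passed in wrong hallmark order")
        an.append(mechanism_score(well.kt_pos_mn_per_cell, g_f1))
        cl.append(mechanism_score(well.h2ax_foci_per_nucleus, g_f2))
    a = sum(an) / len(an)
    c = sum(cl) / len(cl)
    return MechanismScore(cid, a, c, call_label(a, c, genotox_category,
                                               mixed_threshold))
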