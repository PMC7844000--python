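"""Genotoxicity flagging from micronucleus fold induction.

A compound is flagged at its CC50 exemplar by the fold change of its
micronucleus frequency over the plate solvent baseline: >= 3-fold is
positive, 2- to 3-fold is borderline, below 2-fold is negative. The
exact 3.0 boundary is resolved as positive so the categories partition
the fold axis; both thresholds are configurable.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

from .errors import PipelineError, ValidationError
from .plate_io import WellRecord

POSITIVE = "positive"
BORDERLINE = "borderline"
NEGATIVE = "negative"
UNDETERMINED = "undetermined"

_ORDER = {NEGATIVE: 0, BORDERLINE: 1, POSITIVE: 2}


@dataclass(frozen=True)
class GenotoxCall:
    compound_id: str
    replicate_id: int | None   # None for a compound-level aggregate
    fold_change: float | None  # None when undetermined
    category: str

    def __post_init__(self):
        if self.category not in (POSITIVE, BORDERLINE, NEGATIVE, UNDETERMINED):
            raise ValidationError(f"unknown category {self.category!r}")


def _metric(well: WellRecord, metric: str) -> float:
    if metric == "mn_per_cell":
        return well.mn_per_cell
    if metric == "mn_cell_fraction":
        return well.micronucleated_cell_fraction
    raise ValidationError(f"unknown genotox metric {metric!r}")


def mn_fold_change(exemplar_well: WellRecord, dmso_wells: list[WellRecord],
                   metric: str = "mn_per_cell") -> float:
    """Micronucleus induction of the exemplar well over the plate baseline.

    The baseline is the mean of the metric over the plate's usable solvent
    wells. A zero baseline returns +inf with a warning (the fold is then
    uninformative but the positive direction is preserved).
    """
    usable = [w for w in dmso_wells if w.role == "dmso" and w.usable]
    if not usable:
        raise PipelineError("no usable DMSO wells for fold-change baseline")
    baseline = sum(_metric(w, metric) for w in usable) / len(usable)
    value = _metric(exemplar_well, metric)
    if baseline == 0:
        warnings.warn("plate DMSO micronucleus baseline is zero; "
                      "fold change reported as +inf")
        return math.inf
    return value / baseline


def classify(fold: float, positive_fold: float = 3.0,
             borderline_fold: float = 2.0) -> str:
    """Map a fold change to positive / borderline / negative."""
    if fold < 0:
        raise ValidationError("fold change must be non-negative")
    if fold >= positive_fold:
        return POSITIVE
    if fold >= borderline_fold:
        return BORDERLINE
    return NEGATIVE


def aggregate_calls(calls: list[GenotoxCall], positive_fold: float = 3.0,
                    borderline_fold: float = 2.0) -> GenotoxCall:
    """Aggregate replicate calls: mean fold, category recomputed.

    Undetermined replicates are excluded; a compound whose replicates are
    all undetermined stays undetermined.
    """
    if not calls:
        raise ValidationError("need at least one replicate call")
    cid = calls[0].compound_id
    folds = [c.fold_change for c in calls if c.category != UNDETERMINED]
    if not folds:
        return GenotoxCall(cid, None, None, UNDETERMINED)
    mean_fold = sum(folds) / len(folds)
    return GenotoxCall(cid, None, mean_fold,
                       classify(mean_fold, positive_fold, borderline_fold))


def category_rank(category: str) -> int:
    """negative < borderline < positive (undetermined unranked)."""
    return _ORDER[category]
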