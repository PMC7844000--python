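"""End-to-end orchestration of the three-step genotoxicity workflow.

Per plate: the solvent wells anchor the expected cell number, the
micronucleus baseline and the cell-cycle model; the aneugen and
clastogen control wells anchor the two mechanism-scoring Gaussians.
Per compound x replicate: precipitation masking, cytotoxicity labelling
and smoothing, CC50 exemplar selection, micronucleus fold-change
flagging; positive/borderline compounds proceed to mechanism scoring
and cell-cycle profiling at the exemplar. Replicates aggregate by mean
at the fold and score level. Everything is deterministic given the
inputs and config.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import confusion_matrix, matthews_corrcoef

from . import cellcycle, cytotox, genotox, moa
from .config import PipelineConfig
from .errors import FitError, PipelineError, ValidationError
from .plate_io import DoseResponse, WellRecord, group_dose_responses

logger = logging.getLogger("mnscreen")

EVAL_CLASSES = ("negative", "aneugen", "clastogen")


@dataclass
class PlateContext:
    """Per-plate anchors derived from control wells."""

    plate_id: str
    expected_cells: float
    dmso_wells: list[WellRecord]
    gauss_f1: moa.ControlGaussian | None
    gauss_f2: moa.ControlGaussian | None
    cc_model: cellcycle.CellCycleModel | None


@dataclass
class CompoundResult:
    compound_id: str
    exemplar_concentration: float | None       # highest determined exemplar
    exemplar_by_replicate: dict[int, float | None]
    fold_change: float | None
    genotox_category: str
    aneugen_score: float | None
    clastogen_score: float | None
    mechanism_label: str
    cellcycle: cellcycle.CellCycleProfile | None


@dataclass
class ScreenResult:
    compounds: list[CompoundResult]
    metadata: dict = field(default_factory=dict)


@dataclass
class EvaluationSummary:
    classes: tuple[str, ...]
    confusion: pd.DataFrame      # rows: truth, cols: predicted
    accuracy: float
    mcc: float
    n_excluded: int


# ---------------------------------------------------------------------------

def build_plate_contexts(wells: list[WellRecord],
                         cells: pd.DataFrame | None,
                         config: PipelineConfig) -> dict[str, PlateContext]:
    contexts: dict[str, PlateContext] = {}
    for plate_id in sorted({w.plate_id for w in wells}):
        plate_wells = [w for w in wells if w.plate_id == plate_id]
        roles = {r: [w for w in plate_wells if w.role == r]
                 for r in ("dmso", "aneugen_control", "clastogen_control")}
        missing = [r for r, ws in roles.items()
                   if len(ws) < (1 if r == "dmso" else 2)]
        if missing:
            raise PipelineError(
                f"plate {plate_id}: missing required control wells: {missing}")
        expected = cytotox.expected_cell_number(plate_wells)

        def _fit(ctrl_wells, attr, hallmark):
            try:
                return moa.fit_control_gaussian(
                    [getattr(w, attr) for w in ctrl_wells], hallmark,
                    plate_id=plate_id, sd_scale=config.sd_scale)
            except ValidationError as exc:
                logger.warning("plate %s: %s Gaussian not fitted: %s",
                               plate_id, hallmark, exc)
                return None

        g1 = _fit(roles["aneugen_control"], "kt_pos_mn_per_cell", "F1_kt_mn")
        g2 = _fit(roles["clastogen_control"], "h2ax_foci_per_nucleus",
                  "F2_h2ax_foci")

        cc_model = None
        if cells is not None and len(cells):
            dmso_pos = {w.well for w in roles["dmso"]}
            sel = cells[(cells["plate_id"] == plate_id)
                        & (cells["well"].isin(dmso_pos))]
            if len(sel):
                try:
                    cc_model = cellcycle.fit_model(
                        sel["hoechst_intensity"].to_numpy(),
                        peak_ratio=config.peak_ratio, n_bins=config.n_bins,
                        maxiter=config.cc_maxiter, xatol=config.cc_xatol,
                        fatol=config.cc_fatol)
                except (FitError, ValidationError) as exc:
                    logger.warning("plate %s: cell-cycle fit failed: %s",
                                   plate_id, exc)
        contexts[plate_id] = PlateContext(plate_id, expected, roles["dmso"],
                                          g1, g2, cc_model)
        logger.info("plate %s: expected cells %.1f, gaussians %s/%s, "
                    "cc model %s", plate_id, expected,
                    g1 is not None, g2 is not None, cc_model is not None)
    return contexts


def _series_plate(dr: DoseResponse) -> str:
    plates = {w.plate_id for w in dr.wells}
    if len(plates) != 1:
        raise PipelineError(
            f"dose series {dr.compound_id} replicate {dr.replicate_id} "
            f"spans plates {sorted(plates)}; a series must sit on one plate")
    return next(iter(plates))


def _replicate_exemplar(dr: DoseResponse, ctx: PlateContext,
                        config: PipelineConfig):
    """Run masking -> labelling -> smoothing -> exemplar for one series."""
    masked = cytotox.detect_precipitation(dr, config.jump_factor,
                                          config.mn_floor)
    labels = cytotox.flag_cytotoxic(dr, ctx.expected_cells, config.cc50_ratio)
    labels = cytotox.smooth_labels(labels)
    return cytotox.select_exemplar(labels, masked, dr), masked


def _exemplar_profile(well: WellRecord, ctx: PlateContext,
                      cells: pd.DataFrame | None,
                      config: PipelineConfig) -> np.ndarray | None:
    if cells is None or ctx.cc_model is None:
        return None
    sel = cells[(cells["plate_id"] == well.plate_id)
                & (cells["well"] == well.well)]
    if not len(sel):
        return None
    labels = cellcycle.classify_cells(sel["hoechst_intensity"].to_numpy(),
                                      ctx.cc_model, config.band_width_sd)
    return cellcycle.profile(labels).as_array()


def run_screen(wells: list[WellRecord], cells: pd.DataFrame | None = None,
               config: PipelineConfig | None = None) -> ScreenResult:
    """Execute the full workflow over a validated well (and cell) table."""
    config = config or PipelineConfig()
    contexts = build_plate_contexts(wells, cells, config)
    series = group_dose_responses(wells)
    by_compound: dict[str, list[DoseResponse]] = {}
    for dr in series:
        by_compound.setdefault(dr.compound_id, []).append(dr)

    results: list[CompoundResult] = []
    for cid in sorted(by_compound):
        replicate_calls: list[genotox.GenotoxCall] = []
        exemplar_wells: list[tuple] = []
        exemplar_by_rep: dict[int, float | None] = {}
        profiles: list[np.ndarray] = []
        for dr in sorted(by_compound[cid], key=lambda d: d.replicate_id):
            ctx = contexts[_series_plate(dr)]
            exemplar, masked_set = _replicate_exemplar(dr, ctx, config)
            if exemplar is None or not exemplar.well.usable:
                exemplar_by_rep[dr.replicate_id] = None
                replicate_calls.append(genotox.GenotoxCall(
                    cid, dr.replicate_id, None, genotox.UNDETERMINED))
                logger.info("%s rep %d: exemplar undetermined (masked=%d)",
                            cid, dr.replicate_id, len(masked_set))
                continue
            exemplar_by_rep[dr.replicate_id] = exemplar.concentration
            fold = genotox.mn_fold_change(exemplar.well, ctx.dmso_wells,
                                          config.genotox_metric)
            cat = genotox.classify(fold, config.positive_fold,
                                   config.borderline_fold)
            replicate_calls.append(genotox.GenotoxCall(
                cid, dr.replicate_id, fold, cat))
            exemplar_wells.append((exemplar.well, ctx.gauss_f1, ctx.gauss_f2))
            prof = _exemplar_profile(exemplar.well, ctx, cells, config)
            if prof is not None:
                profiles.append(prof)
            logger.info("%s rep %d: exemplar %.3g M (%s), fold %.3g -> %s",
                        cid, dr.replicate_id, exemplar.concentration,
                        exemplar.provenance, fold, cat)

        agg = genotox.aggregate_calls(replicate_calls, config.positive_fold,
                                      config.borderline_fold)
        if agg.category in (genotox.POSITIVE, genotox.BORDERLINE):
            score = moa.score_compound(exemplar_wells, agg.category,
                                       config.mixed_threshold)
        else:
            label = (moa.NEGATIVE if agg.category == genotox.NEGATIVE
                     else moa.UNDETERMINED)
            score = moa.MechanismScore(cid, None, None, label)

        cc_prof = None
        if profiles:
            mean = np.mean(profiles, axis=0)
            mean = mean / mean.sum()
            cc_prof = cellcycle.CellCycleProfile(*mean)

        determined = [c for r, c in exemplar_by_rep.items() if c is not None]
        results.append(CompoundResult(
            compound_id=cid,
            exemplar_concentration=max(determined) if determined else None,
            exemplar_by_replicate=exemplar_by_rep,
            fold_change=agg.fold_change,
            genotox_category=agg.category,
            aneugen_score=score.aneugen_score,
            clastogen_score=score.clastogen_score,
            mechanism_label=score.label,
            cellcycle=cc_prof))
    return ScreenResult(results, metadata={"config": config.to_dict(),
                                           "n_plates": len(contexts),
                                           "n_compounds": len(results)})


# ---------------------------------------------------------------------------
# evaluation

def predicted_label(result: CompoundResult) -> str:
    """Final 3/4-class label: mechanism label for flagged compounds,
    negative otherwise (undetermined stays undetermined)."""
    return result.mechanism_label


def evaluate(result: ScreenResult, truth: pd.DataFrame,
             mixed_handling: str = "own_class") -> EvaluationSummary:
    """Score predictions against ground-truth classes.

    ``truth`` has columns compound_id, true_class. Undetermined
    predictions are excluded from the confusion matrix and counted in
    ``n_excluded``; with ``mixed_handling='exclude'`` compounds whose
    truth is 'mixed' are dropped, otherwise mixed is its own class.
    Accuracy is the confusion-matrix trace over its total; MCC is the
    multiclass (confusion-matrix correlation) generalization.
    """
    truth_map = dict(zip(truth["compound_id"], truth["true_class"]))
    missing = [c.compound_id for c in result.compounds
               if c.compound_id not in truth_map]
    if missing:
        raise ValidationError(f"truth labels missing for compounds: {missing}")

    classes = list(EVAL_CLASSES)
    if mixed_handling == "own_class" and (
            "mixed" in truth_map.values()
            or any(c.mechanism_label == "mixed" for c in result.compounds)):
        classes.append("mixed")

    y_true, y_pred = [], []
    n_excluded = 0
    for c in result.compounds:
        t = truth_map[c.compound_id]
        p = predicted_label(c)
        if p == "undetermined" or (mixed_handling == "exclude" and t == "mixed"):
            n_excluded += 1
            continue
        y_true.append(t)
        y_pred.append(p)
    if not y_true:
        raise ValidationError("no evaluable compounds after exclusions")

    cm = confusion_matrix(y_true, y_pred, labels=classes)
    acc = float(np.trace(cm) / cm.sum())
    mcc = float(matthews_corrcoef(y_true, y_pred))
    return EvaluationSummary(
        classes=tuple(classes),
        confusion=pd.DataFrame(cm, index=classes, columns=classes),
        accuracy=acc, mcc=mcc, n_excluded=n_excluded)
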