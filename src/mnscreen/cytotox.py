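"""CC50 exemplar selection.

The pipeline evaluates genotoxicity at a single concentration per
compound x replicate: the lowest concentration showing >= 50% loss of
cells relative to the plate's solvent wells, or the highest tested
concentration when no cytotoxicity is seen. Isolated cytotoxic labels
flanked by non-cytotoxic neighbours are smoothed away as well-level
artifacts, and wells flagged for compound precipitation truncate the
series from that concentration upward.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

from .errors import PipelineError, ValidationError
from .plate_io import DoseResponse, WellRecord

CYTOTOXIC = "cytotoxic"
NON_CYTOTOXIC = "non_cytotoxic"

PROVENANCES = ("first_cytotoxic", "highest_concentration", "highest_after_mask")


@dataclass(frozen=True)
class CytotoxLabels:
    """Per-concentration cytotoxicity labels for one dose series."""

    compound_id: str
    replicate_id: int
    concentrations: tuple[float, ...]
    labels: tuple[str, ...]
    expected_cells: float

    def __post_init__(self):
        if len(self.labels) != len(self.concentrations):
            raise ValidationError("one label per concentration required")
        if self.expected_cells <= 0:
            raise ValidationError("expected_cells must be positive")
        if any(lbl not in (CYTOTOXIC, NON_CYTOTOXIC) for lbl in self.labels):
            raise ValidationError("labels must be cytotoxic/non_cytotoxic")


@dataclass(frozen=True)
class CC50Exemplar:
    """The single concentration carried into flagging and mechanism scoring."""

    compound_id: str
    replicate_id: int
    concentration: float
    well: WellRecord
    provenance: str


def expected_cell_number(plate_wells: list[WellRecord]) -> float:
    """Mean cell count of the plate's solvent (DMSO) wells.

    This is the 'expected' cell number every well on the plate is
    normalized against; a plate without solvent wells cannot be analysed.
    """
    counts = [w.cell_count for w in plate_wells if w.role == "dmso"]
    if not counts:
        plate = plate_wells[0].plate_id if plate_wells else "<empty>"
        raise PipelineError(f"plate {plate}: no DMSO wells, cannot normalize")
    return sum(counts) / len(counts)


def flag_cytotoxic(dr: DoseResponse, expected: float,
                   cc50_ratio: float = 0.5) -> CytotoxLabels:
    """Label each concentration cytotoxic iff observed/expected <= cc50_ratio.

    The boundary is inclusive: a well at exactly half the expected cell
    number is cytotoxic.
    """
    if expected <= 0:
        raise ValidationError("expected cell number must be positive")
    labels = tuple(
        CYTOTOXIC if w.cell_count / expected <= cc50_ratio else NON_CYTOTOXIC
        for w in dr.wells)
    return CytotoxLabels(dr.compound_id, dr.replicate_id,
                         tuple(dr.concentrations), labels, expected)


def smooth_labels(labels: CytotoxLabels) -> CytotoxLabels:
    """Relabel isolated cytotoxic concentrations as non-cytotoxic.

    An interior cytotoxic label whose immediate lower- and
    higher-concentration neighbours are both non-cytotoxic is treated as
    well-to-well variability rather than genuine cytotoxicity. The rule
    reads the original vector (no in-place cascading), never touches the
    endpoints, and never smooths runs of two or more cytotoxic labels.
    Idempotent.
    """
    src = labels.labels
    out = list(src)
    for i in range(1, len(src) - 1):
        if (src[i] == CYTOTOXIC and src[i - 1] == NON_CYTOTOXIC
                and src[i + 1] == NON_CYTOTOXIC):
            out[i] = NON_CYTOTOXIC
    return replace(labels, labels=tuple(out))


def detect_precipitation(dr: DoseResponse, jump_factor: float = 10.0,
                         mn_floor: float = 1000.0) -> set[float]:
    """Flag concentrations whose raw MN/well count jumps implausibly.

    Compound precipitate is segmented as spurious micronuclei, producing
    discontinuous jumps (e.g. 50 -> 15,000 MN/well between adjacent
    doses) that genuine genotoxicity cannot explain. A concentration is
    masked when its MN/well count is >= ``jump_factor`` times the count at
    the previous (lower) concentration AND >= ``mn_floor``; both bounds
    are inclusive. A jump from zero counts is treated as infinite-fold.
    Higher concentrations are removed downstream by the truncation rule
    in :func:`select_exemplar`.
    """
    if len(dr) < 2:
        return set()
    masked: set[float] = set()
    for prev, cur in zip(dr.wells, dr.wells[1:]):
        if cur.mn_count < mn_floor:
            continue
        if prev.mn_count == 0 or cur.mn_count >= jump_factor * prev.mn_count:
            masked.add(cur.concentration)
    return masked


def select_exemplar(labels: CytotoxLabels, masked: set[float],
                    dr: DoseResponse) -> CC50Exemplar | None:
    """Pick the CC50 exemplar concentration for one dose series.

    With precipitation masking, the lowest masked concentration and
    everything above it are dropped and the highest remaining
    concentration is the exemplar. Otherwise the exemplar is the lowest
    cytotoxic concentration, falling back to the highest tested
    concentration when the series shows no cytotoxicity. Returns ``None``
    (an undetermined result) when masking removes the whole series.
    """
    by_conc = {w.concentration: w for w in dr.wells}
    if masked:
        cutoff = min(masked)
        remaining = [c for c in labels.concentrations if c < cutoff]
        if not remaining:
            return None
        conc = max(remaining)
        prov = "highest_after_mask"
    else:
        cytotoxic = [c for c, lbl in zip(labels.concentrations, labels.labels)
                     if lbl == CYTOTOXIC]
        if cytotoxic:
            conc, prov = min(cytotoxic), "first_cytotoxic"
        else:
            conc, prov = max(labels.concentrations), "highest_concentration"
    return CC50Exemplar(labels.compound_id, labels.replicate_id, conc,
                        by_conc[conc], prov)
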