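"""Tabular I/O for the screen pipeline.

The well table emulates an annotated per-well export from high-content
image analysis: one row per well with plate/well identifiers, compound
annotation, and the aggregated micronucleus and hallmark features. The
cell table carries single-nucleus integrated Hoechst intensities for
cell-cycle deconvolution. Both are plain UTF-8 CSV with a documented
header, comma separator and "." decimal; a thin column-mapping dict lets
other image-analysis dialects be ingested without code changes.

Concentrations are molar throughout. Solvent wells carry an empty
concentration field.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import RowError, SchemaError, ValidationError

ROLES = ("dmso", "aneugen_control", "clastogen_control", "test")
SOLVENT = "DMSO"

ROWS_384 = "ABCDEFGHIJKLMNOP"
COLS_384 = range(1, 25)

WELL_COLUMNS = [
    "plate_id", "well", "role", "compound_id", "concentration",
    "replicate_id", "cell_count", "mn_count", "mn_per_cell",
    "micronucleated_cell_fraction", "kt_pos_mn_per_cell",
    "h2ax_foci_per_nucleus", "pan_h2ax_fraction", "masked",
]

CELL_COLUMNS = ["plate_id", "well", "cell_index", "hoechst_intensity"]


def valid_well_position(well: str) -> bool:
    """True for positions on a 384-well grid (A1..P24, zero-padded ok)."""
    if len(well) < 2 or well[0] not in ROWS_384:
        return False
    try:
        col = int(well[1:])
    except ValueError:
        return False
    return 1 <= col <= 24


@dataclass
class WellRecord:
    """One well's aggregated image-analysis features with role annotation.

    ``mn_per_cell`` is the primary genotoxicity metric (mean micronuclei
    per cell); ``kt_pos_mn_per_cell`` (F1) and ``h2ax_foci_per_nucleus``
    (F2) are the aneugenicity and clastogenicity hallmarks. A well with
    ``cell_count == 0`` stores ``mn_per_cell = 0`` by convention and is
    unusable for fold-change computation.
    """

    plate_id: str
    well: str
    role: str
    compound_id: str
    concentration: float | None
    replicate_id: int
    cell_count: int
    mn_count: int
    mn_per_cell: float
    micronucleated_cell_fraction: float
    kt_pos_mn_per_cell: float
    h2ax_foci_per_nucleus: float
    pan_h2ax_fraction: float
    masked: bool = False
    extra: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.role not in ROLES:
            raise ValidationError(f"unknown role {self.role!r}")
        if not valid_well_position(self.well):
            raise ValidationError(f"invalid 384-well position {self.well!r}")
        if self.role == "test":
            if not self.compound_id or self.compound_id == SOLVENT:
                raise ValidationError("test wells require a compound_id")
            if self.concentration is None or self.concentration <= 0:
                raise ValidationError("test wells require a positive concentration")
        if self.cell_count < 0 or self.mn_count < 0:
            raise ValidationError("counts must be non-negative")
        for name in ("mn_per_cell", "kt_pos_mn_per_cell", "h2ax_foci_per_nucleus"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be non-negative")
        for name in ("micronucleated_cell_fraction", "pan_h2ax_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValidationError(f"{name}={v} outside [0, 1]")
        if self.cell_count > 0:
            implied = self.mn_count / self.cell_count
            # tolerance covers 6-significant-digit CSV round trips
            if not math.isclose(implied, self.mn_per_cell, rel_tol=1e-5, abs_tol=1e-9):
                raise ValidationError(
                    f"mn_per_cell={self.mn_per_cell} inconsistent with "
                    f"mn_count/cell_count={implied:.6g}")

    @property
    def usable(self) -> bool:
        """Usable for fold-change computation (has cells, not masked)."""
        return self.cell_count > 0 and not self.masked


@dataclass(frozen=True)
class CellRecord:
    plate_id: str
    well: str
    cell_index: int
    hoechst_intensity: float

    def __post_init__(self):
        if self.hoechst_intensity <= 0:
            raise ValidationError("hoechst_intensity must be positive")


@dataclass
class DoseResponse:
    """Ordered concentration series of one compound x replicate."""

    compound_id: str
    replicate_id: int
    wells: list[WellRecord]

    def __post_init__(self):
        concs = [w.concentration for w in self.wells]
        if any(c is None or c <= 0 for c in concs):
            raise ValidationError("dose-response wells need positive concentrations")
        if any(b <= a for a, b in zip(concs, concs[1:])):
            raise ValidationError("concentrations must be strictly increasing")

    @property
    def concentrations(self) -> list[float]:
        return [w.concentration for w in self.wells]

    def __len__(self) -> int:
        return len(self.wells)


# ---------------------------------------------------------------------------
# reading

_NUMERIC = {
    "concentration": float, "replicate_id": int, "cell_count": int,
    "mn_count": int, "mn_per_cell": float, "micronucleated_cell_fraction": float,
    "kt_pos_mn_per_cell": float, "h2ax_foci_per_nucleus": float,
    "pan_h2ax_fraction": float,
}


def read_well_table(path: str | Path, column_map: dict[str, str] | None = None
                    ) -> list[WellRecord]:
    """Read and validate a well-table CSV into records (row order kept).

    ``column_map`` maps this package's canonical column names to the names
    used in the file. Unknown columns are retained in ``WellRecord.extra``.
    Raises :class:`SchemaError` for missing columns and :class:`RowError`
    (with the 1-based file line) for invalid rows.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    if column_map:
        df = df.rename(columns={v: k for k, v in column_map.items()})
    missing = [c for c in WELL_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"well table missing mandatory column(s): {missing}")
    passthrough = [c for c in df.columns if c not in WELL_COLUMNS]

    records: list[WellRecord] = []
    for i, row in enumerate(df.itertuples(index=False)):
        line = i + 2  # header is line 1
        raw = dict(zip(df.columns, row))
        kwargs: dict = {"plate_id": raw["plate_id"], "well": raw["well"],
                        "role": raw["role"], "compound_id": raw["compound_id"]}
        for col, caster in _NUMERIC.items():
            text = raw[col].strip()
            if col == "concentration" and text == "":
                kwargs[col] = None
                continue
            try:
                kwargs[col] = caster(float(text))
            except ValueError:
                raise RowError(line, f"non-numeric value {text!r} in column {col!r}")
        kwargs["masked"] = raw["masked"].strip().lower() in ("true", "1", "yes")
        kwargs["extra"] = {c: raw[c] for c in passthrough}
        try:
            records.append(WellRecord(**kwargs))
        except ValidationError as exc:
            raise RowError(line, str(exc)) from exc
    return records


def read_cell_table(path: str | Path) -> pd.DataFrame:
    """Read the single-cell Hoechst-intensity table.

    Returned as a DataFrame (one row per nucleus) because cell tables run
    to millions of rows; :class:`CellRecord` documents the row contract.
    """
    df = pd.read_csv(path)
    missing = [c for c in CELL_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"cell table missing mandatory column(s): {missing}")
    if (df["hoechst_intensity"] <= 0).any():
        bad = int(df.index[df["hoechst_intensity"] <= 0][0]) + 2
        raise RowError(bad, "hoechst_intensity must be positive")
    return df


# ---------------------------------------------------------------------------
# writing

def _fmt(value) -> str:
    """Serialize a numeric value at 6 significant digits."""
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return ""
    if isinstance(value, bool):
        return str(value)
    if isinstance(value, (int, np.integer)):
        return str(int(value))
    return format(float(value), ".6g")


def wells_to_frame(wells: Iterable[WellRecord]) -> pd.DataFrame:
    rows = []
    for w in wells:
        row = {c: getattr(w, c) for c in WELL_COLUMNS}
        row.update(w.extra)
        rows.append(row)
    return pd.DataFrame(rows)


def write_well_table(wells: Iterable[WellRecord], path: str | Path) -> None:
    df = wells_to_frame(wells)
    for col in _NUMERIC:
        df[col] = df[col].map(_fmt)
    df.to_csv(path, index=False)


def write_cell_table(cells: pd.DataFrame, path: str | Path) -> None:
    out = cells.copy()
    out["hoechst_intensity"] = out["hoechst_intensity"].map(_fmt)
    out.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# grouping

def group_dose_responses(wells: Sequence[WellRecord]) -> list[DoseResponse]:
    """Partition test wells into per-(compound, replicate) dose series.

    Control and solvent wells are ignored (they form the plate pools).
    Duplicate (compound, replicate, concentration) triples are an error.
    Output order follows first appearance; within a series wells are
    sorted by ascending concentration, so the grouping is invariant to
    input permutation up to series order.
    """
    groups: dict[tuple[str, int], list[WellRecord]] = {}
    for w in wells:
        if w.role != "test":
            continue
        groups.setdefault((w.compound_id, w.replicate_id), []).append(w)
    out = []
    for (cid, rid), ws in sorted(groups.items()):
        ws = sorted(ws, key=lambda w: w.concentration)
        concs = [w.concentration for w in ws]
        if len(set(concs)) != len(concs):
            dup = next(c for i, c in enumerate(concs) if c in concs[:i])
            raise ValidationError(
                f"duplicate concentration {dup:g} M for compound "
                f"{cid!r} replicate {rid}")
        out.append(DoseResponse(cid, rid, ws))
    return out


# ---------------------------------------------------------------------------
# reporting

REPORT_COLUMNS = [
    "compound_id", "exemplar_concentration", "fold_change", "genotox_call",
    "aneugen_score", "clastogen_score", "mechanism_call",
    "cc_sub_g1", "cc_g1", "cc_s", "cc_g2", "cc_over_4n",
]


def write_report(result, out_dir: str | Path) -> tuple[Path, Path]:
    """Write a per-compound report CSV and a JSON run summary.

    ``result`` is a :class:`mnscreen.pipeline.ScreenResult`. Numeric values
    are serialized at 6 significant digits; two runs on identical inputs
    produce byte-identical files. Returns (csv_path, json_path).
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for c in result.compounds:
        prof = c.cellcycle
        rows.append({
            "compound_id": c.compound_id,
            "exemplar_concentration": _fmt(c.exemplar_concentration),
            "fold_change": _fmt(c.fold_change),
            "genotox_call": c.genotox_category,
            "aneugen_score": _fmt(c.aneugen_score),
            "clastogen_score": _fmt(c.clastogen_score),
            "mechanism_call": c.mechanism_label,
            "cc_sub_g1": _fmt(prof.sub_g1 if prof else None),
            "cc_g1": _fmt(prof.g1 if prof else None),
            "cc_s": _fmt(prof.s if prof else None),
            "cc_g2": _fmt(prof.g2 if prof else None),
            "cc_over_4n": _fmt(prof.over_4n if prof else None),
        })
    csv_path = out_dir / "report.csv"
    pd.DataFrame(rows, columns=REPORT_COLUMNS).to_csv(csv_path, index=False)

    json_path = out_dir / "summary.json"
    summary = {
        "n_compounds": len(result.compounds),
        "calls": {c.compound_id: c.mechanism_label for c in result.compounds},
        "metadata": result.metadata,
    }
    json_path.write_text(json.dumps(summary, indent=2, sort_keys=True) + "\n")
    return csv_path, json_path
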