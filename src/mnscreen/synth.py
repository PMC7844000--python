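"""Synthetic in vitro micronucleus screen generator.

Emulates the post-segmentation feature tables of a 384-well
high-content IVM screen so the full analysis pipeline can be exercised
without external data: per plate, 14 solvent (DMSO) wells, 12 aneugen
control wells (Paclitaxel 2.5 nM) and 12 clastogen control wells
(Etoposide 0.35 µM); test compounds run as 15-point dose series from
1 nM to 1 mM in replicate.

Compound behaviour is parameterized by a :class:`CompoundProfile`:
cytotoxicity follows a decreasing Hill curve, micronucleus induction
rises toward ``mn_max_fold`` at genotoxic doses, and the hallmark
features (kinetochore-positive MN per cell, γH2AX foci per nucleus)
shift by class-specific multipliers at those same doses. Optional
compound precipitation inflates the raw micronucleus count
discontinuously above a solubility limit. Noise: overdispersed
(lognormal-Poisson) counts, lognormal hallmark noise, and single-cell
Hoechst intensities drawn from the cell-cycle module's generative
mixture. Everything is seeded and byte-reproducible.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import cellcycle
from .errors import CapacityError, ValidationError
from .plate_io import (ROWS_384, SOLVENT, WellRecord, write_cell_table,
                       write_well_table)

# 15 geometrically spaced points across the 1 nM - 1 mM range
# (step ratio 10^(6/14), i.e. slightly finer than half-log).
DOSE_GRID: tuple[float, ...] = tuple(np.geomspace(1e-9, 1e-3, 15))

N_DMSO = 14
N_ANEUGEN_CTRL = 12
N_CLASTOGEN_CTRL = 12
PACLITAXEL_CONC = 2.5e-9   # molar
ETOPOSIDE_CONC = 3.5e-7    # molar

_POSITIONS = tuple(f"{r}{c}" for r in ROWS_384 for c in range(1, 25))
_SERIES_PER_PLATE = (len(_POSITIONS) - N_DMSO - N_ANEUGEN_CTRL
                     - N_CLASTOGEN_CTRL) // len(DOSE_GRID)

CLASSES = ("negative", "aneugen", "clastogen", "mixed")


@dataclass(frozen=True)
class CompoundProfile:
    """Ground-truth behaviour of one simulated compound."""

    compound_id: str
    true_class: str
    cytotox_ec50: float        # molar; 50%-survival concentration
    cytotox_slope: float       # Hill slope of the survival curve
    mn_max_fold: float         # maximal MN-per-cell fold over solvent
    f1_shift: float            # multiplier on kt+ MN hallmark at genotoxic doses
    f2_shift: float            # multiplier on γH2AX-foci hallmark
    precipitation_conc: float | None = None

    def __post_init__(self):
        if self.true_class not in CLASSES:
            raise ValidationError(f"unknown class {self.true_class!r}")
        if self.cytotox_ec50 <= 0 or self.cytotox_slope <= 0:
            raise ValidationError("cytotox_ec50 and slope must be positive")
        if self.mn_max_fold < 1:
            raise ValidationError("mn_max_fold must be >= 1")
        if self.true_class == "negative" and self.mn_max_fold >= 2:
            raise ValidationError("negative profiles need mn_max_fold < 2")
        if self.true_class == "aneugen" and not (
                self.f1_shift > 1 >= self.f2_shift):
            raise ValidationError("aneugen profiles need f1_shift > 1 >= f2_shift")
        if self.true_class == "clastogen" and not (
                self.f2_shift > 1 >= self.f1_shift):
            raise ValidationError("clastogen profiles need f2_shift > 1 >= f1_shift")
        if self.true_class == "mixed" and not (
                self.f1_shift > 1 and self.f2_shift > 1):
            raise ValidationError("mixed profiles need both shifts > 1")
        if self.precipitation_conc is not None and self.precipitation_conc <= 0:
            raise ValidationError("precipitation_conc must be positive")


@dataclass(frozen=True)
class SolventBaseline:
    """Solvent-well expectations the simulator perturbs."""

    cell_count: float = 1500.0        # ~1 doubling of 750 seeded cells over 48 h
    mn_per_cell: float = 0.03         # endogenous micronucleus frequency ~3%
    kt_pos_mn_per_cell: float = 0.01  # endogenous kt+ MN rate (free parameter)
    h2ax_foci_per_nucleus: float = 1.0
    pan_h2ax_fraction: float = 0.02
    cell_count_cv: float = 0.08       # lognormal CV on expected cell count
    feature_cv: float = 0.10          # lognormal CV on hallmark features
    hoechst_mu_g1: float = 100.0      # arbitrary intensity units
    hoechst_cv: float = 0.06          # noise SD / G1 peak
    w_g1: float = 0.62
    w_s: float = 0.16
    w_g2: float = 0.22
    frac_sub_g1: float = 0.01
    frac_over_4n: float = 0.01

    def cellcycle_model(self) -> cellcycle.CellCycleModel:
        return cellcycle.CellCycleModel(
            mu_g1=self.hoechst_mu_g1,
            sigma=self.hoechst_cv * self.hoechst_mu_g1,
            w_g1=self.w_g1, w_s=self.w_s, w_g2=self.w_g2)


@dataclass(frozen=True)
class WellAssignment:
    role: str
    compound_id: str
    concentration: float | None
    replicate_id: int


@dataclass
class PlateLayout:
    plate_id: str
    wells: dict[str, WellAssignment]  # position -> assignment

    def count_role(self, role: str) -> int:
        return sum(1 for a in self.wells.values() if a.role == role)


def make_layout(n_compounds: int, n_replicates: int, seed: int,
                compound_ids: list[str] | None = None,
                max_plates: int | None = None) -> list[PlateLayout]:
    """Lay out compounds as 15-point series across as many plates as needed.

    Every plate carries its own 14 DMSO + 12 aneugen-control + 12
    clastogen-control wells; each compound x replicate series (15
    concentrations) stays on a single plate so plate-anchored
    normalization is always possible. Well positions are shuffled per
    plate under the seed. Deterministic for a fixed seed.
    """
    if n_compounds < 1 or n_replicates < 1:
        raise ValidationError("n_compounds and n_replicates must be >= 1")
    ids = compound_ids or [f"CPD-{i + 1:03d}" for i in range(n_compounds)]
    if len(ids) != n_compounds:
        raise ValidationError("compound_ids length must equal n_compounds")
    series = [(cid, rep) for cid in ids for rep in range(1, n_replicates + 1)]
    n_plates = -(-len(series) // _SERIES_PER_PLATE)
    if max_plates is not None and n_plates > max_plates:
        raise CapacityError(
            f"{len(series)} series need {n_plates} plates "
            f"({_SERIES_PER_PLATE} series/plate); only {max_plates} allotted")

    rng = np.random.default_rng(seed)
    layouts = []
    for p in range(n_plates):
        positions = list(_POSITIONS)
        rng.shuffle(positions)
        wells: dict[str, WellAssignment] = {}
        cursor = 0
        for _ in range(N_DMSO):
            wells[positions[cursor]] = WellAssignment("dmso", SOLVENT, None, 1)
            cursor += 1
        for _ in range(N_ANEUGEN_CTRL):
            wells[positions[cursor]] = WellAssignment(
                "aneugen_control", "PACLITAXEL", PACLITAXEL_CONC, 1)
            cursor += 1
        for _ in range(N_CLASTOGEN_CTRL):
            wells[positions[cursor]] = WellAssignment(
                "clastogen_control", "ETOPOSIDE", ETOPOSIDE_CONC, 1)
            cursor += 1
        for cid, rep in series[p * _SERIES_PER_PLATE:(p + 1) * _SERIES_PER_PLATE]:
            for conc in DOSE_GRID:
                wells[positions[cursor]] = WellAssignment("test", cid, conc, rep)
                cursor += 1
        layouts.append(PlateLayout(f"PLATE-{p + 1:02d}", wells))
    return layouts


# ---------------------------------------------------------------------------
# per-well simulation

def _survival(conc: float, profile: CompoundProfile) -> float:
    if conc <= 0:
        return 1.0
    return 1.0 / (1.0 + (conc / profile.cytotox_ec50) ** profile.cytotox_slope)


def _genotox_effect(conc: float, profile: CompoundProfile) -> float:
    """Saturating 0..1 dose effect driving MN induction and hallmark shifts.

    Centred below the cytotoxic EC50 so the effect is near-maximal at the
    CC50 exemplar, mirroring MN induction rising into the cytotoxic range.
    """
    if conc <= 0:
        return 0.0
    ec50_g = profile.cytotox_ec50 / 3.0
    return conc ** 2 / (conc ** 2 + ec50_g ** 2)


def simulate_well(profile: CompoundProfile | None, concentration: float,
                  baseline: SolventBaseline, seed: int | np.random.Generator,
                  *, plate_id: str = "PLATE-01", well: str = "A1",
                  role: str = "test", replicate_id: int = 1,
                  effect_override: float | None = None,
                  cells_cap: int | None = None
                  ) -> tuple[WellRecord, np.ndarray]:
    """Simulate one well; returns the record and its nuclei intensities.

    ``profile=None`` (or concentration 0) simulates a solvent well.
    ``effect_override`` pins the genotoxic-effect level regardless of
    concentration — used for the fixed-dose plate control wells.
    """
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    if concentration < 0:
        raise ValidationError("concentration must be >= 0")

    if profile is None:
        surv, effect, f1s, f2s, fold_max = 1.0, 0.0, 1.0, 1.0, 1.0
    else:
        surv = _survival(concentration, profile)
        effect = (_genotox_effect(concentration, profile)
                  if effect_override is None else float(effect_override))
        f1s, f2s, fold_max = profile.f1_shift, profile.f2_shift, profile.mn_max_fold

    expected_cells = baseline.cell_count * surv
    expected_cells *= rng.lognormal(0.0, baseline.cell_count_cv)
    cell_count = int(rng.poisson(expected_cells))

    mn_fold = 1.0 + (fold_max - 1.0) * effect
    mn_rate = baseline.mn_per_cell * mn_fold * rng.lognormal(0.0, baseline.feature_cv)
    mn_count = int(rng.poisson(cell_count * mn_rate))
    if (profile is not None and profile.precipitation_conc is not None
            and concentration >= profile.precipitation_conc):
        # precipitate segmented as spurious micronuclei: discontinuous jump
        mn_count += int(rng.poisson(15000))
    mn_per_cell = mn_count / cell_count if cell_count > 0 else 0.0
    mcf = (rng.binomial(cell_count, -np.expm1(-mn_rate)) / cell_count
           if cell_count > 0 else 0.0)

    f1 = (baseline.kt_pos_mn_per_cell * (1.0 + (f1s - 1.0) * effect)
          * rng.lognormal(0.0, baseline.feature_cv))
    f2 = (baseline.h2ax_foci_per_nucleus * (1.0 + (f2s - 1.0) * effect)
          * rng.lognormal(0.0, baseline.feature_cv))
    pan = min(1.0, baseline.pan_h2ax_fraction * (1.0 + 0.5 * (f2s - 1.0) * effect))

    # cell-cycle perturbation: aneugens arrest in G2/M, clastogens slow S
    # and raise the apoptotic (Sub-G1) tail
    w = np.array([baseline.w_g1, baseline.w_s, baseline.w_g2])
    sub, over = baseline.frac_sub_g1, baseline.frac_over_4n
    if f1s > 1:
        shift = min(0.30 * effect, w[0] - 0.05)
        w = w + np.array([-shift, 0.0, shift])
        over = min(0.2, over + 0.03 * effect)
    if f2s > 1:
        shift = min(0.20 * effect, w[0] - 0.05)
        w = w + np.array([-shift, shift, 0.0])
        sub = min(0.3, sub + 0.05 * effect)
    model = cellcycle.CellCycleModel(
        mu_g1=baseline.hoechst_mu_g1,
        sigma=baseline.hoechst_cv * baseline.hoechst_mu_g1,
        w_g1=float(w[0]), w_s=float(w[1]), w_g2=float(w[2]))
    n_cells = cell_count if cells_cap is None else min(cell_count, cells_cap)
    if n_cells > 0:
        intensities, _ = cellcycle.sample_intensities(
            model, n_cells, rng, frac_sub_g1=sub, frac_over_4n=over)
    else:
        intensities = np.empty(0)

    record = WellRecord(
        plate_id=plate_id, well=well, role=role,
        compound_id=profile.compound_id if profile is not None else SOLVENT,
        concentration=concentration if concentration > 0 else None,
        replicate_id=replicate_id, cell_count=cell_count, mn_count=mn_count,
        mn_per_cell=mn_per_cell, micronucleated_cell_fraction=float(mcf),
        kt_pos_mn_per_cell=float(f1), h2ax_foci_per_nucleus=float(f2),
        pan_h2ax_fraction=float(pan))
    return record, intensities


# ---------------------------------------------------------------------------
# whole-screen simulation

@dataclass(frozen=True)
class ScreenScenario:
    """Composition and effect strengths of a simulated screen."""

    n_negative: int = 5
    n_aneugen: int = 5
    n_clastogen: int = 5
    n_mixed: int = 0
    n_replicates: int = 2
    mn_fold_range: tuple[float, float] = (5.0, 8.0)
    hallmark_shift_range: tuple[float, float] = (3.5, 6.0)
    negative_fold_range: tuple[float, float] = (1.0, 1.5)
    control_mn_fold: float = 3.5        # MN induction of the fixed-dose controls
    control_hallmark_shift: float = 4.0  # hallmark elevation of the controls
    precipitation_rate: float = 0.1     # fraction of compounds with a solubility limit
    cells_per_well_cap: int | None = None
    baseline: SolventBaseline = field(default_factory=SolventBaseline)

    def __post_init__(self):
        for n in (self.n_negative, self.n_aneugen, self.n_clastogen,
                  self.n_mixed):
            if n < 0:
                raise ValidationError("class counts must be non-negative")
        if self.n_negative + self.n_aneugen + self.n_clastogen + self.n_mixed == 0:
            raise ValidationError("scenario needs at least one compound")
        if self.n_replicates < 1:
            raise ValidationError("n_replicates must be >= 1")
        if not 0 <= self.precipitation_rate <= 1:
            raise ValidationError("precipitation_rate must lie in [0, 1]")

    @property
    def n_compounds(self) -> int:
        return self.n_negative + self.n_aneugen + self.n_clastogen + self.n_mixed


@dataclass
class ScreenDataset:
    wells: list[WellRecord]
    cells: pd.DataFrame
    truth: pd.DataFrame        # compound_id, true_class
    profiles: list[CompoundProfile]
    metadata: dict


def sample_profiles(scenario: ScreenScenario, rng: np.random.Generator
                    ) -> list[CompoundProfile]:
    """Draw ground-truth compound profiles for a scenario."""
    profiles = []
    specs = ([("negative", "NEG")] * scenario.n_negative
             + [("aneugen", "ANE")] * scenario.n_aneugen
             + [("clastogen", "CLA")] * scenario.n_clastogen
             + [("mixed", "MIX")] * scenario.n_mixed)
    counters: dict[str, int] = {}
    lo_s, hi_s = scenario.hallmark_shift_range
    for cls, prefix in specs:
        counters[prefix] = counters.get(prefix, 0) + 1
        cid = f"{prefix}-{counters[prefix]:02d}"
        if cls == "negative":
            # half the negatives are cytotoxic within the dose range,
            # half (sucrose-like) never reach 50% kill
            ec50 = 10.0 ** rng.uniform(-5.5, -1.5)
            fold = rng.uniform(*scenario.negative_fold_range)
            f1s = f2s = 1.0
        else:
            ec50 = 10.0 ** rng.uniform(-6.5, -4.5)
            fold = rng.uniform(*scenario.mn_fold_range)
            f1s = rng.uniform(lo_s, hi_s) if cls in ("aneugen", "mixed") else 1.0
            f2s = rng.uniform(lo_s, hi_s) if cls in ("clastogen", "mixed") else 1.0
        precip = None
        if rng.random() < scenario.precipitation_rate:
            precip = float(DOSE_GRID[rng.integers(11, 14)])
        profiles.append(CompoundProfile(
            compound_id=cid, true_class=cls, cytotox_ec50=float(ec50),
            cytotox_slope=float(rng.uniform(1.5, 3.0)), mn_max_fold=float(fold),
            f1_shift=float(f1s), f2_shift=float(f2s),
            precipitation_conc=precip))
    return profiles


_CTRL_EFFECT = 1.0  # plate controls are dosed at their fully effective concentration


def _control_profile(kind: str, scenario: ScreenScenario) -> CompoundProfile:
    s = scenario.control_hallmark_shift
    if kind == "aneugen_control":
        return CompoundProfile("PACLITAXEL", "aneugen", 1e-3, 2.0,
                               scenario.control_mn_fold, s, 1.0)
    return CompoundProfile("ETOPOSIDE", "clastogen", 1e-3, 2.0,
                           scenario.control_mn_fold, 1.0, s)


def simulate_screen(scenario: ScreenScenario, seed: int) -> ScreenDataset:
    """Simulate a full screen: well table, cell table and truth labels.

    Deterministic: a fixed (scenario, seed) pair reproduces the dataset
    byte for byte when written with :func:`write_dataset`.
    """
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    profiles = sample_profiles(scenario, rng)
    layouts = make_layout(scenario.n_compounds, scenario.n_replicates,
                          seed=seed,
                          compound_ids=[p.compound_id for p in profiles])
    by_id = {p.compound_id: p for p in profiles}
    ctrl = {k: _control_profile(k, scenario)
            for k in ("aneugen_control", "clastogen_control")}

    wells: list[WellRecord] = []
    cell_frames: list[pd.DataFrame] = []
    for layout in layouts:
        # deterministic well order: row-major over the 384 grid
        for pos in sorted(layout.wells,
                          key=lambda w: (w[0], int(w[1:]))):
            a = layout.wells[pos]
            if a.role == "dmso":
                prof, conc, eff = None, 0.0, None
            elif a.role == "test":
                prof, conc, eff = by_id[a.compound_id], a.concentration, None
            else:
                prof, conc, eff = ctrl[a.role], a.concentration, _CTRL_EFFECT
            rec, intens = simulate_well(
                prof, conc, scenario.baseline, rng, plate_id=layout.plate_id,
                well=pos, role=a.role, replicate_id=a.replicate_id,
                effect_override=eff, cells_cap=scenario.cells_per_well_cap)
            wells.append(rec)
            if intens.size:
                cell_frames.append(pd.DataFrame({
                    "plate_id": layout.plate_id, "well": pos,
                    "cell_index": np.arange(intens.size),
                    "hoechst_intensity": intens}))

    cells = (pd.concat(cell_frames, ignore_index=True) if cell_frames
             else pd.DataFrame(columns=["plate_id", "well", "cell_index",
                                        "hoechst_intensity"]))
    truth = pd.DataFrame({"compound_id": [p.compound_id for p in profiles],
                          "true_class": [p.true_class for p in profiles]})
    meta = {
        "seed": seed,
        "scenario": _scenario_dict(scenario),
        "dose_grid_molar": [float(c) for c in DOSE_GRID],
        "n_plates": len(layouts),
    }
    return ScreenDataset(wells, cells, truth, profiles, meta)


def _scenario_dict(scenario: ScreenScenario) -> dict:
    d = dataclasses.asdict(scenario)
    for k, v in d.items():
        if isinstance(v, tuple):
            d[k] = list(v)
    return d


def write_dataset(dataset: ScreenDataset, out_dir: str | Path) -> dict[str, Path]:
    """Write wells.csv, cells.csv, truth.csv and metadata.json."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "wells": out / "wells.csv",
        "cells": out / "cells.csv",
        "truth": out / "truth.csv",
        "metadata": out / "metadata.json",
    }
    write_well_table(dataset.wells, paths["wells"])
    write_cell_table(dataset.cells, paths["cells"])
    dataset.truth.to_csv(paths["truth"], index=False)
    paths["metadata"].write_text(
        json.dumps(dataset.metadata, indent=2, sort_keys=True) + "\n")
    return paths
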