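import json

import numpy as np
import pytest

from mnscreen import synth
from mnscreen.errors import CapacityError, ValidationError
from mnscreen.plate_io import valid_well_position
from mnscreen.synth import (DOSE_GRID, CompoundProfile, ScreenScenario,
                            SolventBaseline)


def profile(cls="aneugen", **kw):
    defaults = dict(compound_id="X-01", true_class=cls, cytotox_ec50=1e-5,
                    cytotox_slope=2.0, mn_max_fold=6.0,
                    f1_shift=4.0 if cls in ("aneugen", "mixed") else 1.0,
                    f2_shift=4.0 if cls in ("clastogen", "mixed") else 1.0)
    if cls == "negative":
        defaults.update(mn_max_fold=1.3, f1_shift=1.0, f2_shift=1.0)
    defaults.update(kw)
    return CompoundProfile(**defaults)


class TestLayout:
    def test_single_compound_two_replicates_on_one_plate(self):
        (plate,) = synth.make_layout(1, 2, seed=7)
        roles = [a.role for a in plate.wells.values()]
        assert roles.count("test") == 30
        assert roles.count("dmso") == 14
        assert roles.count("aneugen_control") == 12
        assert roles.count("clastogen_control") == 12
        assert all(valid_well_position(p) for p in plate.wells)

    def test_seed_determinism(self):
        a = synth.make_layout(3, 2, seed=7)
        b = synth.make_layout(3, 2, seed=7)
        assert [(p.plate_id, p.wells) for p in a] == [
            (p.plate_id, p.wells) for p in b]

    def test_twelve_compounds_duplicate_bookkeeping(self):
        layouts = synth.make_layout(12, 2, seed=0)
        # exhaustive enumeration of the emitted layout
        seen: dict[tuple, int] = {}
        for plate in layouts:
            assert plate.count_role("dmso") == 14
            assert plate.count_role("aneugen_control") == 12
            assert plate.count_role("clastogen_control") == 12
            for a in plate.wells.values():
                if a.role == "test":
                    key = (a.compound_id, a.replicate_id, a.concentration)
                    seen[key] = seen.get(key, 0) + 1
        assert sum(seen.values()) == 12 * 2 * 15 == 360
        assert set(seen.values()) == {1}
        for cid in {k[0] for k in seen}:
            concs = {k[2] for k in seen if k[0] == cid and k[1] == 1}
            assert concs == set(DOSE_GRID)

    def test_capacity_error(self):
        with pytest.raises(CapacityError):
            synth.make_layout(30, 2, seed=0, max_plates=1)

    def test_dose_grid_spans_range(self):
        assert DOSE_GRID[0] == pytest.approx(1e-9)
        assert DOSE_GRID[-1] == pytest.approx(1e-3)
        assert len(DOSE_GRID) == 15
        ratios = np.diff(np.log10(DOSE_GRID))
        assert np.allclose(ratios, 6 / 14)


class TestProfileInvariants:
    def test_aneugen_requires_f1_shift(self):
        with pytest.raises(ValidationError):
            profile("aneugen", f1_shift=1.0)

    def test_negative_requires_low_fold(self):
        with pytest.raises(ValidationError):
            profile("negative", mn_max_fold=2.5)

    def test_clastogen_requires_f2_shift(self):
        with pytest.raises(ValidationError):
            profile("clastogen", f2_shift=0.9, f1_shift=2.0)


class TestSimulateWell:
    baseline = SolventBaseline()

    def test_negative_compound_stays_below_two_fold(self):
        p = profile("negative", cytotox_ec50=1.0)  # no cytotoxicity in range
        rec, _ = synth.simulate_well(p, 1e-3, self.baseline, seed=5)
        assert rec.mn_per_cell / self.baseline.mn_per_cell < 2.0
        assert rec.cell_count > 0.7 * self.baseline.cell_count

    def test_endogenous_baseline_default(self):
        assert self.baseline.mn_per_cell == 0.03
        rec, _ = synth.simulate_well(None, 0.0, self.baseline, seed=5,
                                     role="dmso")
        assert rec.mn_per_cell == pytest.approx(0.03, abs=0.02)

    def test_precipitation_jump_is_discontinuous(self):
        p = profile("negative", cytotox_ec50=1.0, precipitation_conc=1e-4)
        below, _ = synth.simulate_well(p, 3.16e-5, self.baseline, seed=5)
        above, _ = synth.simulate_well(p, 1e-4, self.baseline, seed=6)
        assert above.mn_count >= 10 * max(below.mn_count, 1)
        # cell number is continuous across the solubility limit
        assert 0.5 < above.cell_count / below.cell_count < 2.0

    def test_hallmarks_shift_only_at_genotoxic_doses(self):
        p = profile("aneugen", cytotox_ec50=1e-5)
        low, _ = synth.simulate_well(p, 1e-9, self.baseline, seed=5)
        high, _ = synth.simulate_well(p, 1e-4, self.baseline, seed=5)
        assert low.kt_pos_mn_per_cell < 2 * self.baseline.kt_pos_mn_per_cell
        assert high.kt_pos_mn_per_cell > 2 * self.baseline.kt_pos_mn_per_cell

    def test_invalid_concentration_rejected(self):
        with pytest.raises(ValidationError):
            synth.simulate_well(profile(), -1.0, self.baseline, seed=0)


class TestSimulateScreen:
    scenario = ScreenScenario(n_negative=4, n_aneugen=4, n_clastogen=4,
                              cells_per_well_cap=50)

    def test_bookkeeping_and_schema_validity(self):
        ds = synth.simulate_screen(self.scenario, seed=1)
        assert len(ds.truth) == 12
        assert set(ds.truth["true_class"]) == {"negative", "aneugen",
                                               "clastogen"}
        # WellRecord construction enforces the schema invariants
        for w in ds.wells:
            assert w.cell_count >= 0 and w.mn_count >= 0
            assert 0 <= w.micronucleated_cell_fraction <= 1
            if w.role == "test":
                assert w.concentration > 0
        assert (ds.cells["hoechst_intensity"] > 0).all()

    def test_control_well_phenotypes(self):
        ds = synth.simulate_screen(self.scenario, seed=1)
        by_role = {}
        for w in ds.wells:
            by_role.setdefault(w.role, []).append(w)
        f1 = {r: np.mean([w.kt_pos_mn_per_cell for w in ws])
              for r, ws in by_role.items()}
        f2 = {r: np.mean([w.h2ax_foci_per_nucleus for w in ws])
              for r, ws in by_role.items()}
        # aneugen controls: elevated kt+ MN, baseline γH2AX; clastogen converse
        assert f1["aneugen_control"] > 2 * f1["dmso"]
        assert f2["aneugen_control"] < 2 * f2["dmso"]
        assert f2["clastogen_control"] > 2 * f2["dmso"]
        assert f1["clastogen_control"] < 2 * f1["dmso"]

    def test_byte_identical_for_fixed_seed(self, tmp_path):
        for d in ("a", "b"):
            synth.write_dataset(synth.simulate_screen(self.scenario, seed=9),
                                tmp_path / d)
        for name in ("wells.csv", "cells.csv", "truth.csv", "metadata.json"):
            assert ((tmp_path / "a" / name).read_bytes()
                    == (tmp_path / "b" / name).read_bytes()), name

    def test_different_seeds_differ(self):
        a = synth.simulate_screen(self.scenario, seed=1)
        b = synth.simulate_screen(self.scenario, seed=2)
        assert any(x.cell_count != y.cell_count
                   for x, y in zip(a.wells, b.wells))

    def test_metadata_records_grid_and_seed(self, tmp_path):
        paths = synth.write_dataset(
            synth.simulate_screen(self.scenario, seed=3), tmp_path)
        meta = json.loads(paths["metadata"].read_text())
        assert meta["seed"] == 3
        assert len(meta["dose_grid_molar"]) == 15

    def test_invalid_scenario_rejected(self):
        with pytest.raises(ValidationError):
            ScreenScenario(n_negative=0, n_aneugen=0, n_clastogen=0)
        with pytest.raises(ValidationError):
            ScreenScenario(precipitation_rate=1.5)
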