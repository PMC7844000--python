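import dataclasses
import itertools

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mnscreen import cytotox
from mnscreen.cytotox import CYTOTOXIC as C
from mnscreen.cytotox import NON_CYTOTOXIC as N
from mnscreen.errors import PipelineError
from mnscreen.synth import DOSE_GRID

from conftest import make_series, make_well


def labels_from(pattern, expected=1000.0):
    return cytotox.CytotoxLabels("CPD-001", 1, tuple(DOSE_GRID[:len(pattern)]),
                                 tuple(pattern), expected)


def smooth_oracle(pattern):
    """Direct application of the flanked-singleton rule to all index triples."""
    out = list(pattern)
    for i in range(1, len(pattern) - 1):
        if pattern[i - 1] == N and pattern[i] == C and pattern[i + 1] == N:
            out[i] = N
    return tuple(out)


class TestExpectedCellNumber:
    def test_arithmetic_mean(self):
        wells = [make_well(well=f"A{i + 1}", role="dmso", cell_count=c)
                 for i, c in enumerate([1000, 1200, 800])]
        assert cytotox.expected_cell_number(wells) == 1000

    def test_single_dmso_well(self):
        assert cytotox.expected_cell_number(
            [make_well(role="dmso", cell_count=999)]) == 999

    def test_fourteen_wells_match_oracle_mean(self, rng):
        counts = rng.integers(800, 2000, 14)
        wells = [make_well(well=f"A{i + 1}", role="dmso", cell_count=int(c))
                 for i, c in enumerate(counts)]
        assert cytotox.expected_cell_number(wells) == pytest.approx(
            counts.sum() / 14)

    def test_no_dmso_wells_is_fatal(self):
        with pytest.raises(PipelineError, match="no DMSO"):
            cytotox.expected_cell_number([make_well()])


class TestFlagging:
    @pytest.mark.parametrize("cells,expected_label", [
        (500, C),    # ratio exactly 0.5 is inclusive
        (501, N),
        (0, C),
        (1000, N),
    ])
    def test_half_expected_boundary(self, cells, expected_label):
        dr = make_series([cells])
        labels = cytotox.flag_cytotoxic(dr, expected=1000.0)
        assert labels.labels == (expected_label,)

    def test_no_cytotoxicity_anywhere(self):
        dr = make_series([1000] * 15)
        labels = cytotox.flag_cytotoxic(dr, expected=1000.0)
        assert set(labels.labels) == {N}


class TestSmoothing:
    def test_isolated_singleton_removed(self):
        pattern = (N, N, C, N, N) + (N,) * 10
        assert cytotox.smooth_labels(labels_from(pattern)).labels == (N,) * 15

    def test_terminal_run_unchanged(self):
        pattern = (N,) * 12 + (C, C, C)
        assert cytotox.smooth_labels(labels_from(pattern)).labels == pattern

    def test_endpoints_never_relabeled(self):
        pattern = (C, N, N, N, C)
        out = cytotox.smooth_labels(labels_from(pattern)).labels
        assert out[0] == C and out[-1] == C

    def test_alternating_matches_brute_force(self):
        pattern = tuple(C if i % 2 == 0 else N for i in range(15))
        out = cytotox.smooth_labels(labels_from(pattern)).labels
        assert out == smooth_oracle(pattern)
        assert out[0] == C  # first label kept

    @given(st.lists(st.sampled_from([C, N]), min_size=1, max_size=15))
    @settings(derandomize=True, max_examples=200)
    def test_matches_oracle_and_is_idempotent(self, pattern):
        labels = labels_from(tuple(pattern))
        once = cytotox.smooth_labels(labels)
        assert once.labels == smooth_oracle(tuple(pattern))
        assert cytotox.smooth_labels(once).labels == once.labels
        n_before = sum(1 for x in pattern if x == C)
        n_after = sum(1 for x in once.labels if x == C)
        assert n_after <= n_before


class TestExemplarSelection:
    def test_first_cytotoxic_concentration_wins(self):
        # cytotoxic from index 6 upward (colchicine-like)
        dr = make_series([1000] * 6 + [300] * 9)
        labels = cytotox.smooth_labels(cytotox.flag_cytotoxic(dr, 1000.0))
        ex = cytotox.select_exemplar(labels, set(), dr)
        assert ex.concentration == DOSE_GRID[6]
        assert ex.provenance == "first_cytotoxic"

    def test_no_cytotoxicity_takes_limit_dose(self):
        dr = make_series([1000] * 15)
        labels = cytotox.flag_cytotoxic(dr, 1000.0)
        ex = cytotox.select_exemplar(labels, set(), dr)
        assert ex.concentration == DOSE_GRID[14] == pytest.approx(1e-3)
        assert ex.provenance == "highest_concentration"

    def test_mask_truncates_to_next_lower_concentration(self):
        dr = make_series([1000] * 15)
        labels = cytotox.flag_cytotoxic(dr, 1000.0)
        ex = cytotox.select_exemplar(labels, {DOSE_GRID[10]}, dr)
        assert ex.concentration == DOSE_GRID[9]
        assert ex.provenance == "highest_after_mask"

    def test_masking_everything_is_undetermined(self):
        dr = make_series([1000] * 15)
        labels = cytotox.flag_cytotoxic(dr, 1000.0)
        assert cytotox.select_exemplar(labels, {DOSE_GRID[0]}, dr) is None

    def test_exemplar_monotone_under_added_masking(self):
        dr = make_series([1000] * 8 + [200] * 7)
        labels = cytotox.smooth_labels(cytotox.flag_cytotoxic(dr, 1000.0))
        masked = {DOSE_GRID[13]}
        prev = cytotox.select_exemplar(labels, masked, dr).concentration
        for idx in (12, 9, 5, 2):
            masked.add(DOSE_GRID[idx])
            ex = cytotox.select_exemplar(labels, masked, dr)
            conc = ex.concentration if ex else 0.0
            assert conc <= prev
            prev = conc


class TestPrecipitationDetection:
    def test_anecdotal_jump_masked(self):
        # 50 -> 15,000 MN/well between adjacent doses
        dr = make_series([1500] * 15, mn_counts=[50] * 10 + [15000] * 5)
        masked = cytotox.detect_precipitation(dr)
        assert DOSE_GRID[10] in masked

    def test_smooth_genotoxic_rise_not_masked(self):
        mn = [int(45 * 3 ** (i / 14)) for i in range(15)]
        dr = make_series([1500] * 15, mn_counts=mn)
        assert cytotox.detect_precipitation(dr) == set()

    def test_exact_jump_factor_is_inclusive(self):
        dr = make_series([1500] * 3, mn_counts=[10, 120, 1200])
        masked = cytotox.detect_precipitation(dr, jump_factor=10.0,
                                              mn_floor=1000.0)
        assert masked == {DOSE_GRID[2]}  # 1200 == 10 x 120, above floor

    def test_below_floor_never_masked(self):
        dr = make_series([1500] * 3, mn_counts=[5, 500, 999])
        assert cytotox.detect_precipitation(dr) == set()

    def test_matches_direct_rule_evaluation(self):
        mn = [40, 50, 45, 60, 5000, 4000, 52000, 30, 29, 1500]
        dr = make_series([1500] * 10, mn_counts=mn)
        expect = {DOSE_GRID[i] for i in range(1, 10)
                  if mn[i] >= 1000 and (mn[i - 1] == 0
                                        or mn[i] >= 10 * mn[i - 1])}
        assert cytotox.detect_precipitation(dr) == expect
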