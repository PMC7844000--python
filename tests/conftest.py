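import numpy as np
import pytest

from mnscreen.plate_io import DoseResponse, WellRecord
from mnscreen.synth import DOSE_GRID


def make_well(plate_id="PLATE-01", well="A1", role="test", compound_id="CPD-001",
              concentration=1e-6, replicate_id=1, cell_count=1500, mn_count=45,
              kt_pos_mn_per_cell=0.01, h2ax_foci_per_nucleus=1.0,
              pan_h2ax_fraction=0.02, micronucleated_cell_fraction=None,
              masked=False, **extra) -> WellRecord:
    """Construct a consistent WellRecord with minimal boilerplate."""
    if role == "dmso":
        compound_id, concentration = "DMSO", None
    mn_per_cell = mn_count / cell_count if cell_count else 0.0
    if micronucleated_cell_fraction is None:
        micronucleated_cell_fraction = min(1.0, mn_per_cell)
    return WellRecord(
        plate_id=plate_id, well=well, role=role, compound_id=compound_id,
        concentration=concentration, replicate_id=replicate_id,
        cell_count=cell_count, mn_count=mn_count, mn_per_cell=mn_per_cell,
        micronucleated_cell_fraction=micronucleated_cell_fraction,
        kt_pos_mn_per_cell=kt_pos_mn_per_cell,
        h2ax_foci_per_nucleus=h2ax_foci_per_nucleus,
        pan_h2ax_fraction=pan_h2ax_fraction, masked=masked, extra=dict(extra))


def make_series(cell_counts, mn_counts=None, compound_id="CPD-001",
                replicate_id=1, plate_id="PLATE-01") -> DoseResponse:
    """Build a 15-point dose series on the standard grid."""
    n = len(cell_counts)
    concs = DOSE_GRID[:n]
    if mn_counts is None:
        mn_counts = [int(0.03 * c) for c in cell_counts]
    # distinct rows keep positions valid and unique (A1, A2, ...)
    wells = [make_well(plate_id=plate_id, well=f"B{i + 1}",
                       compound_id=compound_id, concentration=concs[i],
                       replicate_id=replicate_id, cell_count=cell_counts[i],
                       mn_count=mn_counts[i])
             for i in range(n)]
    return DoseResponse(compound_id, replicate_id, wells)


@pytest.fixture
def well_factory():
    return make_well


@pytest.fixture
def series_factory():
    return make_series


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
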