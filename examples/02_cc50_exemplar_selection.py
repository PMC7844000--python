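"""CC50 exemplar selection on a hand-built dose series.

Shows the cytotoxicity rule (observed/expected cell ratio <= 0.5),
flanked-singleton label smoothing, and precipitation masking with
truncation to the highest remaining concentration.
"""

from mnscreen import (detect_precipitation, flag_cytotoxic, select_exemplar,
                      smooth_labels)
from mnscreen.plate_io import DoseResponse, WellRecord
from mnscreen.synth import DOSE_GRID

# cell counts: healthy up to 1 µM, an isolated dip at index 5, real
# cytotoxicity from index 10; MN counts jump 50 -> 15000 at index 13
cells = [1500, 1480, 1520, 1450, 1500, 600, 1400, 1350, 1300, 1200,
         700, 400, 200, 150, 100]
mn = [45] * 13 + [15000, 16000]
wells = [WellRecord("P1", f"B{i + 1}", "test", "CPD-X", DOSE_GRID[i], 1,
                    cells[i], mn[i], mn[i] / cells[i],
                    min(1.0, mn[i] / cells[i]), 0.01, 1.0, 0.02)
         for i in range(15)]
dr = DoseResponse("CPD-X", 1, wells)

labels = flag_cytotoxic(dr, expected=1500.0)
print("raw labels:     ", [lbl[0] for lbl in labels.labels])
labels = smooth_labels(labels)
print("smoothed labels:", [lbl[0] for lbl in labels.labels])

masked = detect_precipitation(dr)
print("masked concentrations:", sorted(f"{c:.3g}" for c in masked))

exemplar = select_exemplar(labels, masked, dr)
print(f"exemplar: {exemplar.concentration:.3g} M ({exemplar.provenance})")
# the isolated dip at index 5 is smoothed away; the precipitation jump at
# index 13 truncates the series, so the exemplar is the highest
# concentration below the solubility limit.
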