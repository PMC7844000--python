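"""Simulate a small IVM screen and run the full three-step analysis.

Generates a 384-well-plate screen (4 negatives, 4 aneugens,
4 clastogens, duplicate 15-point dose series plus plate controls), runs
CC50 exemplar selection -> micronucleus fold flagging -> mechanism
scoring -> cell-cycle profiling, and scores the calls against the
simulation's ground truth.
"""

from mnscreen import ScreenScenario, evaluate, run_screen, simulate_screen

scenario = ScreenScenario(n_negative=4, n_aneugen=4, n_clastogen=4,
                          cells_per_well_cap=200)
dataset = simulate_screen(scenario, seed=7)
print(f"{len(dataset.wells)} wells on {dataset.metadata['n_plates']} plates, "
      f"{len(dataset.cells)} nuclei")

result = run_screen(dataset.wells, dataset.cells)
for c in result.compounds:
    cc = (f" G1={c.cellcycle.g1:.2f} G2={c.cellcycle.g2:.2f}"
          if c.cellcycle else "")
    print(f"{c.compound_id}: fold={c.fold_change:.2f} "
          f"genotox={c.genotox_category} mechanism={c.mechanism_label}{cc}")

summary = evaluate(result, dataset.truth)
print(summary.confusion)
print(f"accuracy={summary.accuracy:.2f} mcc={summary.mcc:.2f}")
# fold is micronucleus induction over the plate solvent baseline at the
# CC50 exemplar; accuracy/MCC compare mechanism calls with ground truth.
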