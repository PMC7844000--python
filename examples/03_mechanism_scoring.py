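"""Mechanism scoring against plate-control Gaussians.

Fits the aneugen-control Gaussian (kinetochore-positive MN per cell,
SD widened 3x) and converts hallmark values into bounded scores: 1.0 at
or above the control mean, the PDF-over-max-PDF ratio below it.
"""

import numpy as np

from mnscreen import call_label, fit_control_gaussian, mechanism_score

rng = np.random.default_rng(0)
control_f1 = rng.normal(0.040, 0.004, 12)   # 12 Paclitaxel wells
g = fit_control_gaussian(list(control_f1), "F1_kt_mn")
print(f"control Gaussian: mu={g.mu:.4f}, 3xSD={g.sigma_scaled:.4f}")

for label, x in [("colchicine-like (above mean)", 0.055),
                 ("weak aneugen (1 scaled SD below)", g.mu - g.sigma_scaled),
                 ("clastogen-like (near solvent)", 0.010)]:
    print(f"{label}: F1={x:.4f} -> aneugen score {mechanism_score(x, g):.3f}")

print("call for scores (1.0, 0.04):",
      call_label(1.0, 0.04, genotox_category="positive"))
# scores are likelihood ratios under the widened control Gaussian; a
# compound matching the aneugen-control phenotype scores exactly 1.0.
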