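# Methods

## Scope and data model

`mnscreen` operates on post-segmentation feature tables, one row per
well, as produced by high-content image-analysis platforms after
micronucleus and foci detection: cell count, MN count, MN per cell,
micronucleated-cell fraction, kinetochore-positive MN per cell (F1),
γH2AX foci per nucleus (F2) and a pan-γH2AX fraction carried as a
passthrough feature only (its biology is out of scope). Concentrations
are molar; a series is one compound × replicate at 15 concentrations
held on a single plate so that all normalization anchors (solvent
baseline, control Gaussians, cell-cycle model) are intra-plate.
A cell table carries single-nucleus integrated Hoechst intensities in
arbitrary units.

Column names are this package's own dialect; `read_well_table` accepts
a column map for other exports. `mn_per_cell` in a well with zero cells
is defined as 0 and the well is flagged unusable for fold-change work,
preserving its cytotoxicity signal while avoiding a division by zero.

## CC50 exemplar selection

Cytotoxicity is threshold-based by design — no IC50 curve fit. The
observed/expected ratio boundary is **inclusive** (≤ 0.5 cytotoxic).
Label smoothing reads the *original* label vector and rewrites only
interior isolated cytotoxic singletons whose both neighbours are
non-cytotoxic; endpoints and runs of ≥ 2 are never touched. Reading the
original vector (rather than cascading in place) makes the operation
order-independent and idempotent.

Precipitation masking flags a concentration when raw MN/well is at
least `jump_factor` (default 10, inclusive) times the previous
concentration's count **and** at least `mn_floor` (default 1000)
MN/well; a jump from zero counts is treated as infinite-fold. The
absolute floor prevents genuine dose-related MN induction (bounded by a
few hundred MN/well at realistic cell numbers) from tripping the
detector, while real precipitate — tens of thousands of spurious
objects — clears it easily. Both thresholds are config keys because
only one anecdotal magnitude is available to calibrate against.
Masking is applied per replicate. When the masked set is non-empty the
lowest masked concentration and everything above it are removed and the
highest remaining concentration becomes the exemplar regardless of the
cytotoxicity labels; consequently the exemplar is monotone
non-increasing as more concentrations are masked *within* the masking
regime (the switch from cytotoxicity-based to mask-based selection can
move it either way, which is inherent to the rule).

## Genotoxicity flagging

Fold change uses `mn_per_cell` by default; the micronucleated-cell
fraction is a config alternative (`genotox_metric`) since both
conventions exist in practice. Boundaries: fold ≥ 3 positive,
2 ≤ fold < 3 borderline, < 2 negative. Exactly 3.0 is resolved as
positive so the three categories partition the fold axis; both
thresholds are configurable. A zero solvent baseline yields +inf with a
warning rather than an error. Replicates aggregate by mean fold with
the category recomputed from the mean; undetermined replicates are
excluded, and an all-undetermined compound stays undetermined.

## Mechanism scoring

Per plate and hallmark, μ and s are the sample mean and sample SD
(ddof = 1) of the control wells' values, and the scoring Gaussian is
N(μ, (3s)²). The 3× widening makes the score a graded similarity
measure rather than a sharp in/out test. The score is computed in
closed form, `exp(-(x-μ)²/(2(3s)²))` below the mean and 1.0 at or above
it, so normalization constants cancel exactly; a `scipy.stats.norm` PDF
ratio serves as an independent oracle in the tests. The score is
invariant under joint affine rescaling of the value and controls, so
unit changes cannot alter it.

Scoring uses the hallmark values of the same exemplar well that
produced the genotoxicity flag. The score→label map — argmax of the
pair, with both ≥ `mixed_threshold` (default 0.5) called mixed, ties
below it undetermined, and genotox-negative compounds forced negative —
is this package's rule; both raw scores are always reported so users
can re-map. Borderline compounds do proceed to mechanism scoring, and
their final evaluation label is their mechanism label.

Constant control values have zero spread and raise an error (with a
pointer to jitter/config) rather than silently producing a degenerate
delta-function scorer.

## Cell-cycle deconvolution

The DNA-content model: G1 nuclei at intensity μ_G1 and G2/M nuclei at
`peak_ratio`·μ_G1 (default 2.0, the 2N→4N position ratio; the ratio is
held fixed during fitting), both Gaussian with one shared noise SD σ;
S-phase mass uniform on [μ_G1, μ_G2]; plus a uniform debris background
over the whole observed range that absorbs Sub-G1 fragments and >4N
events. Without the background term those tails inflate σ by ~50% at a
realistic 2% debris load. The stored component weights (G1, S, G2) sum
to ≤ 1, the residual being the background mass.

The objective is the exact binned negative log-likelihood on a 256-bin
histogram (bin masses via Gaussian CDF differences and uniform
overlaps), minimized by Nelder–Mead over (log μ_G1, log σ, and three
weight logits) simultaneously. Initialization is deterministic:
μ_G1 from the histogram mode — evaluated both as the G1 peak and as the
G2 peak (mode/ratio), keeping the better optimum, so G2-dominant
(arrested) cultures initialize correctly — σ = 0.1·μ_G1, weights from
coarse ±2σ band counts. No random restarts; refits on identical data
are bit-identical. Non-convergence raises an error carrying the
best-so-far parameters. Fewer than 200 cells triggers a warning.

Classification bands, with k = `band_width_sd`·σ (default 2σ):
x < μ_G1−k → Sub-G1; |x−μ_G1| ≤ k → G1; strictly between the bands →
S; |x−μ_G2| ≤ k → G2; x > μ_G2+k → >4N. Band-edge ties resolve to the
peak class per the "within two SDs" convention, and the bands partition
the line whenever μ_G2−μ_G1 > 2k (otherwise classification raises: the
S band is undefined). The model is fitted on solvent-control cells per
plate and then applied to treated wells.

Recovery is validated by comparing phase fractions obtained under the
fitted parameters with those obtained under the generating parameters
on the same cells. This isolates fit error from band bias: the 2-SD
band rule *deliberately* assigns the ~4.6% of each Gaussian peak
outside ±2σ, and all S-phase mass within 2σ of a peak, to neighbouring
phases, so band-classified fractions differ from true mixture weights
by a known, rule-intrinsic amount that no fitting procedure should be
penalized for. Direct parameter recovery (μ_G1 within 2%, σ within 10%
at n = 5000) is checked separately.

## Synthetic screen generator

The generator emulates the assay's structure, not its images. Defaults
(chosen once, as the study conditions the pipeline assumes):

- Plate layout: 14 DMSO + 12 aneugen-control + 12 clastogen-control
  wells per 384-well plate; 15-point dose grid geomspace(1e-9, 1e-3) —
  15 points at ratio 10^(6/14), honouring both the stated point count
  and range (strict half-log steps over six decades would give 13
  points); the grid is recorded in the metadata sidecar.
- Solvent baseline: 1500 cells/well (≈ one doubling of 750 seeded
  cells over 48 h), endogenous MN frequency 0.03 per cell, endogenous
  F1 = 0.01 kt⁺ MN/cell and F2 = 1.0 foci/nucleus (free parameters —
  solvent levels of the hallmarks are not constrained by the assay
  description), lognormal noise with CV 8% on cell counts and 10% on
  hallmark features, Poisson MN counts given the per-cell rate.
- Cytotoxicity: decreasing Hill curve (EC50 log-uniform 10⁻⁶·⁵–10⁻⁴·⁵ M
  for genotoxic compounds, slope 1.5–3); the genotoxic effect is a
  saturating curve centred at EC50/3 so MN induction and hallmark
  shifts are near-maximal at the CC50 exemplar.
- Effect strengths: genotoxic compounds draw mn_max_fold U(5, 8) and
  hallmark shifts U(3.5, 6)×; plate controls are simulated at full
  effect with 3.5-fold MN induction and 4× hallmark elevation;
  negatives draw mn_max_fold U(1, 1.5) with no hallmark shift.
- Precipitation: 10% of compounds receive a solubility limit in the
  upper dose range; above it the MN count gains a Poisson(15000)
  spurious-object term while the cell count is continuous.
- Hoechst: G1 peak 100 (arbitrary units), noise CV 6%, solvent weights
  (G1, S, G2) = (0.62, 0.16, 0.22) with 1% Sub-G1 and 1% >4N debris;
  aneugens shift mass G1→G2 (mitotic arrest) and clastogens G1→S plus
  an apoptotic Sub-G1 increase, scaled by the dose effect.

What the generator does **not** emulate: segmentation failure modes,
plate-edge and spatial gradients, well-to-well carry-over, S9
metabolism, and compound-specific cell-cycle signatures beyond the
class-level shifts. Passing tests therefore demonstrate that the
decision rules are implemented exactly and that the workflow recovers
class structure under its own assumptions — not field performance on
real screens, which depends on assay calibration quality.

## Determinism and evaluation

All stochasticity lives in the generator behind explicit integer
seeds; the pipeline itself is deterministic, and reports serialize
numerics at 6 significant digits so identical inputs give byte-identical
files. Evaluation uses accuracy and the multiclass Matthews correlation
coefficient (confusion-matrix correlation form, via scikit-learn, with
a direct-formula oracle in the tests); undetermined compounds are
excluded from the matrix and reported as a count, and mixed-class
handling (own class vs excluded) is a config switch. Test and
validation runs here use screens of 12–15 compounds in duplicate
(2 plates, with per-well cell tables capped at 150–200 nuclei), sizes
at which every stage of the workflow, including per-plate cell-cycle
fits, is exercised in seconds.

## Known limitations

- The precipitation detector sees only adjacent-dose jumps; gradual
  precipitation ramps would evade it.
- Mechanism scores depend on control-well spread; unusually tight
  controls make the scorer harshly selective, and plates with
  degenerate (constant) controls yield undetermined mechanisms rather
  than a fallback score.
- The cell-cycle S component is uniform; real S-phase DNA synthesis
  profiles are not flat, which biases the fitted S weight slightly on
  real data.
- The exemplar concentration reported per compound is the highest
  determined replicate exemplar; replicate exemplars can differ by a
  dose step, and downstream aggregation happens at the fold/score
  level, not the concentration level.
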