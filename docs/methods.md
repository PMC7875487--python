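# Methods

## The measurement problem

Knocksideways experiments acutely reroute an FKBP-tagged protein from its
native location — here the mitotic spindle — to mitochondria, by adding
rapamycin to cells that express a mitochondrially anchored FRB domain
(MitoTrap). Quantifying the experiment means answering, per cell: how much
of the tagged protein (and of a co-expressed partner protein in a second
channel) left the spindle, and where did it go?

knockscope implements the measurement chain for paired pre/post-rapamycin
frames of a two-channel movie:

1. **Registration.** The post frame is aligned to the pre frame by an
   integer-pixel translation that maximizes normalized cross-correlation
   over a ±10 px search (`register_translation`). Ties are broken by
   smallest shift magnitude, then lexicographically. Inside `measure_cell`
   the correlation is evaluated on the thresholded cell footprint of the
   target channel rather than raw intensities: rerouting moves intensity
   from the spindle to the mitochondria, so raw pre/post frames can be
   nearly uncorrelated at the true alignment, while the cell footprint is
   unchanged by internal redistribution. The footprint is the pixels above
   the lower of the two 3-class Otsu thresholds (frames are roughly
   trimodal: extracellular background, cytoplasm, bright organelle).
2. **ROI measurement.** Three square ROIs per compartment (spindle,
   cytoplasm, mitochondria), combined by unweighted mean of the three ROI
   means; one background box outside the cell; one whole-cell box. ROI
   sizes default to 15×15 px for spindle and cytoplasm and 5×5 px for the
   thin mitochondrial tubules in movie mode, and to 31×31 px (1.4 µm² at
   0.0382 µm/px) in fixed-cell mode. The movie-mode sizes are package
   defaults, not a claim about the original protocol, which does not state
   them.
3. **Background subtraction, then bleach correction.** Every compartment
   and whole-cell mean has the background mean subtracted first; negative
   differences are floored at zero with a warning (intensities are
   physical). Each post value is then divided by the whole-cell decay
   factor `wholecell_t / wholecell_0` of its own channel, normalizing to
   the pre-rapamycin frame. This makes corrected compartment means of a
   noiseless bleached-but-untransferred movie constant in time to better
   than 1e-6 relative (tested).

## Statistics

- **Spindle fraction** `f = spindle / (spindle + mito)` on the corrected
  mean intensities: 1 = fully spindle-localized, 0 = fully mitochondrial.
  Per-cell (f_pre → f_post) pairs for target (x) and partner (y) channels
  form the arrow plot; the mean arrow and a two-sided paired Student
  t-test per channel summarize a cohort. The t statistic is computed from
  the classical formula `t = mean(d)/(sd(d)/√n)`, df = n−1, and is
  cross-checked against an independent library implementation in the test
  suite. No multiple-testing correction is applied across conditions.
- **Ternary composition** divides the three corrected compartment means by
  their sum, placing each measurement on the 2-simplex (checked exact to
  1e-12). Compositions are mean-intensity based, consistent with the ROI
  measurements they derive from.
- **Relocalization efficiency**: a cell counts as relocalized when its
  target-channel spindle fraction drops by at least 0.3 (absolute). The
  original scoring was by inspection; 0.3 is an explicit, exposed
  threshold calibrated so that complete-transfer simulations score 100%,
  and sits far from both failure modes (complete transfer gives drops
  ≈0.9, no transfer gives |Δf| < 0.05 at default noise).
- **Spindle-localization score** (fixed cells): log2 of the
  background-subtracted spindle/cytoplasm ratio, so 0 = no enrichment,
  +1 = twice, −1 = half. Antisymmetric under swapping compartments and
  invariant to adding a constant offset to image and background (both
  property-tested).
- **Line-scan enrichment**: mean intensity along three 1–3 µm lines on
  microtubules over three adjacent control lines, both background-
  subtracted. Lines are rasterized by a standard integer line walk at
  1-pixel width; the original method's line width is unstated and 1 px
  matches the line-scan tools it adapted. The same extracellular
  background measurement is assumed for both line groups.
- **Group comparisons**: one-way ANOVA followed by Tukey HSD (delegated to
  scipy/statsmodels), reported against a designated reference group (WT)
  with tiers *** p<0.001, ** p<0.01, NS p>0.05; the band 0.01–0.05, which
  the figure conventions leave undefined, is encoded "*".
- **Mitotic timing**: per-cell NEB→metaphase and NEB→anaphase intervals
  with movie-end censoring (12 h movies, 3 min frame interval by default).
  Cumulative histograms keep censored cells in the denominator, so curves
  plateau at the exit fraction. Medians are over observed transitions
  only — consistent with reporting a median alongside an exit percentage —
  and are flagged unreliable when more than half the cohort is censored.
  The fold delay is the treated/control ratio of median NEB→anaphase times.

## The synthetic-data generator

Because raw images are not redistributable, every stage is validated on
synthetic data with attached ground truth.

**Geometry.** A metaphase cell is a 20 µm disc in a 25.6 µm field
(256×256 px at 0.1 µm/px; the fixed-cell preset uses 512×512 px at
0.0382 µm/px, the pixel size implied by a 31×31 px = 1.4 µm² ROI). The
spindle is a central ellipse with 2.2 × 5.5 µm semi-axes. Mitochondria are
8–15 curvilinear ribbons (persistent random walks, 4–10 µm long, 5 px
wide with a square cross-section) confined to the cytoplasm and clear of
the spindle. The ribbon width and length were chosen so that (a) a 5×5
mito ROI fits entirely inside a ribbon anywhere along its path (a point
dilated by a k×k square contains a k×k box), and (b) the mitochondrial
area is comparable to the spindle area, as in real cells with extensive
mitochondrial networks — this is what keeps the cytoplasmic share of
mean-intensity ternary compositions nearly constant during transfer.
Optional coated-pit-like puncta (off by default) act as decoy structures
for ROI-placement stress tests.

**Kinetics.** Transfer follows a single exponential
`phi(t) = phi_max (1 − exp(−t/tau))` with defaults phi_max = 0.95 and
tau = 2 min, so transfer is >99% of its asymptote by 10 min — the
simplest kinetics consistent with rerouting being complete on that
timescale. Observed timecourses vary between proteins; no per-protein
kinetics are modeled, only the single exposed tau. The partner channel
transfers `coupling × phi(t)` with coupling ∈ [0, 1] (1 = full
co-rerouting, 0 = none). Transfer conserves integrated fluorescence: the
spindle loses `phi` of its initial amplitude and the mitochondria gain the
same integrated amount spread over their area (conservation is exact to
1e-12 relative in noiseless renders, tested).

**Image formation.** Per channel: uniform extracellular background plus
per-compartment amplitudes (defaults, in a.u. — target: spindle 150,
cytoplasm 30, mito 10, background 5; partner: 100/40/20, background 8);
the whole frame is multiplied by `exp(−bleach_rate t)` (default
0.02 min⁻¹ per channel); additive Gaussian noise (default sd 3 a.u.) is
applied last. A shot-noise-like option (variance proportional to the
mean) exists; Gaussian is the default for analytic tractability. All
randomness flows from one explicit integer seed per generator call;
identical seeds give bit-identical output.

**Timing cohorts.** Log-normal NEB→metaphase and metaphase→anaphase
intervals parameterized by median and log-sd shape (defaults 13.2 min and
20.8 min, shape 0.35 — untreated HeLa-like values), a multiplicative
`delay_factor` on the metaphase→anaphase interval, an `arrest_prob` of
never exiting metaphase, and censoring at the 720 min movie end.

**Line-scan scenes.** Straight filaments (4 µm, 3 px wide) with a probe
channel set to `background + r_true × base` on filaments and
`background + base` off them, so the noiseless measured ratio is exactly
`r_true`. Measured-line endpoints are taken from the rasterized filament
centerline; control lines are parallel offsets verified to clear every
filament.

**What the generator does not emulate.** No point-spread function or
optics model, no 3-D stacks, no spatial intensity gradients or flat-field
error, no cell-to-cell amplitude variability beyond the seed, no moving
organelles, and no cytoplasmic intermediate during transfer. Passing the
recovery suites therefore shows the measurement chain is correct and
unbiased under the stated image model; it does not certify performance on
real microscopy, where segmentation quality, focus drift and non-uniform
background dominate error budgets.

## Numerical and design notes

- Images are float64 end to end; TIFF round-trips are bit-identical.
- Coordinates are 0-based row-major; ROI boxes are half-open
  `[r0, r0+h) × [c0, c0+w)`.
- Registration tie-breaks: smallest Euclidean magnitude, then
  lexicographic (dr, dc); constant images are rejected as degenerate.
- Whether the original automated routine averaged ROI means or pooled
  pixels is unstated; the unweighted mean of the three ROI means is used.
- The whole-cell measurement uses the cell bounding box; including
  background pixels dilutes the mean but cancels exactly in the bleach
  ratio when the background is uniform.
- Degenerate inputs raise typed errors (`DegenerateInputError`,
  `PlacementError`, ...) rather than returning NaN, except the paired
  t-test on zero-variance differences, which reports a degenerate result
  with p = NaN, since that arises in legitimate summaries.

## Problem sizes

Default verification runs use 256×256 px two-frame movies (seconds per
movie), cohorts of 15–28 cells for arrow/efficiency statistics matching
the reported per-line cell counts, 50 scenes for line-scan recovery, and
n = 1000 cells for timing-median recovery (5% tolerance).
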