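# Methods

## Experiment model

An experiment is six wheat genotypes — three parent/NIL pairs — with ten
replicates per genotype × treatment (120 plants).  The control treatment is
watered to 90% plant-available water content (PAWC) throughout; the stress
treatment drops to 30% PAWC on DAS 31 (mild drought) and 20% on DAS 64
(severe drought).  Plants are imaged daily until DAS 95 and every second
day until DAS 121; each plant leaves the platform on its own maturity day.
Temperature phases (12/16, 16/20, 20/24 °C night/day) are carried as design
metadata only; no computation consumes them.  All schedules are keyed on
integer DAS (1-based).

## Image-derived traits

* **EB** (estimated biovolume, voxel = pixel³) is computed as
  `sqrt((mean side area)² × top area)` from the three side-view and one
  top-view projected areas.  This is the dimensional reading of the usual
  side²×top construction — pixel²·pixel² under the square root yields
  pixel³.  EB is reported after division by 10⁶.  When a top view is
  missing, EB is emitted as missing while PH and CVa are still computed
  from the side views.
* **PH** (mm) is (pot-rim row − topmost plant row) × mm-per-pixel from a
  side view; the maximum over the three side views is reported.
* **CVa** pools the three side-view hue histograms (20 equal bins over
  [0,1)) and returns the count-weighted mean of bin centers.  Hue is
  treated linearly, not circularly: plant hues run green (≈0.23) to yellow
  (≈0.12), far from the red wrap point — a documented limitation if the
  package were pointed at imagery with reds.  Whether to pool views or
  average per-view CVa values is not externally fixed; pooling was chosen
  (per-view CVa remains available via `color_value_cva`).
* Segmentation is a hue-window (default [0.04, 0.45]) and saturation
  (≥0.25) threshold with removal of connected components below 4 px and
  exclusion of the pot rows in side views.  This is deliberately simple:
  the package's fixtures are rendered with controlled backgrounds, and any
  real deployment with similar imaging chambers can retune the window.

## Day-wise statistics

Each day × treatment × trait cell is analysed independently; there is no
cross-day model (growth-curve modelling is out of scope).

* **Outliers**: Tukey fences [Q1 − 1.5·IQR, Q3 + 1.5·IQR] per genotype ×
  treatment × day × trait, quartiles by linear interpolation; groups of
  fewer than four values are never filtered.  This is the narrowest
  grouping consistent with fitting each day and treatment separately.
* **BLUEs**: with genotype fixed, the one-way model *Y = μ + G + e* is a
  cell-means model, so the BLUE of a genotype is its replicate mean; the
  standard error is the pooled residual SD divided by √n.
* **Variance components**: the one-way random model *Y = G + e* is fitted
  by REML.  The restricted likelihood is profiled to the variance ratio
  λ = v_G/v_e; λ is located by golden-section search on [0, 10⁷] and then
  polished by a Brent root-find on the analytic score, because a bracketing
  search alone stalls at the floating-point noise floor of the nearly flat
  profiled criterion (~10⁻⁷ relative).  Estimates are truncated at zero.
  On balanced data the interior solution equals the ANOVA closed form
  (v_e = MSE, v_G = (MSB − MSE)/n) to machine precision; when the
  between-genotype signal is too weak, both truncate v_G to 0, and the
  profiled residual variance is then the total variance SST/(N−1) —
  matching lme4/MixedLM, not the ANOVA MSE.
* **Repeatability**: R = v_G/(v_G + v_e/n_Rep).
* **Pairwise tests**: Student's pooled-variance two-sample t-test, two
  sided, α = 0.05.  Groups are equal-sized by design and the published
  p-values are consistent with the pooled form; Welch is available behind
  a flag.  No multiple-testing correction is applied across days, matching
  how such per-day tests are conventionally reported; this inflates the
  family-wise error over the 100+ day series and is the reason onset
  detection requires sustained significance (below).
* **Confidence bands**: BLUE ± t(1−α/2, df)·SE, with the non-overlap rule
  read one-way: disjoint bands imply a significant difference; overlapping
  bands imply nothing.

## Timing metrics

* **Divergence onset**: the earliest imaging day from which the per-day
  p-value is ≤ α for `sustain_k = 3` consecutive imaging days.  Sustained
  significance defines the onset because single-day significance occurs by
  chance and replicate deviations persist across days.  The control-vs-
  stress scan starts at the first reduced-watering day: before it the
  "treatments" are the same condition.
* **Response lag** between two units is the difference of their onsets.
* **Maturity day**: the largest DAS on which at least ⌈quorum·n⌉
  replicates (default 7/10) were still on the platform.
* **Senescence onset**: the first day at which a centred 3-point median of
  CVa drops below (early-season baseline − δ) and never recovers.  With
  the sensitive default δ = 0.02 the detector fires near the start of hue
  decay; calibrating δ to half the green→mature span makes the detected
  day coincide with the logistic midpoint parameter of the generator,
  which is what the recovery checks use.
* **Stay-green score**: mean CVa advantage of one genotype over another
  across a late-season window plus the per-day significant days.

## Maturity traits

WUE = biomass/water sum (g/l); flag-leaf area = length × width × 0.75 with
width converted mm→cm; tiller gain = late − early count.  Harvest index is
computed per plant and averaged; its definition (grain/biomass vs
grain/(grain+straw)) is configurable because published HI columns are not
always reconcilable with the printed grain and biomass columns.
Treatment-effect percentages weight genotypes equally (mean of genotype
means); with balanced data this equals the plant-level mean.  Percentages
are rounded half-away-from-zero only in the reporting layer.

### Transcribed reference tables

The package ships transcriptions of a published parent/NIL comparison
(mean ± sd of n = 10 plants per cell, two-decimal p-values with bold
significance marks).  Three cells carry obvious decimal misprints
("1,251" for 12.51 g); a repair rule divides any value exceeding 50× its
trait-column median by 100 and flags the cell.  When re-testing the printed
significance pattern from these summaries, three kinds of cell are
excluded as undecidable at the printed precision: repaired cells, cells
printed exactly "0.05" (either side of α rounds to it), and cells whose
implied standard error of the mean difference is below four print quanta
(0.04) — there two-decimal rounding of the means dominates the
t-statistic.  All remaining cells (215 of 269) reproduce the printed
pattern exactly.

## Synthetic data generator

Per genotype × treatment, EB follows a logistic
`A/(1+exp(−r(t−m)))` (r = 0.18/day; m two days before the genotype's
heading day) with an exponential ripening decline (0.03/day from five days
after heading); with these defaults peak EB falls ~7 days after heading.
PH uses a shallower logistic (0.12/day, midpoint 12 days before heading)
so seedlings have a few cm of height and final height settles shortly
after heading.  CVa decays logistically from green (0.23) to mature yellow
(0.12) with its midpoint at the senescence-onset parameter; stress onsets
are 18 days earlier, and the stay-green NILs senesce several days later
than their parents.

Drought multiplies EB by
`1 − (1−m_d)·smoothstep((t − onset − lag)/14)` — a smooth ramp to the
genotype's asymptotic stress/control ratio (0.37–0.51) beginning a
genotype-specific lag (0–7 days) after the watering step-down.  Both
treatments share identical trajectories before the ramp (the asymptotes
and inflections are anchored on the control heading day), so pre-drought
the treatments are statistically exchangeable, as they must be.  The
14-day ramp makes the response lag a cleanly recoverable parameter while
statistical divergence still emerges several days after the step-down.
PH feels a genotype-calibrated fraction of the drought effect so its
asymptote matches the observed stress/control height ratio.

Replicates apply multiplicative Normal(1, CV) noise (CV = 8%) to the
asymptotes, day-to-day measurement noise of 3% (EB), 1.5% (PH) and 0.004
hue (CVa), and draw removal days from Normal(maturity mean, sd) clipped to
the platform period.  Harvest traits are drawn per plant from per-genotype
Normal distributions whose means/sds mirror the published harvest table
(water sums under stress about a third of control); a `yield_coupling`
switch scales them by the plant's realized size factor to induce an
EB↔biomass correlation, and defaults to independent draws.

Rendered views are 150×200 px at 5 mm/px: a low-saturation background and
pot band, and plant pixels selected as the exactly-N nearest pixels to a
fan of culm segments (side views; a spike thickens the culm top after
heading, and pixels above the culm tip are excluded so drawn height equals
modelled height) or to a lobed rosette metric (top view).  Exact pixel
counts make truth areas strictly monotone in the modelled biovolume.
Plant hue is jittered (sd 0.008) around the modelled CVa.

What the generator does *not* emulate: leaf-level architecture, occlusion
and self-shadowing, soil/pot water dynamics, spatial greenhouse gradients
and the associated re-randomization, heteroscedastic sensor noise, and
correlated day-to-day weather effects.  Passing the image-fidelity checks
therefore demonstrates correctness of the extraction chain on controlled
imagery, not segmentation robustness on real greenhouse images; passing
the recovery checks demonstrates that the statistics recover the
generator's effects at realistic noise levels, not that real experiments
will show them.

## Problem sizes and numerical choices

The test suite and the acceptance script run the full trait-level design
(120 plants, 108 imaging days) for statistics checks, a reduced rendered
design (2 pairs × 2 treatments × 5 replicates, every third imaging day)
for image checks, and stride-2 imaging for determinism runs; these sizes
were chosen to keep a complete run at desk scale.  Divergence recovery
uses 20 simulated experiments; REML oracle checks 100 random balanced
tables; coverage and implication checks use 1000 draws.  REML: golden
section 140 iterations plus Brent polish at machine tolerance; boundary
decided by the sign of the score at λ = 0.  Quartiles, t-tests and
t-quantiles come from numpy/scipy.  CSV output uses `%.10g` floats, UTF-8
and `.` decimals regardless of locale, which is what makes byte-identical
reruns possible.

## Known limitations

* The t-test layer reports unadjusted per-day p-values (by design); a
  Benjamini–Hochberg switch would be a natural extension and is not wired
  into the pipeline.
* Hue averaging is linear, not circular (safe for green→yellow only).
* The renderer's Jaccard against truth masks is essentially 1.0 because
  segmentation and rendering share the same color model; it validates the
  pipeline plumbing, not real-world segmentation difficulty.
* Repeatability of CVa before senescence is intrinsically low in the
  generator (genotypes share the green hue), unlike EB/PH; the data-quality
  claim (day-averaged R above 0.85) applies to the growth traits.
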