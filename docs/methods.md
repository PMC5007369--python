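# Methods

## Measurement model

A 2D-GE spot volume is a fluorescence integral over a protein spot.  With
saturation thiol labeling, the Asc+ channel signal of spot *s* for
subject *j* is proportional to the protein amount; the Asc− channel
signal is additionally attenuated by the fraction of the spot's cysteines
carrying S-NO.  We model fluorescence quenching as linear in S-NO
occupancy *q* (signal ∝ unmodified thiol fraction, 1 − *q*).  Published
descriptions of the assay state the quenching only directionally; the
linear form is the simplest consistent model and is what the ratio
arithmetic assumes.

Group contrasts are ratios of geometric means: volumes are
log2-transformed, averaged within group, and back-transformed.  Ratios of
geometric means compose exactly — the ratio of ratios equals the
difference of log2 contrasts — and are consistent with the log-scale
Welch tests used for significance.  Whether the original gel-analysis
software used arithmetic or geometric group means is not documented;
geometric is our choice and is flagged here.

### Signed fold convention

All ratios are reported as signed folds: linear *r* ≥ 1 maps to +*r*,
*r* < 1 to −1/*r*.  The mapping is a monotone bijection and the package
converts losslessly in both directions (`snoquant.folds`).

### Ratio of ratios and the direction call

RoR = ΔS-NO / Δabundance, computed on the linear scale and reported as a
fold.  Because S-NO quenches dye binding, RoR ≤ −t calls S-NO
*increased* and RoR ≥ +t calls it *decreased*, with threshold t = 1.5 by
default.

### The packaged spot table

`snoquant/data/spot_table.tsv` carries 147 annotated spots with printed
two-decimal ΔS-NO, Δabundance and RoR folds.  `verify_table_fixture`
recomputes each row's RoR from its two printed inputs using interval
arithmetic: each printed fold stands for any underlying value within
±0.005 (clipped to the valid fold domain |f| ≥ 1), the implied RoR
interval is widened by the output's own ±0.005 rounding, and the printed
RoR must fall inside.  A flat tolerance would either over- or
under-constrain, since the inputs are themselves rounded.  The table's
`delta_sno_NH` column (a within-NH channel ratio) is carried for
completeness but takes no part in the verification; the printed RoR is
numerically the HF channel column divided by the abundance column.

## Normalization

Gel-to-gel loading, labeling and imaging differences act multiplicatively
on all spots of a gel.  Assuming most spots unchanged, the mean
natural-log ratio of a gel to a common reference estimates that bias, and
the gain factor `exp(−mean log-ratio)` recentres it at zero.  The mean
(rather than median) matches the "adjust the mean spot ratios to 0"
behaviour of standard gel software; a trimmed-mean option (`trim`,
default 0) covers the robust "most spots unchanged" reading without
asserting either.  Zero volumes are excluded from bias estimation (log
undefined) but still scaled.  The reference gel is the one with the most
nonzero spots; ties fall to the highest median Spearman correlation of
log-volumes with all other gels, then to the lexicographically first gel
id.  One common reference serves all groups and channels.

## Differential statistics

Per spot and channel: log2 group means and SDs (sample SD, n−1), CoV
computed on the raw scale (SD/mean of back-transformed volumes, since CoV
of a log2 mean near zero is ill-defined), Welch's t with
Welch–Satterthwaite degrees of freedom, and Benjamini–Hochberg step-up
q-values across spots.  Spots with fewer than two positive volumes in a
group are reported NA and excluded from the multiplicity count.
Degenerate inputs follow fixed conventions: zero pooled variance with
equal means gives p = 1; with unequal means p → 0 with a warning.

Selection is the joint rule |fold| ≥ threshold AND (q or p) < α.  Two
named presets reflect the two uses of the screen: `discovery`
(|fold| ≥ 1.5, BH q < 0.05) for nominating spots, and `mars_input`
(|fold| ≥ 1.5, BH q < 0.001) for choosing classifier features.  Published
descriptions of this workflow are internally inconsistent about whether
the discovery cut uses raw or adjusted p; both are supported
(`use_adjusted`) and the BH-adjusted form is the default.  Abundance
significance tests the Asc+ channel with the Asc+ fold; S-NO significance
tests the Asc− channel with the |RoR| fold, and direction comes from the
RoR sign.  Venn classification partitions the selected spots into
abundance-only, S-NO-only and both.

## MARS classifier

Classification is least-squares MARS on 0/1 labels (score threshold 0.5),
the classic formulation; no logistic link.  The forward pass adds, at
each step, the reflected hinge pair max(0, x−k)/max(0, k−x) over all
variables and all observed knot values that maximally reduces the RSS,
implemented by projecting candidate columns onto the orthogonal
complement of the current column space (so each step is exactly the
brute-force optimum; the equivalence is tested).  Candidate knots are all
observed values — no minspan thinning, appropriate for cohort-sized n; a
rank-deficient candidate column is dropped.  `max_bases` counts hinge
terms (the intercept is free) and defaults to the number of features,
mirroring the convention of allowing as many basis functions as input
spots.

The backward pass deletes the weakest basis (smallest RSS increase)
iteratively and returns the model of the nested sequence minimising

    GCV = (RSS/n) / (1 − C/n)²,   C = #coefficients + penalty·#knots,

with penalty 2 (standard for additive models) and #knots the distinct
(variable, knot) sites — a reflected pair shares its knot.  Models with
C ≥ n are skipped with a warning.  "1 max interaction term" is read as
degree 1 (purely additive); `max_interaction` exposes higher degrees.

Variable importance is the GCV increase caused by removing all of a
variable's bases, rescaled so the top variable scores 100; absent
variables score 0.  Validation schemes: stratified 10-fold CV with
out-of-fold scores pooled into one test ROC (the train ROC comes from the
full-data fit), and a stratified 80/20 split.  The fold count is capped
at the minority class size.  ROC/AUC come from scikit-learn and equal
Mann–Whitney concordance with ties counted 1/2 (checked against an O(n²)
oracle).  Note that a *single* permuted-label AUC is not 0.5: when the
model separates the true groups well, it is close to the permutation's
chance agreement with the true labels (SD ≈ 0.08 at n = 60), so
chance-level checks average over permutations.

## Synthetic gel sets

The generator emulates the split-sample design: per spot, a baseline
intensity log-uniform over three orders of magnitude (10⁴–10⁷ AU); per
subject, a shared biological log-normal factor (`biological_cov`, default
0.15 — between-subject variation is not separable from technical noise in
published summaries, so it is exposed as its own parameter); per gel, a
log-normal bias `exp(N(0, bias_log_sd²))` (default 0.2); per volume,
mean-one log-normal technical noise with σ² = ln(1 + CoV²) so the
coefficient of variation equals `technical_cov` (default 0.09, the
reported triplicate CV of the assay).  Volumes are positive by
construction, matching the multiplicative error structure of fluorescence
data; `missing_frac` can zero a random fraction to exercise degenerate
handling.

Defaults mirror the study design being emulated: 30 subjects/group, 635
spots, ~15% abundance-affected (2-fold, alternating up/down) and ~17%
S-NO-affected (occupancy shift 0.3 on a 0.2 baseline, alternating
direction).  A "decreased" S-NO spot carries the elevated occupancy in
the NH group — this keeps occupancies in [0, 1) and keeps the planted
directions balanced, as observed in real cohorts; one-sided planting
would bleed into the per-gel bias estimate and attenuate every RoR.
All draws flow through one seeded numpy generator: identical configs give
bit-identical gel sets.

What the generator does *not* emulate: spatial gel artifacts, spot
overlap and mis-segmentation, saturation at the imager's ceiling,
missing-not-at-random spots, and correlated biology across spots
(proteoforms of one protein).  Passing tests therefore demonstrate the
statistical machinery under the stated error model, not robustness to
image-level pathologies.

## Numerical choices and problem sizes

* Fixture verification uses interval arithmetic (above); display rounding
  is half-even to two decimals.
* Bias factors require ≥ 3 spots positive in both gel and reference.
* Forward-pass acceptance requires an RSS reduction ≥ 1e-8 of the initial
  RSS; ties in reference selection and basis deletion resolve to the
  first candidate in a fixed order.
* The replicated checks run at study scale where it matters: null
  calibration uses 30 vs 30 subjects × 500 spots (200 replicates in the
  test suite, 100 in the acceptance script); recovery uses 30 vs 30 × 200
  spots over 50 (tests) or 25 (script) replicates — spot count reduced
  from 635 since power is per-spot and the multiplicity correction sees
  hundreds of tests either way.

## Known limitations

* The RoR is computed from group-level ratios, as the workflow it
  implements does; a per-subject paired RoR would use the split-sample
  pairing more efficiently but is not the reference method.
* Least-squares MARS scores are not calibrated probabilities; only their
  ranking (ROC/AUC) is interpreted.
* With GCV penalty 2, pure-noise fits at n ≈ 60 occasionally retain a few
  hinge terms after pruning; penalty 3 prunes to intercept-only but is
  not the additive-model default.
* Knot recovery is as good as the RSS-optimal estimator allows: at noise
  σ = 0.01 and n = 200 the optimal knot can sit one or two data values
  away from the true break.
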