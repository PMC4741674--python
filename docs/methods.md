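# Methods

## Scope and data model

The package operates on serum antibody profile matrices: samples ×
array components, with separate IgG and IgM channels, on a log2
relative-fluorescence-unit (RFU) scale.  All thresholds are defined on
that scale; linear-scale input must pass through `log2_normalize`
(`log2(max(raw, floor))`), and the container tracks its scale so the
transform cannot be applied twice.  Component names are opaque join
keys — matching is exact and case-sensitive after whitespace
normalisation around hyphens, because printed component tables contain
spacing variants (`BG-B2-Sp - 05` vs `BG-B2-Sp-05`) and silent
mis-joins are worse than strict failures.  Name parsing
(`BG-<det><chain>-<linker>-<density>`, plus the Globo, 2′F and A-LeB
families) extracts determinant class, chain type 1–6, linker and
density; densities below 8 glycans per carrier are classed low.  One
published listing of the flow-chart panel names BG-A2-Oct-17 where
another names BG-A2-Oct-16; the -16 reading is canonical here and the
variant is accepted with a warning.

## Typing logic

A threshold band maps a signal to negative/unclassified/positive;
values exactly on a threshold are unclassified — the conservative
choice, consistent with preferring accuracy over classification rate.
Band pairs map to calls by the Landsteiner table; any unclassified
band blocks the call.  For averaged IgG targets, averaging happens
*before* banding (the rule is defined on the mean signal).  In the
two-stage flow chart, stage-1 calls are final; stage 2 re-evaluates
only stage-1-unclassified samples, using the IgG-average rules alone
with their unclassified bands widened by the `stringency` parameter
(default 1.0 log2 unit on each side) — fewer targets, more stringent
thresholds.  Every call retains a per-rule evidence trail for audit
and mislabel screening.

## Threshold fitting

Two-component methods are fitted by exhaustive search over (A
candidate, B candidate, lowerA ≤ upperA, lowerB ≤ upperB) from a
threshold grid (default 0.25 log2-unit steps spanning the observed
range — fine enough to resolve a 1-unit unclassified band).  Survivors
must classify at least `min_classification_rate` of the training set
(default 0.80); ranking is lexicographic: accuracy among classified,
then classification rate, then smaller total band width, then target
names and threshold values for full determinism.

Multi-rule methods (the 10-component flow chart, all-agree systems)
are fitted by coordinate ascent: rules are updated in a fixed order
(anti-A IgG, anti-A IgM, anti-B IgG, anti-B IgM) for two full sweeps,
each update choosing the rule's band from the grid to maximise the
joint accuracy-then-rate objective subject to the same minimum
classification-rate constraint.  Joint exhaustive search over all
rules is combinatorially infeasible; equivalence with exhaustive
search is asserted on small instances in the test suite.  Two further
choices matter in practice:

* **The rate constraint is part of the objective, not decoration.**
  Accuracy among classified samples can always be driven to 100% by
  refusing to classify awkward samples; the constraint caps how much
  of the training set the optimiser may sacrifice.
* **Tie-breaking prefers robust thresholds.**  Where the joint
  objective is flat (it changes only when a threshold crosses a
  training signal), candidates are preferred first by the rule's own
  banding correctness (foreign-determinant samples positive, self
  samples negative), then by the distance from the nearest training
  signal to the nearer band edge.  This centres thresholds in the
  inter-class margin instead of leaving them degenerate at a grid
  point adjacent to data.

Rule initialisation before the first sweep maximises per-rule banding
correctness with the same tie-breaks.

## Mislabel screening

`flag_suspected_mislabels` reports samples whose confident
(non-unclassified) call contradicts the recorded blood type, ranked by
margin — the minimum distance of any signal contributing to the
deciding stage from its nearest threshold.  Two deliberate choices:
the *final* call is used (a stage-2 call is as final as a stage-1
call; restricting to stage 1 lets single-component noise hide true
mislabels behind a stage-2 rescue), and screening fits should use
`min_classification_rate=1.0` so the optimiser cannot absorb
contradicting samples into the unclassified band.  With contaminated
labels, an accuracy-first fit otherwise *hides* exactly the samples
one is trying to find.

## Evaluation conventions

Classification rate is `n_classified / n_total`; accuracy is
`n_correct / n_classified` (unclassified samples are refusals, not
errors; a total-denominator accuracy is also emitted).  An optional
relabel map replaces reference labels before scoring, supporting
"corrected" accuracy when some reference labels are known to be wrong.
With zero classified samples the accuracy is reported as NaN with a
warning.

## ANOVA component ranking

Each component/isotype is tested by one-way fixed-effects ANOVA on the
blood-type factor (four levels by default; a pooled A/AB-vs-B/O
two-level factor is available).  Implementation is vectorised sums of
squares with explicit degenerate conventions: constant signal → F = 0,
p = 1; zero within-group variance with non-zero between-group variance
→ F = +∞ with p floored at 1e-300 (the floor also guards underflow in
sorted output).  Ranking uses raw p-values; a Bonferroni column is
emitted for information only.  Groups smaller than two samples flag
the ranking rather than failing it.

## Survival analysis

Implemented from the defining formulas (these analyses are the point
of the package; standard library implementations are used as
independent cross-checks in the tests, never as the implementation):

* **Kaplan-Meier**: product-limit estimator; at tied times deaths are
  processed before censorings (a subject censored at *t* remains at
  risk for deaths at *t*).  The median is the smallest event time with
  S(t) ≤ 0.5, NaN if never reached — used even without censoring so
  there is a single code path.
* **Log-rank**: two-group (O − E)²/V with the hypergeometric variance
  accumulated over distinct event times; p from the χ²(1) upper tail.
* **Odds ratio**: cross-product ad/bc on the 2×2 table; 95% CI by the
  Woolf log-OR normal approximation (SE = √(1/a+1/b+1/c+1/d));
  Haldane-Anscombe +0.5 applied to every cell when any cell is zero;
  two-sided p from the Wald z on log OR, with Fisher's exact p
  reported alongside (the choice between cross-product and model-based
  ORs is genuinely open; the cross-product is the primary route).
* **OS − HPS**: per-patient overall survival minus Halabi-predicted
  survival (months), compared between groups with a two-tailed Welch
  t-test (the conventionally stated test, although it compares means)
  and a Mann-Whitney rank-sum test side by side.
* **Stratification**: A/AB (blood-group A self) vs B/O (A foreign);
  Forssman responder ⇔ log2(post) − log2(pre) ≥ 2, i.e. a ≥4-fold rise,
  boundary inclusive; the four-way blood-type × response strata
  combine both.  Unknown/unclassified blood types are excluded with a
  logged count.

## Synthetic data generator

The generator defines the study conditions for all tests.

**Signals.**  For a subject of true type *t* and a component with
determinant *d* ∈ {A, B}: mean = `baseline_mu` + `incompat_delta` ×
`isotype_scale[iso]` × `density_effect[(iso, density class)]` if *d*
is foreign to *t* (anti-A present iff *t* ∈ {B, O}; anti-B iff *t* ∈
{A, O}), plus `crossreact_epsilon` if *d* is self; Gaussian noise with
SD `sigma`.  Defaults: `baseline_mu` = 8, `incompat_delta` = 4,
`sigma` = 1 (log2 units), placing foreign-determinant IgM signals and
self signals on either side of the low-teens/high-single-digit RFU
regime reported for such arrays.  Isotype and density multipliers —
IgG 1.0 / IgM 0.7, and (IgG, high) 1.0, (IgG, low) 0.6, (IgM, high)
0.8, (IgM, low) 1.0 — encode the observed orderings that IgG
separates blood types better than IgM, that IgG separation is
stronger on high-density glycans, and that IgM can favour low-density
presentations; the magnitudes are this package's own calibration, not
estimates.  `crossreact_epsilon` = 0.3 adds a small self-bleed.
Recorded labels flip to a uniformly random other type with probability
`mislabel_rate` (default 0 — clean panels; the mislabel-recovery
experiment injects exactly four flips deterministically via
`inject_label_flips`).  Blood-type frequencies default to an
approximate U.S. distribution (O 0.44, A 0.42, B 0.10, AB 0.04).

**Cohorts.**  OS is lognormal (or exponential) with median
`baseline_median` = 16 months, multiplied by `vaccine_bo_multiplier`
= 1.8 only for vaccine-arm B/O patients and further by
`forssman_multiplier` = 1.6 for vaccine-arm B/O Forssman responders —
so control-arm survival is blood-type-independent by construction.
`os_sigma` = 0.6 is the lognormal log-scale SD (a survival CV around
0.65, typical of advanced-cancer cohorts); the field was added because
a two-parameter lognormal needs a shape.  HPS is `baseline_median` ×
exp(N(0, `hps_noise_sd`)) with `hps_noise_sd` = 0.3 interpreted as a
log-scale SD (keeping HPS positive), independent of blood type and
arm.  Forssman response occurs with probability
`forssman_response_rate` = 0.4 independent of blood type; responders
draw a log2 rise of 2 + Exp(0.8), non-responders Uniform(−0.5, 1.5).
Censoring is off by default (medians of complete follow-up); an
administrative horizon and a random-censoring fraction are available.

**What the generator does not emulate**: batch/array-position
artifacts, day-to-day drift, inter-vendor differences, ABO subgroup
(A1/A2) serology, secretor status, heavy-tailed signal noise, and any
dependence of Forssman response on blood type.  Passing tests
demonstrate that the algorithms recover the structure this model
encodes at these noise levels — not that real sera are this clean.

## Problem sizes and numerics

The test suite and the acceptance script use the 60/40/120
train/test/validation design and 80 + 37 two-arm cohorts; calibration
and power use 1000 replicate cohorts of n = 80, and oracle-equivalence
checks use small instances (≤ 2 candidate pairs, ≤ 5 grid points)
where exhaustive enumeration is exact.  Threshold grids use 0.25
log2-unit steps.  Log-rank p-values are floored at the smallest
positive double; ANOVA p-values at 1e-300.  Sub-seeds for independent
experiments are spawned from a single seed via `SeedSequence`, and
identical seeds give byte-identical outputs end to end (asserted
through the CLI pipeline).

## Known limitations

* Flow-chart thresholds are fitted, not transcribed from a published
  figure; different training draws give different (equally valid)
  bands.
* Coordinate ascent is a local search; its optimality is verified only
  on small instances, and the fixed rule order is part of the method
  definition.
* The log-rank p uses the asymptotic χ² tail; at very small group
  sizes a permutation p (provided as a test oracle) is preferable.
* Whether group medians should be KM medians or raw sample medians is
  convention-dependent; KM medians are used throughout (identical
  without censoring).
* The GEO-series reader is a documented stub; profiles must be
  supplied as long/wide TSV.
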