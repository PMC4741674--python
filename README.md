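# glycotype

Reverse ABO blood typing from glycan-microarray serum antibody
profiles, and the downstream survival analyses that blood-type
assignments enable.

## The problem

ABO blood type can be inferred from serum alone: by Landsteiner's rule
an individual carries antibodies (anti-A, anti-B) against whichever
blood-group antigens their own red cells lack — type O sera contain
both, type A sera anti-B only, type B sera anti-A only, and type AB
sera neither.  A glycan microarray measures IgG and IgM antibody
binding to dozens of synthetic blood-group A and B determinants
(tetrasaccharide types 1–6, on `Oct` or `Sp` linkers, at high or low
glycan density) from a few microlitres of serum, which makes *reverse
typing* possible for banked clinical samples too small for red-cell
agglutination.  Typed retrospectively, cohorts from immunotherapy
trials can then be stratified by blood type to ask whether antigen
recognition of a vaccine vector (which itself displays blood-group A
and Forssman antigens) influences survival.

`glycotype` is aimed at researchers analysing anti-glycan antibody
profile matrices: it implements the typing classifiers, the procedure
that develops them, and the survival statistics, together with a
synthetic-data generator reproducing the statistical structure the
analysis relies on, so every stage is testable without patient data.

## The method

Signals are analysed as log2 relative fluorescence units (RFU).  Each
piece of typing evidence is a **threshold band** over a signal `s`
(single component or the mean of several):

    band(s) = positive      if s > upper
              negative      if s < lower
              unclassified  otherwise (boundaries inclusive)

Anti-A and anti-B bands combine into a call — (pos, pos) → O,
(neg, pos) → A, (pos, neg) → B, (neg, neg) → AB, anything involving an
unclassified band → unclassified.  Three combination modes exist:

* **pairwise** — one A component and one B component;
* **all-agree** — several rules per determinant, all of which must
  produce the same non-unclassified band;
* **flow chart** — the 10-component two-stage method: stage 1 bands
  the *average IgG* over four A glycans (BG-A2-Sp-17, BG-A2-Oct-16,
  BG-A3-Oct-14, Globo A-09) plus IgM to BG-A2-Sp-17, and the
  mirror-image B set (BG-B2-Sp-20, BG-B2-Oct-17, BG-B3-Oct-17,
  Globo B-12; IgM to BG-B2-Sp-05); samples left unclassified are
  re-evaluated at stage 2 with fewer targets (IgG averages only) and
  more stringent (wider) unclassified bands.

Thresholds are fitted on labelled training sera by exhaustive grid
search (two-component methods) or coordinate ascent (multi-rule
methods), maximising accuracy among classified samples subject to a
minimum classification rate (default 80%).  Performance is always
reported as both the classification rate and the accuracy *among
classified samples*.  The survival module implements the product-limit
(Kaplan-Meier) estimator, the two-group log-rank test, cross-product
odds ratios with Woolf confidence intervals and Haldane-Anscombe
correction, survival-relative-to-prognosis (OS − Halabi-predicted
survival) comparisons, and A/AB-vs-B/O and Forssman-responder
stratification, all from their defining formulas.

The classifiers follow scikit-learn conventions (`FlowchartTyper`,
`ThresholdTyper`, `TwoComponentGridSearch`, `AnovaRanker` with
`fit`/`predict`/`get_params`), so they compose with sklearn tooling.

## Worked example

```python
import numpy as np
from glycotype import (
    simulate_profiles, simulate_cohort, fit_flowchart_thresholds,
    predict_types, evaluate, stratify, longer_than_threshold_odds,
)
from glycotype.survival import compare_survival_by_group

rng = np.random.default_rng(7)
train, y_train = simulate_profiles(60, seed=rng, sample_prefix="T")
valid, y_valid = simulate_profiles(120, seed=rng, sample_prefix="V")

method = fit_flowchart_thresholds(train, y_train)
report = evaluate(predict_types(valid, method), y_valid)
print(report.summary())

cohort, profiles = simulate_cohort(80, 37, seed=rng)
calls = predict_types(profiles, method)["call"]
strat = stratify(cohort.assign(blood_type=calls))
vac = strat[strat["arm"] == "vaccine"]
cmp = compare_survival_by_group(vac)
print(f"median OS  B/O {cmp.medians['B/O']:.1f} mo  vs  A/AB {cmp.medians['A/AB']:.1f} mo")
print(f"log-rank p = {cmp.logrank_p:.4g}")
odds, thr = longer_than_threshold_odds(vac)
print(f"OR(live > {thr:.1f} mo) = {odds.or_value:.2f}  (95% CI {odds.ci_low:.2f}-{odds.ci_high:.2f})")
```

prints

```
classified 117/120 (97.5%), accuracy 100.0% (117/117)
median OS  B/O 33.4 mo  vs  A/AB 16.1 mo
log-rank p = 1.415e-05
OR(live > 20.4 mo) = 3.57  (95% CI 1.40-9.08)
```

The first line scores the fitted 10-component flow chart on 120 held-out
synthetic sera: 117 received a definite type (97.5% classification
rate) and every classified call matched the generator's truth.  The
remaining lines stratify a simulated two-arm cohort by the *assigned*
blood types: vaccine-arm B/O patients (for whom the blood-group A
antigen is foreign) outlive A/AB patients by median survival, log-rank
test, and the odds of exceeding the cohort's median survival — the
pattern the generator encodes and the analysis is designed to detect.

The same pipeline is available from the shell:

```sh
glycotype simulate --n-train 60 --n-valid 120 --seed 7 --out-dir sim
glycotype rank     --profiles sim/profiles_train.tsv --labels sim/labels_train.tsv --out ranks.tsv
glycotype fit      --train sim/profiles_train.tsv --labels sim/labels_train.tsv --mode flowchart --out method.yaml
glycotype type     --profiles sim/profiles_valid.tsv --method method.yaml --out calls.tsv
glycotype evaluate --calls calls.tsv --labels sim/labels_valid.tsv --out eval.json
glycotype survival --cohort sim/cohort.tsv --out survival.json
```

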