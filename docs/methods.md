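# Methods

## The selection problem

Clinical prediction models are usually restricted to a handful of
predictors. Given a binary outcome (here, cancer remission) and m = 26
candidate predictors, the package compares three strategies for choosing
up to five of them:

* **StepSVM** — a forward wrapper built on a support vector machine. The
  first stage fits an SVM to every unordered pair of candidates, C(m,2) =
  m(m−1)/2 models, and keeps the pair with the best 10-fold
  cross-validated accuracy. Each later stage tries appending every
  remaining candidate (m−2, then m−3, …) and keeps the best addition,
  stopping when the criterion no longer *strictly* increases, when the
  size cap (default 5) is reached, or when candidates run out. At m = 26 a
  run that accepts a variable at every stage evaluates 325 + 24 + 23 + 22
  = 394 models; an uncapped run would cost m(m−1)/2 + (m−2)(m−1)/2.
  The selection criterion can be switched from accuracy to sensitivity or
  specificity.
* **SVM-RFE** — backward elimination: fit a linear-kernel SVM on the
  surviving variables, rank each variable by the sum of squared weights
  over its encoded column block, drop the lowest, repeat (m fits in
  total). The last k eliminated are the selected set.
* **Stepwise logistic regression** — conventional AIC-driven forward
  selection with backward checks on the aggregate (unclustered) data,
  summarized by the concordance statistic (C-statistic) of the fitted
  linear predictor, computed as the normalized Mann–Whitney U over all
  positive–negative pairs with ties counted one half.

The maximum-margin solver itself is delegated to libsvm through
scikit-learn's `SVC`; this package implements everything around it (the
wrapper search, the block-aggregated RFE ranking, the evaluation
protocol).

## Evaluation protocol

SVM-based strategies split each dataset into 80% training / 20% test,
stratified by outcome and seeded. Subset selection is driven by k-fold
(default 10) cross-validated accuracy *on the training portion only*.
Per repetition the benchmark reports two numbers for each SVM method:
the selected model's training-portion CV accuracy — the quantity the
selection criterion itself optimizes, and the convention the headline
comparison follows — and the accuracy on the untouched 20% as the
unbiased complement. The CV number inherits a selection-maximization
bias for the wrapper (it is the maximum over hundreds of candidate
subsets) that weight-ranked elimination does not enjoy; that asymmetry
is part of what the comparison measures, and the held-out column
quantifies it. The logistic comparator follows the aggregate-data
convention: it is fitted and its C-statistic computed on the full
dataset, without a split. The two SVM methods see identical folds within
a repetition.

Hyperparameter tuning minimizes the cross-validated mean squared error of
the hard 0/1 predictions, which for a binary label equals the
misclassification rate; `tune` therefore maximizes CV accuracy, breaking
ties toward the earlier grid point (grids are declared linear before RBF,
ascending C, ascending γ). SVM-RFE always uses a linear kernel with
C ∈ {0.1, 10}. StepSVM's default is RBF with C = 10, γ = 1 — the
full-scale benchmark's setting — but those values are themselves the
output of CV tuning at n ≈ 8500, and at a few hundred subjects an RBF
with γ = 1 saturates: one-hot cluster blocks dominate every pairwise
distance, so adding covariates to a selected cluster identifier cannot
change the kernel enough to register. The reduced-scale profile
therefore re-applies the tuning procedure (grid search per repetition)
rather than inheriting settings tuned at a 17× larger n; in practice the
grid then selects a linear kernel with moderate C.

Feature encoding: categorical and cluster-identifier predictors are
one-hot encoded for the SVMs; continuous and ordinal predictors are
standardized with *training-fold* statistics (one-hot columns are left as
0/1). RBF and linear kernels are scale-sensitive, so standardization is
not optional. For the logistic design, categorical predictors enter as
dummy blocks but cluster identifiers enter as their numeric codes — the
way an integer ID column enters a plain GLM formula. This choice is
deliberate: handing the stepwise logistic one-hot ID blocks lets it
memorize cluster intercepts outright at reduced scale (AIC accepts a
~50-dummy DID block on n ≈ 500, inflating the in-sample C-statistic above
0.85), a behavior that has no analogue in the ordinary aggregate-data
logistic analysis this comparator represents.

Cross-validation folds are stratified by outcome and keyed on a canonical
row ordering (the patient ID when present), so CV results do not depend on
how rows happen to be stored. Ties among equally scoring candidates are
broken by roster order, making every selection path reproducible from the
seed alone.

## The synthetic hierarchical generator

Datasets emulate a three-level study: 35 hospitals, each with 8–15
doctors, each seeing 2–40 patients (counts drawn uniformly over those
inclusive ranges). The expectation under uniform draws is
35 × 11.5 × 21 = 8452.5 patients. The binary remission outcome follows a
random-intercept logistic model

    logit P(y = 1) = β₀ + Σ_j β_j (x_j − c_j) + u_doctor + u_hospital,

with u_doctor ~ N(0, sd_doctor²), u_hospital ~ N(0, sd_hospital²), and
covariates centred at fixed nominal values c_j so that β₀ controls
prevalence. The 26-predictor roster mixes patient-level clinical
measures, doctor-level attributes (Experience, School, Lawsuits —
constant within doctor), one hospital-level share (Medicaid), and the
cluster identifiers DID and HID, which are legitimate candidates for every
selector; the patient ID never is. A draw whose outcome is single-class
is retried with a derived seed a bounded number of times, then errors.

Default effects: CancerStage −0.45, Experience +0.12, mobility −0.22,
FamilyHx −0.9, LengthofStay −0.25, SmokingHx −0.45 (per unit of each
variable's natural scale), intercept −1.3, sd_doctor = 2.0,
sd_hospital = 0.5. The random-intercept standard deviations follow the
values multilevel fits of the well-known hospital–doctor–patient (hdp)
teaching dataset report, and the intercept puts remission prevalence near
0.30, matching that dataset. With these defaults the dominant structure
is doctor-level heterogeneity, which is what makes the cluster
identifiers and doctor-level covariates genuinely informative: the RBF
SVM can exploit them (one-hot DID blocks, or near-unique continuous
doctor attributes, act as cluster lookups), whereas the linear logistic
model sees only the modest fixed effects. This reproduces the
qualitative behavior the benchmark is designed to show — the logistic
selects fixed-effect variables (C-statistic ≈ 0.70), SVM-RFE ranks DID
and HID first, and StepSVM attains the highest accuracy by pairing a
cluster identifier with clinical covariates.

What the generator does *not* emulate: longitudinal structure, missing
data, covariate correlation beyond the cluster constancy of doctor- and
hospital-level variables, and informative cluster sizes. Passing tests
therefore demonstrate correct algorithmic behavior under a clean
random-intercept world, not performance on messy registry data.

## Replication benchmark

`run_benchmark` repeats: derive a per-repetition seed from (master seed,
repetition index); generate a dataset; split; run StepSVM, SVM-RFE at
both C settings, and the stepwise logistic; record selections (by
position 1–5) and performance. Aggregates are variable-by-position
selection-frequency tables (with cumulative variants) and per-method
mean/SD/min/max. Repetitions are persisted as JSON so interrupted runs
resume to identical aggregates; a failed repetition is excluded with a
logged reason and more than 10% failures aborts.

Two profiles ship with the package. The full-scale profile is the study
design itself: 100 repetitions of the 35-hospital hierarchy (n ≈ 8500)
with the fixed RBF C = 10, γ = 1 — several CPU-hours of SVM fits. The
default desk-scale profile keeps the design but shrinks it to 10
repetitions of a 10-hospital hierarchy (4–6 doctors of 5–15 patients,
n ≈ 500) with per-repetition kernel tuning, which finishes in minutes;
at this scale the binding claim is ordinal (StepSVM's mean accuracy
exceeds both comparators' means), not the full-scale magnitudes, whose
exact values also depend on data-generating coefficients that are not
publicly documented.

## Numerical choices and edge cases

* Strict improvement in the stopping rule: a plateau terminates the path
  (non-strict acceptance could loop on ties indefinitely).
* Tuning is fixed once per StepSVM run (the benchmark settings above); a
  per-subset re-tuning mode would multiply cost ~grid-fold and is
  intentionally not the default.
* RFE ties on the squared-weight ranking eliminate the variable earliest
  in roster order (first-minimum rule).
* Stepwise logistic candidates whose GLM fit fails (separation,
  non-convergence, non-finite AIC) are skipped with a logged warning.
* `accuracy` is undefined for zero evaluated subjects; the C-statistic
  requires both classes; non-stratified folds that lose a class raise an
  error advising stratified folds.
* Seeds: a single master seed; per-repetition and per-purpose seeds are
  derived deterministically via `SeedSequence` and kept below 2³¹.

## Known limitations

* The three headline numbers are not on a common footing — an in-sample
  C-statistic for the logistic, training-portion CV accuracy for the
  SVMs — they are compared the way the field reports them, and the
  held-out column in `performance.csv` provides the common-footing view
  for the SVM methods.
* At desk scale the CV accuracy criterion is noisy (fold test sets of ~40
  subjects), so StepSVM's selected sets vary across repetitions more than
  they would at n ≈ 8500, and its mean advantage over SVM-RFE at C = 10
  is modest (well under one percentage point per repetition pair).
* The stepwise logistic caps entries at five but AIC may stop earlier;
  positions beyond the stopping point are simply absent from the
  frequency tables (column sums are bounded by, not equal to, the
  repetition count when a method stops early).
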