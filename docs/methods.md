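# Methods

## Overview

`ucrpanel` selects a small signature panel (M ≪ N features) of transcribed
ultraconserved regions from a log2 microarray expression matrix, then
evaluates the panel diagnostically (held-out classification) and
prognostically (survival stratification). The pipeline is a funnel:

    probes ──volcano──► candidates ──ensemble ranks──► sum scores ──cutoff──► panel
                                                                        │
                               held-out confusion matrix ◄──────────────┤
                     Ward clustering → k groups → log-rank ◄────────────┘

The matrix is assumed already normalized on the log2 scale; no
normalization, background correction or batch handling is performed.

## Differential selection

Per probe and comparison (LG vs NBE, HG vs NBE by default; a pooled
BlCa-vs-NBE mode is available): `log2FC = mean(case) − mean(control)` and a
two-tailed two-sample t-test. The t-test is Student (pooled variance) by
default — the conventional class-comparison choice for small microarray
cohorts — with Welch available as a switch. Candidates are the union of
the per-comparison hits, sorted by probe id for determinism.

Decisions worth knowing:

* **Strict inequalities at the cutoffs** (`p < p_thr`, `|log2FC| >
  lfc_thr`): a probe exactly on a threshold is *not significant*.
* **Degenerate variance**: two groups of identical constants compare as
  (t = 0, p = 1); zero pooled variance with unequal means is an error
  rather than a silent infinity.
* **No multiple-testing correction is applied as a filter**: selection is
  on raw p values, matching the methodology this package implements. An
  FDR column can be added to reports downstream but never changes the
  candidate set.
* Raw-scale fold-change thresholds are converted internally
  (`fc_to_log2`); FC 2 ↔ 1, FC 3 ↔ 1.585 (printed as 1.58 at 2 d.p.).

## Ensemble feature relevance

Binary target: cancer (LG+HG pooled) = 1 vs NBE = 0; tumour grade is not
used at this stage. Stratified k-fold cross-validation (default k = 5,
seeded); inside each training fold the candidate features are standardized
(mean 0, population sd 1) with *training* statistics only, a model is fit,
and its importance vector recorded; fold vectors are averaged and ranked
once. Ranking ties break by ascending feature id, so every ranking is a
deterministic permutation 1..N. (An `average_ranks` switch instead ranks
per fold and averages ranks; the default averages importances.)

Per-model importances:

* **LR** — logistic regression, weak L2 penalty (C = 1000) so coefficients
  are examined rather than shrunk; importance = |coefficient|.
* **LASSO** — L1-penalized logistic regression; the penalty is chosen by
  cross-validated deviance (10 values of C, log-spaced 1e-2..1e2) inside
  each training fold; importance = |coefficient|, zeros meaning the
  feature was dropped.
* **RF** — 500 trees, `max_features=None`; importance = normalized mean
  impurity decrease (sums to 1).
* **XGB** — binary logistic objective, 100 trees of depth 3, learning rate
  0.3, exact splits; importance = total gain, 0 for never-used features.

These hyperparameters are package defaults, all overridable; they are not
claimed to match any particular prior study's settings. Constant features
standardize to all-zero and are flagged rather than dropped.

## Rank-sum aggregation and the panel cutoff

Rank r among N candidates maps to score `N − r` (best rank 1 → N−1, worst
→ 0). Sum scores over the four models with equal weight and no
normalization; re-sort descending (ties by ascending feature id). The
panel is every feature with

    sum_score ≥ f × 4(N − 1)        (inclusive ≥)

Expressing the cutoff as a fraction *f* of the maximum achievable sum
makes the panel invariant to the affine choice of rank-to-score mapping:
any mapping `a − b·rank` sorts features identically, and the
fraction-of-maximum threshold picks the same set. *f* = 0.5 and 0.6 are
the documented settings. If no feature reaches the threshold the panel is
empty and downstream stages halt with a warning rather than erroring.

## Stratification and survival

Only cancer samples are clustered for survival grouping (controls would
otherwise dominate the top dendrogram split). Panel rows are z-scored
(population sd; constant rows → 0, flagged), samples clustered with
Euclidean distance and Ward linkage (both configurable — the choice is a
package default, since heatmap dendrograms in this literature rarely state
theirs), and the dendrogram is cut into k groups. k is a config input (4
for the stricter panel, 3 for the looser one, in the documented settings);
there is no automatic k selection. Group labels are canonicalized by order
of first appearance, making assignments invariant to input sample order up
to relabeling.

Kaplan–Meier estimation and the k-sample log-rank test (chi-square, k−1
df) are delegated to `lifelines`; censored subjects shrink the risk set
without steps, and tied event times share one risk-set computation. Both
are cross-checked in the test suite against independently coded
product-limit and observed/expected oracles. Groups lacking survival data
are excluded from the comparison; a log-rank with no events is an error.

## Held-out evaluation

Stratified 70/30 split on the binary label (seeded, deterministic);
logistic regression on the standardized panel features (training
statistics only); decision threshold 0.5; 2×2 confusion matrix and
accuracy on the test split. No ROC/AUC and no nested model selection — the
panel, not the classifier, is the object under evaluation.

## Synthetic study generator

The generator emulates the reference study design so every stage can be
tested with known truth: 481 UCRs × {sense, antisense} = 962 probes, 17
NBE / 12 LG / 12 HG samples, quadruplicate spots per probe.

Model (all on the log2 scale):

* per-probe baseline ~ N(8, 1.5²) — arrays span a wide intensity range;
* within-group noise Gaussian, sd `noise_sd` = 1 by default — the standard
  microarray log-scale assumption;
* `n_de` = 24 planted probes shifted by `effect_lg` = 2 / `effect_hg` =
  2.5 log2 units in LG/HG, direction randomized per probe (both up- and
  down-regulated markers occur);
* the 24 cancer samples are split evenly into four planted subgroups; each
  subgroup adds its own ±1.0 log2 signature over the planted probes. The
  magnitude 1.0 is deliberate: subgroup structure inflates within-grade
  variance at the planted probes, and much larger signatures would push
  them past the p < 0.001 volcano cutoff — prognostic subgroups must not
  destroy the diagnostic signal they live on;
* survival: exponential per subgroup with means (4, 15, 60, 200) months
  and 10% uniform administrative censoring; controls carry no survival
  data. With only ~6 patients per subgroup an exponential log-rank needs
  strongly separated means to be reliably detectable, hence the wide
  spread — qualitatively one rapidly progressing group, one long-surviving
  group, two intermediate;
* spot-level replicates add independent N(0, `replicate_sd`²) noise per
  spot; collapsing takes the per-cell median of non-missing spots (robust
  to single bad spots — the collapse statistic is this package's choice).

Identical config (including seed) reproduces the study bit-for-bit.

What the generator does **not** emulate: dye/scanner artifacts, batch
effects, probe-specific variances, correlation between sense and antisense
probes of the same UCR (generated independently, mirroring their treatment
as separate features), non-exponential survival, informative censoring.
Passing recovery tests therefore demonstrates that the pipeline's
machinery is correct and calibrated under a clean generative model — not
that real arrays meet these assumptions.

## Numerical and degenerate-input conventions

* Missing-value tokens in input matrices: empty string, `NA`, `null`
  (case-insensitive); any other non-numeric cell is a hard error naming
  the probe and sample. Missing values are legal only pre-collapse.
* Duplicate probe ids, duplicate sample ids, empty matrices, spot ids
  claimed by two probes: hard errors.
* Probe ids are opaque strings; the `uc.<n>+`/`uc.<n>+A` convention is
  linted (warning) but never enforced.
* All ranking/sorting ties break by ascending feature id; group labels by
  first appearance; every stochastic step takes an explicit seed.
* Standardization uses the population (ddof = 0) standard deviation.

## Test-scale choices

The default test suite and the acceptance script run entirely on synthetic
data: the full 962 × 41 reference design for calibration and recovery
checks (20 generator seeds), and a reduced 120-probe design for end-to-end
pipeline and CLI exercises. Oracle comparisons (t-test, log-rank, rank
aggregation) use small random instances where brute-force computation is
exact.

## Known limitations

* The aggregation assumes all four rankers cover the identical feature
  set; partial ensembles are supported only by passing fewer tables.
* Feature-order invariance is exact for the coefficient-based rankers but
  only approximate for tree ensembles (their RNG stream consumption
  depends on column order); use fixed input ordering (the package sorts
  candidates by id) for reproducibility.
* Log-rank power at n = 24 with 4 groups is intrinsically low; clustered
  group assignments that differ from the planted subgroups by even one or
  two patients can lift p markedly. The stratification stage reports what
  it computes; interpretation at this sample size warrants caution.
* No Cox regression, pairwise post-hoc log-rank tests, or figure
  rendering; outputs are plot-ready TSV/JSON tables.
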