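# Methods

## The distance-from-reference score

The DFR of a sample over a probe universe S is the sum of squared
control-standardized deviations, Σ_i (e_i − M_i)²/V_i, with M_i and V_i the
healthy-control mean and (n−1)-denominator variance of probe i. The score is
non-negative, zero exactly at baseline, additive over disjoint probe
subsets, and invariant under a common rescaling of expression and reference
(e → c·e, M → c·M, V → c²·V). A natural-log variant — the log of the sum,
not the sum of logs — is provided as an option; reported values default to
the raw sum, displayed on a ×10³ scale that is formatting only (stored
scores are raw sums).

Expression values are assumed to be normalized log2-scale intensities;
normalization is treated as upstream and is out of scope. Fold changes are
the only place the scale matters materially: they are computed as linear
ratios of per-group geometric means, 2^(Δ log2 mean), and reported with the
signed convention r if r ≥ 1 else −1/r, so the magnitude is always ≥ 1 and
−3.1 reads "3.1-fold down".

**Sampling null.** When the reference is *estimated* from n controls, a
sample drawn from the same distribution has per-probe expectation
(n−1)/(n−3)·(1+1/n) rather than 1 (the (1+1/n) factor from the estimated
mean, the (n−1)/(n−3) factor from the inverse-chi-square moment of the
estimated variance; finite only for n > 3). Tests assert the empirical mean
of null scores is within 3 standard errors of n_probes times this value.

**Variance floor.** Probes with near-zero control variance make the score
explode. `build_reference` raises per-probe variances below the 10th
percentile of positive variances (configurable quantile) to that floor and
logs how many probes were floored. This is a standard standardization
safeguard; with `floor_quantile=0` the reference is the textbook per-row
mean/variance, and construction fails if any variance is non-positive.

## Probe selection

Per-probe one-way ANOVA F-tests are computed vectorized from between/within
sums of squares across all supplied groups (aged, young, control by
default). Degenerate within-group mean squares are floored at the 10th
percentile of positive within mean squares, so an all-constant probe yields
F = 0, p = 1 instead of 0/0. The implementation is cross-checked in tests
against `scipy.stats.f_oneway`, the t²-identity at k = 2, and a brute-force
sum-of-squares oracle.

Selection requires both a p-value threshold (Benjamini–Hochberg adjusted
p ≤ 0.001 by default; the raw-p mode is available via `use_adjusted=False`
and logged) and a minimum fold change (default two-fold versus controls in
at least one trauma group). Gene-panel restriction intersects selected
probes with a user-supplied panel through a probe→gene table; an empty
intersection is a warning, not an error, and the surviving gene count is
reported — panels are consumed as configuration, never curated here.

## Classification

The classifier is nearest centroid on the working probe set, with a
deterministic lexicographic tie-break; it is deliberately simple and
pluggable behind a fit/predict contract. LOOCV re-runs probe selection
inside each fold by default, so the reported misclassification rate is free
of selection bias; the biased outside-fold variant is retained for
comparison. The permutation null shuffles sample labels (class sizes
preserved), re-runs the full pipeline per permutation, and reports the
add-one-smoothed p-value (1 + #{r_perm ≤ r_obs})/(1 + B), which is never
zero and valid (P(p ≤ α) ≤ α) under exchangeability. A fold whose selection
is empty falls back to the full probe universe rather than failing.

## Cohort statistics

**Matched pairs.** Candidate aged–young pairs require exact gender match,
exact 28-day survival match, and identical sampled-timepoint sets; among
candidates the summed per-region |ΔAIS| (shorter vectors zero-padded) is
minimized greedily, taking pairs in ascending cost with ties broken by
ascending patient ids. Greedy was chosen because the matching is described
by criteria rather than an algorithm; tests verify it against exhaustive
minimum-cost assignment on small instances, where it recovers unique optima.

**Group comparisons.** One-way ANOVA provides the omnibus test;
Student–Newman–Keuls pairwise comparisons use the studentized-range
distribution with range-dependent critical values (unequal n handled via the
Tukey–Kramer-style standard error) and the step-down rule that a
non-rejected stretch blocks every comparison nested inside it. At k = 2 the
SNK decision coincides with the pooled two-sample t-test. Kruskal–Wallis
(tie-corrected, chi-square reference), Holm–Šidák (step-down, sorted p_(j)
vs 1−(1−α)^(1/(m−j+1))), Fisher's exact test (two-sided hypergeometric; odds
ratios Haldane-corrected at zero cells) and the Wilcoxon rank-sum test
(exact enumeration for combined n ≤ 12 without ties, otherwise normal
approximation with tie/continuity correction) wrap scipy/statsmodels
implementations behind a uniform result surface. Clinical-table percentages
are reported at one decimal of percent, matching the printed precision of
the source tables.

**Cytokine model.** "GLM" is read as a two-factor fixed-effects linear model
on log-transformed concentrations with categorical age group and categorical
timepoint (the sampling grid, in hours), using type-II F tests per factor —
appropriate for the unbalanced designs produced by discharge/death dropout.
No repeated-measures covariance structure is fitted; with per-patient
longitudinal correlation the factor tests are anti-conservative for
within-patient effects, a known limitation. An interaction term is exposed
as an option but off by default, since only main-effect significance is
interpreted. Exact zero concentrations are replaced by half the smallest
positive value before the log.

## Synthetic cohorts

The generator defines the study conditions all property tests run under.
Per probe, the control baseline draws M_i ~ Normal(8, 2²) log2 units and
V_i scaled-inverse-chi-square (df 10) with mean 0.25 — invented hyperpriors,
documented here, and standardized out by the DFR. Each responsive probe
(default fraction 0.75 of the array) carries a random sign fixed per probe,
so cohort centroids separate coherently as in real up/down regulation. A
patient sample at day t in cohort (g, c) is shifted by
sign_i · amplitude[g](t) · outcome_scale[c] · √V_i with residual noise of
1 control SD. Default amplitudes (control-SD units) encode the qualitative
signature only — young {0.5 d: 2.0, 1 d: 1.7, 4 d: 0.8, 7 d: 0.4}, aged
{0.5 d: 1.2, 1 d: 1.1, 4 d: 1.4, 7 d: 1.1} — i.e. young > aged acutely,
crossover by day 4, recovery in the young; no magnitude scale in SD units
exists to emulate, so magnitudes are chosen to be realistic for a
genome-scale storm rather than to match any printed value. Beyond the keyed
grid, amplitude decays exponentially at the cohort recovery rate. Cohort
sizes default to 17 patients per cell and 17 controls, the matched-cohort
scale of the motivating study design.

Dropout is monotone (once missing, always missing; per-timepoint hazard
0.10), emulating discharge or death. Cytokine trajectories are log-normal
with additive analyte baseline, decaying time profile, and a negative aged
effect by default; the truth record stores every effect. Clinical tables
are multinomial draws with group totals preserved. Identical parameters and
seed reproduce all outputs bit-identically.

**What the simulation does not emulate:** probe-level chip artifacts, batch
and centre effects, correlated probe blocks (probes are independent given
the cohort shift), within-patient autocorrelation across timepoints, and
intermediate-outcome dynamics. Passing tests therefore demonstrate the
correctness and calibration of the machinery under idealized independence,
not performance on real arrays; analyses of deposited expression data must
additionally confirm the upstream normalization and scale.

## Numerical and design choices

- Time grids: expression days {0.5, 1, 4, 7, 14, 21, 28}; cytokine hours
  {12, 24, 96, 185, 336, 504, 672}. Metadata loading validates against the
  grid unless configured otherwise.
- Missing expression values are rejected at load; there is no imputation
  rule to implement, so callers pre-filter.
- One canonical file dialect (tab-delimited, UTF-8, header row of sample
  ids, first column probe ids) avoids CSV ambiguity; a GEO series-matrix
  reader is provided as an optional convenience and is not load-bearing.
- The genome-wide DFR defaults to all probes passing reference flooring;
  the selected-probe and gene-panel universes are explicit parameters, since
  either reading of "genome-wide" is defensible.
- Problem sizes in tests and the acceptance script (hundreds of probes,
  10–17 patients per cell, 99 permutations, 100 trajectory replicates) are
  chosen as the smallest scales at which the calibration statements are
  sharp; all scale linearly if enlarged.

## Known limitations

Headline cohort-level values from the motivating study design (specific
probe-set counts, printed DFR means such as 116 ± 54 vs 88 ± 29 (×10³))
depend on the deposited arrays of a proprietary chip and a non-public
clinical database; they are external-data reproductions outside this
package's scope, and no test asserts them. Multivariate stepwise logistic
regression, pathway-knowledge-base Z-scores, probe-level normalization and
gene-set curation are likewise out of scope.
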