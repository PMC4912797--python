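# Methods

This note documents the statistical procedures implemented in `vdscore`, the
parameter defaults and their rationale, and the design choices made where the
underlying methodology admits more than one reasonable convention.

## 1. The scoring procedure

Plasma 25-hydroxyvitamin D (25OHD, ng/mL) is categorized into the four
nationally accepted threshold bands. Bands are half-open so every positive
level is classified exactly once; a boundary value belongs to the higher band:

| band | interval | initial sub-score |
| --- | --- | --- |
| replete | [30, ∞) | 0 |
| insufficient | [20, 30) | 1 |
| deficient | [10, 20) | 2 |
| severely deficient | (0, 10) | 3 |

A `ScoreAssignment` attaches one integer sub-score per band; the sub-score is
added to a base index (DCCI or APACHE II) to form the augmented score. Two
published-style assignments ship as constants: the initial (0, 1, 2, 3) and a
collapsed variant (0, 1, 1, 3).

**Search space.** `enumerate_assignments` generates, by default, all
assignments that are (a) bounded by 6 per band, (b) monotone non-decreasing
toward deficiency, and (c) anchored at 0 for the replete band — 84 assignments
(the number of non-decreasing triples over {0..6}, C(9,3)). Monotonicity
encodes the near-inverse-linear association between 25OHD and adverse
outcomes; the anchor makes the replete band the reference. Both constraints
are flags, so the unanchored monotone space (210 assignments) or the fully
unconstrained 7⁴ space can also be searched. The bound of 6 is applied
per band, not to the total added score — the per-band reading keeps the space
well-defined for every base index.

**Search.** `search_best` evaluates every assignment's augmented-score AUC
exhaustively. The AUC is computed from the rank-sum, whose numerator is an
exact half-integer, so exactly tied assignments compare equal in floating
point and the deterministic tie-break applies: smaller sub-score sum first
(parsimony — the all-zero assignment wins when augmentation adds nothing),
then lexicographic order.

## 2. ROC curves and paired AUC inference

Scores are oriented so that larger values mean higher mortality risk; raw
25OHD (inversely associated) is never used directly as a predictor — the
category sub-score is. The prediction rule is "positive iff score ≥
threshold"; ties are grouped at a single threshold, so the empirical curve has
one point per distinct score value plus the endpoints (1, 1) and (0, 0).

The AUC is the Mann–Whitney statistic: over all (case, control) pairs, 1 for a
concordant pair, ½ for a tie, 0 otherwise. An internal cross-check asserts it
equals the trapezoidal area under the tie-grouped curve to 1e-12.

Inference uses the U-statistic (DeLong-type) decomposition. Each positive
case's placement value is the fraction of negatives it outranks (ties ½), and
symmetrically for negatives; the AUC's variance is assembled from the
empirical variances of the two placement sets. For two scores on the same
patients, the covariance of paired placements gives the variance of the AUC
difference, and the equality test is `chi2 = delta² / var(delta)` with 1 df.
Self-comparison (var = 0 and delta = 0) returns chi2 = 0, p = 1; var = 0 with
delta ≠ 0 raises a degenerate-variance error. Confidence intervals are Wald on
the AUC scale (`auc ± 1.96·se`, clamped to [0, 1]); a logit-scale interval is
available behind a flag.

Placement midranks are computed with `scipy.stats.rankdata`, which makes the
components exact for tied data.

## 3. Cut-points

`optimal_cutpoint` scans all candidate cutoffs — the distinct score values
plus one sentinel above the maximum (the all-negative rule) — and maximizes
sensitivity + specificity (the Youden index plus one). Candidates are compared
in exact integer arithmetic: with fixed class sizes the sum equals
`(tp·n_neg + tn·n_pos) / (n_pos·n_neg)`, so the integer numerator orders
candidates without float rounding. Ties break toward higher specificity, then
the higher cutoff, so an uninformative score yields the all-negative rule.
Sensitivity, specificity and accuracy are formed from exact integer 2×2
counts; accuracy uses the cohort's raw prevalence (no balancing).

## 4. Logistic regression

Two covariate-adjusted mortality models are predefined: 25OHD (per 1 ng/mL),
age, sex, race, BMI, patient type, plus either DCCI or APACHE II — never both
in one model. Categorical coding: sex reference = male, race reference =
white, type reference = surgical; the biomarker and index odds ratios are
invariant to these choices.

Fitting is iteratively reweighted least squares (Newton on the logistic
log-likelihood) with step-halving, convergence when the maximum absolute
coefficient change falls below 1e-8 (default, max 100 iterations). The
covariance is the inverse Fisher information at the optimum; odds-ratio
intervals are Wald, `exp(b ± 1.96·SE)`. A pivoted-QR rank check fails loudly
naming collinear columns; complete separation is detected (coefficients
diverging beyond |b| > 30) and flagged rather than penalized, since plain
maximum-likelihood odds ratios are the reporting target. Missing data are
handled by complete-case exclusion at CSV read time, with the dropped-row
count retained.

## 5. LOWESS

The smoother is the classical locally weighted scatterplot smoother: at each
observed x, a degree-1 weighted least-squares fit over the ⌈span·n⌉ nearest
neighbours (ties in distance all included), with tricube weights on scaled
distance; robustness iterations reweight by the bisquare of residuals scaled
by six times their median absolute value. Defaults are the method's classical
settings, span = 2/3 and 3 robustness iterations, both exposed. Evaluation is
at the observed x values only (no interpolation grid). `window_slope` reports
the least-squares slope of the fitted curve within an x-window, the summary
used to compare the deficient range (0–10 ng/mL) with the range above it.

The smoother is hand-written rather than delegated because the neighbourhood
convention (ceiling count, distance ties included, evaluation at observed x)
is part of the contract; statsmodels' implementation is used only as a loose
cross-check in the tests.

## 6. Synthetic cohort generator

The generator emulates the marginal structure and outcome model of a
two-center ICU cohort; it does **not** emulate enrollment timing, exclusion
screening, comorbidity-category flags, or longitudinal 25OHD trajectories.

**Covariates.** Continuous covariates are truncated normals — age (mean 67,
SD 15, truncated at 18 years), BMI (28, 7, truncated at 10 kg/m²), 25OHD (19,
8, truncated at 0.5 ng/mL). Truncation bounds are implementation choices to
keep values physiologic. Binary covariates are Bernoulli: female 0.41,
non-white 0.06, medical 0.30. DCCI and APACHE II are normals (means 4 and 17,
SDs 3 and 9) rounded to the nearest integer and clamped to [0, ∞) and [0, 71].

**25OHD coupling.** A strictly independent covariate draw cannot produce the
characteristic severity-vs-25OHD curve shape (steep below 10 ng/mL,
flat above): under independence both window slopes are ~0. The generator
therefore couples DCCI and APACHE II to 25OHD through a hinge term
`max(0, 10 − vitd)` — zero above 10 ng/mL, linear below — with default
coupling coefficients 0.3 (DCCI) and 0.8 (APACHE II) index points per ng/mL of
deficit. The hinge is mean-centred analytically (closed form under the
truncated normal), so the marginal means of DCCI and APACHE II stay at their
targets. Set both couplings to 0 for fully independent covariates.

**Outcome.** `death90 ~ Bernoulli(expit(α + Σ β·x))`. Default log-odds
coefficients: 25OHD ln(0.84) per ng/mL in the DCCI model and ln(0.86) in the
APACHE model; DCCI ln(1.32) per point; APACHE II ln(1.14) per point. The minor
covariate effects are not externally pinned and were chosen once from
plausible direction and magnitude — age 0.01/year, female 0.3, non-white 1.5,
BMI 0.03/kg·m⁻², medical 1.2 — and never tuned afterward; none of the
package's verified quantities depends on them beyond being part of a correctly
specified model.

**Calibration.** The intercept α is solved by bisection on [−20, 20] so that
the Monte-Carlo mean of `expit(α + linear predictor)` over the configured
covariate distribution hits the target mortality (default 0.19) within 1e-4.
Calibration uses a fixed internal Monte-Carlo seed, separate from the cohort
seed, so a given configuration always maps to the same α; `default_alpha`
caches it per configuration. An unbracketable target raises a convergence
error.

**Determinism.** Identical (config, seed, α) gives an identical cohort;
covariates are drawn in a fixed order from one `numpy` Generator.

## 7. Pipeline conventions

Five scores are analyzed: DCCI, DCCI + 25OHD, APACHE II, APACHE II + 25OHD,
and the 25OHD sub-score alone. "25OHD alone" means the category sub-score
(0–3 under the initial assignment), not the negated raw level, so its optimal
cutoff is expressed on the sub-score scale (e.g. "≥ 3", i.e. < 10 ng/mL). Five
pairwise equality tests are reported, unadjusted for multiplicity (the report
carries a note). In `search` mode each base index gets its own exhaustive
assignment search; the standalone 25OHD score keeps the initial categorical
scale. Report regeneration from the same CSV and configuration is
byte-identical.

## 8. Known limitations

- The assignment search evaluates in-sample: the winning assignment's AUC is
  optimistically biased. The package reports in-sample AUC and leaves
  validation (e.g. a held-out cohort) to the caller.
- No joint covariate correlation structure beyond the 25OHD hinge coupling;
  independence elsewhere is an assumption, configurable only through the
  coupling coefficients.
- No partial AUC, binormal smoothing, >2-curve comparisons, cost-weighted
  cut-points, penalized (Firth) logistic fits, or LOWESS confidence bands.
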