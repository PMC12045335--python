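# Methods

This note documents the statistical machinery, the generative model
behind the synthetic cohorts, the numerical choices, and the design
decisions taken where the design was genuinely open.  It states no
empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## Models and estimation

All four model families are fitted by full Newton–Raphson with
step-halving on the log-likelihood, convergence when the log-likelihood
changes by less than 1e-8, a maximum of 100 iterations (callers may raise
this for sparse strata), and a ridge of 1e-8 on the information matrix
before solving.  Covariances are inverse observed information.

* **Multinomial logit** (baseline-category).  The reference category is
  the lowest outcome level — for a bother-rated symptom item, "not at
  all" — which matches the absent/present reading of the dichotomized
  item.  Predicted probabilities are softmax inversions of the linear
  predictors; every row sums to 1 by construction.
* **Cumulative-logit proportional odds**, sign convention
  `logit P(Y <= k) = θ_k − x'β` (as in SPSS PLUM and MASS::polr), so a
  positive slope shifts mass to higher categories.  A constant design
  column is absorbed into the thresholds.  The log-likelihood is concave
  in (θ, β); Newton steps that would break threshold monotonicity are
  rejected by step-halving, which only re-parameterizes the search path.
* **Binary logistic** with Wald standard errors, odds ratios and 95%
  CIs.  Any |coefficient| above 15 at convergence is declared separation
  and reported with the offending column.
* **OLS** with R² = 1 − SSR/SST; a zero-variance outcome yields R² = 0 by
  the degenerate-input rule.

**Parallel-lines check.**  The statistic is 2·(llₘᵤₗₜᵢ − llₒᵣ𝒹) on
p_slope·(K−2) degrees of freedom.  Two caveats are documented rather
than hidden.  First, the baseline-category multinomial does not strictly
nest the cumulative model, so at finite n the multinomial maximized
likelihood can fall slightly below the ordinal one; a negative difference
is no evidence against proportionality and is reported as statistic 0,
p = 1, with a `flagged` marker.  Second, for two predictors and a
five-level outcome the conventional df is 6; analyses that report df = 3
for this design are using a model variant that cannot be reconstructed
from a printed test line alone, so the package sticks to the conventional
formula.

**Pseudo-R².**  Cox–Snell, Nagelkerke and McFadden are all emitted;
Nagelkerke (Cox–Snell rescaled by its attainable maximum) is the
headline figure in the variance tables, being the conventional
normalized choice when a report prints a single unnamed "pseudo R²".

## The accuracy score

`ACP_i` is the fitted multinomial probability of participant *i*'s
observed category.  The score is dichotomized at the median of its own
stratum; ties at the median go to the *low* class (strict `>`), keeping
the "more accurately classified" class conservative.  Quantiles use
linear interpolation between order statistics.  The low-accuracy share
uses ACP ≤ 0.5.  The default stratification fits the measure separately
for controls and asthma/COPD with sexes pooled; a `group-sex` switch
fits all four cells, since published descriptions of this design mention
both variants and they cannot both describe a single model.

## Psychosocial components

KMO uses anti-image partial correlations from the inverse correlation
matrix; Bartlett's sphericity statistic is −(n−1−(2p+5)/6)·ln|R| on
p(p−1)/2 df.  Components are extracted from the item correlation matrix;
retention is Kaiser (eigenvalue > 1) by default with a fixed-k override.
Rotation is direct oblimin at γ = 0 (direct quartimin) via the oblique
gradient-projection algorithm; the rotated pattern never has a larger
criterion value than the unrotated loadings, and the solution is ordered
by sum of squared structure loadings and sign-aligned so each component's
loading sum is positive.  The 0.4 retention rule operates on absolute
*pattern* loadings (the rule's source does not say pattern vs structure;
pattern — unique contributions — is the standard reading): an item is
kept iff exactly one component reaches 0.4.  Compound scores are
unit-weighted means of z-scored, sign-aligned retained items,
re-standardized; regression scores were rejected because per-component
Cronbach's α presupposes item-scale composites.  α is computed on the
z-scored, sign-aligned items of each component.

## Synthetic cohort generator

The generator emulates the participant table of a large adult population
cohort with an embedded misperception mechanism:

* **Demographics / physiology.**  Female share 0.59; asthma/COPD share
  0.121; FEV1%pred normal per group (96.7 ± 12.2 control, 85.3 ± 14.3
  asthma/COPD) truncated to the plausible 16–225 window; BMI per group
  (25.8 ± 4.24, 26.7 ± 4.93); height sex-specific (1.68 ± 0.065 m women,
  1.81 ± 0.07 m men, adult Dutch stature); weight = BMI·height², so BMI
  calibration holds while weight remains the model predictor.
* **Psychosocial battery.**  Three correlated standard-normal factors
  (negative affect, fear of illness, worry of contracting disease;
  correlations 0.5/0.3/0.4) drive 32 columns: 6 NEO-facet-like sums and
  10 PANAS-NA-like items on the NA factor, 10 binary Whitely-like items
  on fear, 4 binary Whitely-like items plus LTE and long-term-difficulty
  sums on worry.  Loadings sit in the 0.6–0.8 band.  Binary items get
  the top of the band and a median-split endorsement threshold because
  dichotomizing a latent item caps the information it carries (a
  point-biserial correlation loses ~20% at a median split); a composite
  of a handful of true/false items simply cannot correlate arbitrarily
  well with its factor, and the block sizes were chosen so each
  composite's validity clears 0.9.
* **Dyspnea report.**  Latent propensity
  `L = 0.45·z(−FEV1%pred) + 0.20·z(weight) + 1.35·asthma + w'F + logistic noise`
  with distortion weights `w = (0.50, 0.50, 0.35)` by default, cut at
  thresholds (2.95, 4.25, 5.45, 6.65) into the 1–5 item.  Physiology
  z-scores use analytic mixture moments, so the generative coefficients
  are population quantities, not sample-dependent ones.  Thresholds and
  the disease shift were calibrated once so the dichotomized item (≥ 2)
  has prevalence ≈ 7% in controls, ≈ 27% in asthma/COPD and ≈ 10%
  overall, the figures the target cohort reports.  Because the report is
  cumulative-logit by construction, proportional odds holds exactly by
  default; a category-specific FEV1 term (`npo_effect`) breaks it in a
  controlled way, giving the parallel-lines test a real signal.  The
  five yes/no dyspnea items (sumscore 0–5) share the systematic part of
  L with independent logistic noise; the somatization sumscore (12–60)
  loads on L and additionally on the NA factor.
* **Flags.**  CVD/GAD/PD, invalid spirometry and unconfirmed asthma are
  independent Bernoulli draws at the cohort's reported prevalences.
  All randomness flows from one seed through named substreams.

What the generator does **not** emulate: family structure, longitudinal
waves, item-level missingness patterns, measurement error in
self-reported weight, genuinely cross-loading psychosocial items, or the
reference-equation internals behind FEV1%pred.  Synthetic batteries are
cleaner than real ones — adequacy statistics and α come out higher than
a field study would show — so passing tests demonstrate that the
*machinery* recovers known structure, not that real data would be as
kind.

## Pipeline conventions

Exclusions: CVD, GAD, PD, and self-reported asthma without physician
confirmation remove rows outright; technically invalid spirometry keeps
rows for questionnaire descriptives but excludes them from every
spirometry-dependent stage.  Exclusion counts always sum to rows_in −
rows_out.  Missing data are deleted listwise per model with a logged
count.  Smoking enters only the variance-decomposition step-1 model,
not the ACP model, which uses FEV1%pred and body weight alone.  Body
weight is used as reported (kg), not BMI.  Education and age are
descriptive only.  In a stratum where the outcome level set is
incomplete the multinomial is fitted on observed levels with a warning;
a stratum whose fit fails to converge (typically a quasi-separated
singleton level in a tiny stratum) is recorded as a diagnostic and left
unscored rather than aborting the run.  Manifests contain no timestamps
and are byte-identical across reruns of the same input, config and seed.

## Problem sizes

Default analyses and the acceptance script use cohorts of 10,000–20,000
participants; the structure-recovery check uses 20 seeds at n = 5,000,
and the null-calibration check 200 replicates at n = 2,000 — sizes at
which every Monte-Carlo tolerance used in the tests is comfortably
resolved on a single CPU in well under a minute per stage.

## Known limitations

* The ACP inherits the weaknesses of its base model: with a heavily
  skewed outcome the score for majority-category reporters is driven
  almost entirely by physiology, so psychosocial associations in
  low-prevalence strata are attenuated relative to high-prevalence ones.
* The Wald CIs assume no separation; rare outcome levels in small strata
  are the practical failure mode, and the pipeline surfaces them as
  diagnostics instead of estimates.
* Oblimin rotation has rotational indeterminacy up to column order and
  sign; the deterministic ordering convention makes runs reproducible
  but is not itself substantive.
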