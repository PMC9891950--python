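# Methods

## Cardiovascular risk equations

**SCORE2.** The 10-year risk of fatal plus non-fatal cardiovascular
disease is computed from a sex-specific linear predictor on centred and
scaled covariates — age (centre 60 y, scale 5), systolic blood pressure
(120 mmHg, 20), total cholesterol (6 mmol/L, 1), HDL cholesterol
(1.3 mmol/L, 0.5) and current smoking — including the four age
interactions, via `r = 1 − S0^exp(lp)` with baseline 10-year survival
S0 = 0.9605 (men) / 0.9776 (women). The uncalibrated risk is mapped to
one of four regional clusters (low / moderate / high / very-high CVD
risk) with the published per-sex rescaling
`r_cal = 1 − exp(−exp(scale1 + scale2·ln(−ln(1 − r))))`; the map is
strictly increasing for scale2 > 0, so ranking of individuals is
region-invariant. UK-style analyses use the low cluster, US-style the
high cluster. Coefficients, survivals, scales and category thresholds
are YAML data files under `frailtraj/data/`, not code: they are a
versioned configuration, and bit-level agreement with any particular
published calculator is not claimed.

**Three-category classification.** Age-banded cutpoints (under 50:
2.5 / 7.5%; 50–69: 5 / 10%; 70+: 7.5 / 15%) give low-to-moderate, high
and very-high categories. Bands are contiguous and keyed by their lower
edge (an age of 69.5 falls in the 50–69 band); a boundary risk value is
assigned to the *higher* category. Both conventions are deliberate
choices where the source texts are silent, and are encoded in the
threshold file.

**SCORE.** The comparator equation is the cause-specific Weibull form
for 10-year *fatal* CVD (no HDL term): per cause (CHD / non-CHD),
`S(a) = exp(−exp(α)(a−20)^p)`, exposure acting as `S^exp(w)` with
`w = β_chol(TC−6) + β_sbp(SBP−120) + β_smk·smoker`, 10-year risk
`1 − S(age+10)/S(age)`, summed over the two causes and capped at 1.
Because SCORE targets fatal events only, its absolute scale sits below
SCORE2; it is used purely as a discrimination comparator.

## Frailty index

29 items across functional limitations (6 ADL, 5 IADL, 1 mobility),
self-reported health (5-level ordinal mapped to {0, .25, .5, .75, 1} and
a health-worsening flag), the 8 CES-D-8 depressive-symptom components,
6 medical conditions, and cognitive impairment. Each item maps raw
values deterministically into [0, 1]; missing raw values stay missing
and are never imputed to zero. FI = sum of deficit scores / number of
items considered; frail ⇔ FI ≥ 0.25 (boundary inclusive). The default
completeness policy requires ≥ 80% of subset items non-missing and
divides by the observed-item count; a strict mode (all items, fixed
denominator) is available. The revised 26-item index drops the items
tagged hypertension / stroke / diabetes, removing overlap with the risk
equations' inputs; on vectors where those three scores are zero it
equals (29/26) × the 29-item FI exactly. Ordinal cut-offs in the shipped
registry are editable configuration, not asserted survey codings.

## Group-based trajectory model

The FI panel is modelled as a K-component mixture: participant i in
group k has `y_it ~ N(poly_k(t_it), σ)` censored at [0, 1], observations
independent within participant given the group. Censoring means a value
*at* a bound contributes the tail mass (e.g. `Φ((0−μ)/σ)` at zero) —
appropriate because item-sampled FI has a genuine point mass at 0.

Estimation: the observed-data log-likelihood
`Σ_i log Σ_k π_k Π_t f(y_it)` is maximised by L-BFGS-B with analytic
gradients (responsibility-weighted score contributions), parameterised
by polynomial coefficients, log σ and group logits. Time is internally
rescaled to [0, 1] for conditioning and coefficients returned in
per-year units. The plain-normal mode instead runs EM with closed-form
weighted polynomial regression in the M-step; its log-likelihood is
asserted non-decreasing every iteration. Restarts (default 10; the
pipeline uses 2–3) are initialised from k-means on per-participant OLS
intercept/slope summaries, perturbed after the first; σ has a floor of
1e-4. Convergence: |Δ log L| below `tol` (1e-6).

σ is **shared across groups by default** (the convention of the
classic trajectory software); per-group σ is an option. This matters:
with per-group σ a spurious extra group can "fit" the mean-dependent
variance of an item-sampled FI rather than a distinct trajectory, while
the shared-σ model resolves the generated three-class structure cleanly.

Model selection fits K over a grid (orders fixed at quadratic by
default, configurable) and takes the BIC optimum
(`−2 log L + p·ln(N_participants)`); the full candidate table (log L,
BIC, min π_k, min APP) is always returned. Groups are then ordered by
fitted mean FI at the final observation time (ties by fitted slope) and
labelled stable / moderate / accelerated when K = 3, `group_k`
otherwise. Adequacy: average posterior probability of assignment APP_k
and odds of correct classification
`OCC_k = [APP_k/(1−APP_k)] / [π_k/(1−π_k)]`.

## Association models

**Modified Poisson.** Risk ratios for the binary accelerated-trajectory
outcome come from Poisson log-link ML (IRLS) with the HC0 sandwich
`B M B`, `B = (X'WX)^{-1}`, `M = Σ w_i (y_i−μ_i)² x_i x_i'`. Grouped
events/total strata are expanded to frequency-weighted binary rows; the
explicit weighted sandwich makes the grouped and individual-level paths
agree to machine precision (tested to 1e-8). For a saturated categorical
model the RR is the ratio of proportions and
`var(log RR) = (1−p₁)/e₁ + (1−p₀)/e₀` — the closed form that reproduces
every printed grouped-count CI. Wald 95% CIs use z = 1.96 on the log
scale. Trend models code the categories 0/1/2; the per-10% model divides
the continuous risk percentage by 10. Zero events in the reference
category or diverging coefficients (separation) raise errors.

**Linear mixed models.** Physical-function outcomes follow
`y ~ category + time + category×time` with a random intercept and random
time slope per participant and Toeplitz-structured residual correlation
across waves (correlation by lag, default lag order = waves − 1). The
marginal covariance `V_i = Z_i G Z_i' + σ² R_i(ρ)` is fitted by direct
ML: fixed effects are profiled out by GLS, and the profile likelihood is
maximised over (Cholesky of G, log σ, tanh-mapped lag correlations) by
Nelder–Mead with a BFGS polish — chosen after the bounded quasi-Newton
path proved unreliable on this surface. Participants are batched by
observation pattern so each V is factorised once per pattern per
evaluation. A non-PD Toeplitz fit falls back to independent residuals,
flagged. Inference is large-sample Wald; no small-sample
degrees-of-freedom correction is applied (with thousands of
participants its effect is negligible), and the fit object records this
convention. The category×time coefficients are the per-year slope
contrasts vs the low-to-moderate category.

## Predictive-utility battery

AUC uses the midrank Mann–Whitney estimator (+½ per tied pair); the CI
comes from the DeLong structural components. The paired DeLong test
compares two markers on the same individuals. The weighted AUC is the
weight-product pair estimator over case–control pairs (computed by
sorting and cumulative weights), with an approximate placement-value CI;
because DeLong theory is not defined for weighted data, the weighted
marker comparison reports a stratified-bootstrap p-value, labelled as
such. Continuous NRI counts *any* risk movement
(`P(up|event) − P(down|event) + P(down|non-event) − P(up|non-event)`);
IDI is the difference in discrimination slopes and that identity is
asserted to 1e-12 on every call. Calibration uses deciles of predicted
risk (empty bins merged and flagged); Brier = mean squared error of the
risk. Decision curves evaluate `NB(t) = TP/n − FP/n · t/(1−t)` on a 1%
grid over (0.01, 0.60) with treat-all and treat-none references.
Markers whose values exceed 1 are treated as percentages and divided by
100 for the risk-scale metrics.

## Selection-bias weighting

Inclusion probabilities come from a binary logistic model of the
inclusion flag on baseline covariates (set configurable; default age,
sex, SBP, TC); included participants are weighted by 1/p̂, truncated at
the 99th weight percentile by default (untruncated mode available; the
cap is recorded). Balance is reported as absolute standardized mean
differences — continuous: |Δmean|/pooled SD; binary:
|Δp|/√[(p₁(1−p₁)+p₀(1−p₀))/2] — with weighted SMDs computed against the
*same* pooled-SD denominator so the before/after columns of a Love plot
share a scale.

## Study pipeline

Exclusions apply in the stated order — (1) baseline CVD or diabetes,
(2) baseline frailty (FI ≥ 0.25, or baseline FI missing), (3) incomplete
risk-equation inputs, (4) fewer than 2 observed waves (the
loss-to-follow-up rule; the minimum is configurable) — with each
participant counted at the first criterion matched, and the ledger's
counts summing to input − retained by construction. An internal audit
recomputes every category RR from the emitted events/total table and
aborts on mismatch. The baseline descriptive table (t / χ² / Wilcoxon
two-group comparisons) is reporting, not methodology. Reruns with the
same configuration and seed are byte-identical.

## Synthetic cohorts: what they emulate, and what they do not

Each participant draws a latent class (default proportions
0.62 / 0.27 / 0.11, echoing the relative sizes of reported stable /
moderate / accelerated groups), then covariates whose distributions
shift by class — age N(62/66/70, 8.5²) truncated at 50, smoking
10/16/22%, SBP N(131/137/141, 18²), with sex 44.3% male and TC/HDL
class-independent — so the overall baseline moments land near the
published cohort descriptions (age ≈ 64 ± 9, smoking ≈ 13%,
SBP ≈ 134 ± 18) and the risk score genuinely predicts class. Latent FI
follows the class polynomial — stable 0.07 + 0.004t, moderate
0.10 + 0.018t, accelerated 0.14 + 0.016t + 0.0016t² (t in years; curves
clamped to [0, 1]) — plus an occasion-level N(0, 0.04²) wobble, and the
29 items are drawn to invert the index: binary items
Bernoulli(latent FI), the ordinal item a scaled binomial with matching
expectation. The baseline FI mixture has median ≈ 0.08, matching
reported non-frail cohorts. Function outcomes decline linearly with
per-year slopes set by the participant's risk *category* (defaults
reproduce the reported UK-style contrast magnitudes); trials add
independent noise. Dropout is monotone and by default
missing-at-random given baseline age (logit-linear), with an MCAR mode
for mixed-model sanity checks. A fraction of participants carries
baseline disease flags or a missing HDL so each exclusion criterion has
real work to do.

Deliberate simplifications: no persistent person-level FI shift by
default (the generator matches the trajectory model's
conditional-independence assumption; a `fi_person` SD can be switched
on to study the violated-assumption case, in which information criteria
are known to inflate the group count), items are conditionally
independent given the latent FI (real deficits correlate beyond it),
covariate effects on class are one-directional, and no sampling
weights, household structure or instrument effects. Passing tests
therefore demonstrate the *estimators* behave correctly under the
stated generative conditions — not that real panel data are this clean.
With every noise SD at zero the generator emits items equal to the
latent FI (as scale values; compute the panel with `mapped=True`) and
exact function values, giving machine-precision oracles for the mean
structure.

## Numerical choices and degenerate inputs

- Poisson IRLS: convergence at max |Δβ| < 1e-10, 200 iterations;
  |β| > 25 treated as separation.
- GBTM: σ floor 1e-4; degenerate groups (π below max(2/N, 0.005))
  warn; all-restart non-convergence raises an error carrying the
  best-so-far fit.
- LMM: log-scale variance parameters; lag correlations in
  (−0.95, 0.95) via tanh.
- AUC with a single outcome class, empty trial lists, zero pooled SDs,
  empty calibration bins: errors or flagged-missing values as
  documented per function, never silent zeros.
- All randomness flows through `numpy.random.default_rng(seed)`; every
  fit records its seed.

Problem sizes in the shipped analyses (2000 participants per cohort,
seven biennial waves, five trajectory-model candidates with two restarts
each) were chosen as comfortable desk-scale defaults; all are
configuration.

## Known limitations

- The packaged risk-equation coefficients follow the published sources
  but the upstream authors' exact calculator is not available for
  bit-level comparison.
- Covariate-dependent group membership, dual-trajectory and
  survival-joint trajectory models are out of scope.
- The per-10% risk-ratio and AUC magnitudes of the real cohorts are not
  generator targets; on synthetic data only their direction and rough
  scale are meaningful.
- Categorical NRI, time-to-event concordance and stabilized or
  doubly-robust weights are not implemented.
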