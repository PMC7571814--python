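# Methods

`cohortsample` implements and compares sampling designs for two-phase
biomarker studies in time-to-event cohorts: a cohort with complete
follow-up exists, but an expensive marker can only be measured on a subset
of the banked samples, and the number of events is too large to include
them all. This note records the models, the estimators attached to each
design, the resampling methodology, the synthetic-data generators, and the
numerical choices; design rationale is given where the design was genuinely
open.

## Designs and inclusion probabilities

Let the cohort have `N` subjects with follow-up times `T_i`, event
indicators `D_i` and covariates `x_i`. A subject is *at risk* at `t` when
`T_i >= t` (ties included; the convention is stated because nothing in
incidence-density sampling forces either choice). The six designs:

- **full** — everybody; the gold standard the others are measured against.
- **srs** — `n` subjects uniformly without replacement, event status
  ignored. Constant inclusion probability, so unweighted Cox applies.
- **ncc** — every case, plus `m` controls per case drawn uniformly from
  its risk set minus the case (incidence-density sampling).
- **modncc** — cases first thinned with probability `P` (or to a fixed
  count, for reproducing fixed sample-size comparisons); controls only for
  sampled cases.
- **cc** — a uniform subcohort of size `qN`, extended by all cases outside
  it.
- **modcc** — as `cc` but out-of-subcohort cases thinned with probability
  `r`; subcohort cases are always kept.
- **egs** — extreme groups only: cases with an event before `t1` and a
  1-per-case draw from the subjects still event-free at `t2 >= t1`
  (observed time `>= t2`; a later event does not disqualify, which is the
  literal reading of "event-free at t2"). Everyone else — censored before
  `t2` or failing inside `[t1, t2)` — is excluded.

### NCC-type weights

Rather than a stratified (matched-set) analysis, sampled controls are
re-used at every event time where they are at risk, so each subject needs
its *overall* inclusion probability. For a non-case,

    p0_i = 1 - prod_{t_j <= T_i} (1 - P * m / (n(t_j) - 1)),

the product running over the cohort's case event times with `n(t)` the
risk-set size; each factor is the probability of *not* entering at that
event time, marginally over the Bernoulli case thinning. For a case,
`pi_i = P + (1 - P) * p0_i` with its own event time removed from the
product: a case missed by the thinning stays eligible as a control, and if
drawn it enters with its full follow-up and event status. The analysis
weight is `1 / pi_i`. At `P = 1` this is the classical Kaplan-Meier-type
weighting and cases get weight 1.

The marginal form (expectation over the case thinning) was chosen over
probabilities conditional on the realized case set because it is closed
form, reduces exactly to the classical weights at `P = 1`, and is directly
testable: the package's tests verify the empirical inclusion frequency of
every subject of a toy cohort against `pi_i` over 20 000 simulated draws.
These probabilities are exact, not approximate — control draws are
independent across risk sets given the case set, and the thinning is
independent Bernoulli — so the Horvitz-Thompson identities
`E[sum 1/pi] = N` and `E[sum D/pi] = #events` hold exactly and are also
tested.

### Case-cohort weights

Time-fixed inverse sampling probabilities (Lin-Ying style): non-case in
the subcohort `1/q`, case `1/(q + (1-q) r)`. The classical case-cohort
design is `r = 1` (case weight 1). Time-fixed weights were preferred over
time-varying (Borgan-II) weights as the simplest estimator consistent with
plain inverse-probability weighting; the weight function is isolated in
`ipw_weights` and swappable.

## Estimation

- **Weighted Cox** (`fit_cox`): lifelines' partial-likelihood maximizer
  with Efron tie handling (Newton precision tightened to 1e-11 so results
  agree with an independent implementation to 6 decimals) and the
  score-residual sandwich variance. Wald tests and confidence intervals
  for sampled designs use the robust SE; full-cohort summaries report the
  model-based SE alongside. Breslow ties are available for cross-package
  comparison but only for unweighted fits (routed through statsmodels
  PHReg, which does not take weights); weighted analyses are always Efron.
  Non-convergence and separation are flagged on the result, not raised.
- **EGS screening test** (`egs_logistic_test`): logistic regression of
  early-case status on the marker, ML (observed-information) variance.
  This is the design's power workhorse — it asks only "do the extreme
  groups differ?", not "what is the hazard ratio?".
- **EGS hazard-ratio estimation** (`egs_conditional_fit`): a naive Cox fit
  on the extreme groups is biased because the design deletes the middle of
  the outcome distribution. The package fits a parametric conditional
  likelihood under a Weibull proportional-hazards model
  `S(t|x) = exp(-(t/scale)^shape * e^{x'b})`: conditional on inclusion, a
  case contributes `f(T_i|x_i)/D(x_i)` and a control
  `rho * S(t2|x_i)/D(x_i)`, with `D(x) = F(t1|x) + rho * S(t2|x)` and
  `rho` the fraction of eligible controls actually drawn (recorded by the
  design). Optimization is quasi-Newton (L-BFGS-B) over
  `(log shape, log scale, b)` from a neutral start (`b = 0`, scale at
  `t2`), tolerance 1e-8 on the relative objective change, with one
  Nelder-Mead polish on failure; SEs come from the inverse numerical
  observed information. This is a documented parametric stand-in for the
  conditional likelihood literature it approximates; it is labelled as
  such in the API and its fidelity to any particular published EGS
  hazard-ratio value is not claimed. Shape and scale are weakly identified
  from extreme groups alone (only event times below `t1` and survival
  status at `t2` carry information), which inflates their variance but
  leaves the covariate log hazard ratios well behaved; the package's
  recovery tests check the latter, not the former.

## Evaluation methodology

Two experiments per design, both seeded by repetition
(`default_rng(SeedSequence([master_seed, rep]))`, so results are
independent of execution order and identical master seeds give identical
results):

- **Repeated sampling** (`repeated_sampling_experiment`): apply the design
  `M` times to the *fixed* cohort, fit the design-appropriate model,
  record the marker coefficient and whether its Wald test rejects at
  `alpha = 0.05` (two-sided, no multiplicity adjustment — one marker per
  experiment). The SD of the coefficients is `sampSE` (design-induced
  variability only); the rejection fraction is the power. For EGS the
  coefficient comes from the conditional fit and the power from the simple
  (marker-only) logistic test.
- **Bootstrap cohorts** (`bootstrap_experiment`): draw `M` with-replacement
  resamples of size `N`, apply the design once to each, fit; the SD of the
  coefficients is `totalSE`. The bootstrap cohort of repetition `k`
  depends only on `(seed, k)`, so different designs run with the same
  master seed are compared on paired cohorts. The full design gives the
  full-cohort empirical SE.

`IF = totalSE(design)/totalSE(full)`; relative efficiency between designs
is `(IF_a/IF_b)^2`. For modNCC the closed-form approximation
`IF ≈ 1/sqrt(P m/(m+1))` (derived for the stratified analysis, hence an
upper bound for the weighted one) is provided as
`analytic_inflation_factor`. Non-converged repetitions are dropped from
SDs and reported as a count; the Monte-Carlo SE of a reported SD is
`SD/sqrt(2(M-1))`.

Default `M` is 1000 (the CLI's `--full-M` switches to 10 000). The
package's own test suite runs the unbiasedness checks at `M = 2000` and
the totalSE/ordering checks at `M = 1000` on the 1550-subject generator
cohort — sizes at which the orderings under test are separated by many
Monte-Carlo SDs.

## Synthetic cohorts

`dachs_like` (N = 1550) emulates a population-based colorectal-cancer
cohort: age truncated-normal 68.6 (sd 10.5, range 33-94), 42.6% male,
tumor stage categorical (18.6/33.0/34.4/14.0%), adjuvant chemotherapy
46.5%, and a binary microsatellite-instability marker of prevalence 9.4%;
true log hazard ratios (0.019, -0.002, 0.490, 1.150, 2.776, -0.224,
-0.229) for (age, male, stage 2/3/4 vs 1, chemo, marker). `gbsg_like`
(N = 686) emulates a node-positive breast-cancer trial: binary
progesterone-receptor marker (prevalence 60%, true log HR
log 0.53 = -0.635 — the calibration-critical value), plus hormonal
treatment, age, menopausal status, estrogen-receptor status and the
Nottingham Prognostic Index `0.02*size + node stage + grade` computed from
simulated size/nodes/grade; the adjustment effects are plausible
magnitudes, not estimates from the original trial.

Event times are Weibull PH with shape 1 (constant baseline hazard — the
published cohorts give no information on baseline shape beyond the event
fraction and median follow-up, so the simplest choice is used and the
linear predictor is centered at the covariate means for numerical sanity).
Censoring is independent uniform dropout plus an administrative horizon of
8 years. The dropout span sets the reverse-Kaplan-Meier median follow-up
(`span/2` when below the horizon), so it is uniform(0, 10 y) for the
colorectal-like cohort (median ≈ 5 y) and uniform(0, 9 y) for the
breast-like cohort (median ≈ 4.5 y). The baseline scales (10.434 and
8.074 years) were solved once by bisection at n = 400 000 so the marginal
event fractions are 36.7% and 43.6%, and are frozen in the source; they
are never re-fit at run time.

What the generators deliberately do **not** reproduce: covariate
correlations (stage and chemotherapy are strongly dependent in real
cohorts; here everything is independent), non-proportional hazards,
informative censoring, and any baseline-hazard shape information. Tests
passing on these cohorts therefore demonstrate correctness of the design
and estimation machinery under the stated model, not robustness to
violations of it. One concrete consequence of the constant baseline
hazard: the extreme-group contrast with `t2 = t1` at an early boundary
(~1.2 y) amplifies the marker's log odds ratio only mildly over its log
hazard ratio, so the screening-power advantage of extreme-group sampling
shows up robustly on these cohorts with the 5-year landmark variant
(`t2 = 5`), where the amplification is large (the extreme-group log odds
ratio roughly doubles the log hazard ratio); real cohorts with steeper
early survival separation show the advantage for both variants.

## Degenerate inputs and tie-breaks

- A cohort with no events yields an empty NCC sample with a warning; an
  empty EGS stratum raises, since no analysis is possible.
- A case whose risk set contains nobody else simply matches 0 controls
  (warning); its weight product is unaffected because no factor applies.
- EGS `t1` calibration searches the grid "just above each observed case
  event time" (`nextafter`) for the smallest `t1` whose achieved size —
  `n_cases + min(controls_per_case * n_cases, n_eligible)` — reaches the
  target; ties break toward smaller `t1`. With `t2` tied to `t1` the
  achieved size need not be monotone, so the scan is exhaustive.
- Missing marker values are legitimate cohort state (phase-two reality);
  fits fail fast on missing modelled covariates unless `drop_missing=True`
  is passed explicitly.
- The reverse-Kaplan-Meier median follow-up uses R's `survfit` convention:
  when the censoring-KM curve hits 0.5 exactly at a drop time, the median
  is the midpoint of that time and the next drop time.

## Known limitations

- On a *fixed* cohort, the repeated-sampling mean of a design's estimator
  need not equal the full-cohort estimate even with exact inclusion
  probabilities: the weighted Cox statistic is nonlinear, so its design
  expectation carries a conditional finite-sample deviation of order
  1/n_sample. The package's experiments detect this for the time-fixed
  IPW case-cohort estimator at the ~418-of-1550 geometry (a deviation of
  roughly +0.01 to +0.03 on the marker log HR, shrinking to Monte-Carlo
  noise on a cohort eight times larger); the NCC-type and SRS estimators
  show no detectable deviation at the same size. Inclusion probabilities
  themselves are exact (verified by simulation), so this is a property of
  the estimator, not of the weights.
- modNCC with `m > 1` uses the same weight formulas but no published
  number exercises it; it is covered only by the Horvitz-Thompson and
  inclusion-frequency property tests.
- The EGS conditional estimator assumes the Weibull family; under gross
  misspecification of the baseline its hazard-ratio estimates inherit
  bias (the screening test does not, as it is model-free in time).
- No counter-matching, stratified subcohorts, quota sampling, competing
  risks, interval censoring or high-dimensional screening.
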