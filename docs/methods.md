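# Methods

## The estimation problem

In a randomized trial with recurrent events, the PWP family stratifies the
Cox partial likelihood by event number so that each recurrence has its own
baseline hazard.  The gap-time variant (the package default) resets the
clock at every event; the counting-process variant keeps calendar time.
Stratification is the model's strength — it tracks disease progression —
and its weakness: membership in stratum k > 1 requires k − 1 observed
events, so the analysis conditions on a post-randomization outcome.  Any
baseline covariate that influences event risk then differs systematically
between arms inside later risk sets (conditioning on a collider), and the
estimated treatment coefficient absorbs that imbalance.  With protective
covariates the unweighted PWP is biased toward the null and its test
over-rejects; the bias grows with the covariate effect size.

## Entropy balancing of risk sets

The correction re-weights every stratum k > 1 so that it again resembles a
randomized sample.  Within each arm separately, weights minimize the
Kullback–Leibler divergence from uniform reference weights subject to the
arm's weighted covariate means equalling the pooled (both-arm) risk-set
means — first moments only — and the arm's weights summing to its size.
The KL dual reduces each arm's problem to P unconstrained variables (one
per balanced covariate) with weights of exponential-tilt form
`w_i ∝ exp(λᵀ x_i)`; the package solves the dual with damped Newton
iterations (backtracking on the dual potential), declaring convergence
when the largest constraint violation is below 1e−8 (default; far below
any balance diagnostic that matters) within 200 iterations.  Stratum 1
keeps unit weights.  Feasibility requires the pooled mean to lie inside
each arm's covariate hull; the solver checks the per-coordinate ranges
first and raises a named infeasibility error otherwise.

Weights enter the stratified partial likelihood both in the event terms
and the risk-set sums, giving exactly the weighted score equation whose
root is the reported log-hazard-ratio.  Weights are treated as fixed in
the variance; the sandwich estimator aggregates weighted score residuals
within subject across rows and strata.  This ignores the sampling
variability of the weights themselves — a known, deliberate limitation.

### Stratum restriction

Later risk sets shrink quickly.  Two rules limit the analysis:

* **Eligibility** (default): retain the longest prefix of strata in which
  both arms have at least two members.  A stratum that passes this rule
  can still be infeasible to balance (pooled mean outside one arm's hull);
  the retained prefix then ends at the first such stratum.  On the bladder
  data this keeps strata 1–5: stratum 6 has ≥2 per arm, but its treated
  members all have 5–6 initial tumors against a pooled mean of 3.4.
* **SMD**: after weighting, drop everything from the first stratum (k ≥ 2)
  in which any balanced covariate has |SMD| ≥ 0.1.  Stratum 1 is never a
  cut point — it is the randomized sample itself, and its (chance)
  imbalance is not a weighting failure.

SMD is defined as the difference of weighted arm means divided by the
*unweighted* pooled sample SD (ddof = 1) of the whole stratum, so pre- and
post-weighting values share a denominator.

The stabilized-IPW alternative (`weight_method="ipw"`) weights by
P(A)/P(A|X) from a main-effects logistic propensity model per stratum,
with no truncation of extreme weights; its instability in small strata is
a phenomenon the package is meant to be able to exhibit, not hide.  A
stratum whose propensity fit separates perfectly ends the retained prefix.

## Partial-likelihood engine

One engine serves all survival presets, differing only in the model
specification: risk-interval scale (gap or counting-process), stratified
or not, weighted or not, naive or cluster-robust variance,
first-event-only or all rows, optional covariate adjustment in the linear
predictor (outcome regression).  Conventions:

* Ties: Breslow approximation.  Simulated times are continuous (ties have
  probability zero) and Breslow extends transparently to weighted
  likelihoods; the real-data fits match survival software run with the
  same choice.  Efron weights are not implemented.
* Newton–Raphson from β = 0 with step-halving; a step is accepted if the
  log-likelihood does not fall by more than 1e−9·(|ℓ|+1) (floating-point
  slack at the likelihood's magnitude).  Convergence: max |score| < 1e−8
  or step < 1e−9 with the score tolerance met; at most 50 iterations.
* Monotone likelihood (separation) is reported as an error when the
  estimate runs away (|β| > 10 at an apparent optimum, or > 50 mid-path).
* 95% CIs are Wald intervals on the log-HR scale using the variance the
  model prescribes: naive for Cox/AG/PWP/PWP-CP, robust clustered on
  subject for LWYY, PWP-robust and the weighted PWP.
* Risk sets are half-open intervals (start, stop]: a subject is at risk
  at t iff start < t ≤ stop.  Risk-set sums use suffix cumulative sums
  over rows sorted by stop (minus a start-sorted correction under left
  truncation), so each likelihood evaluation is O(rows · log rows).

Count-model comparators collapse the history to one record per subject
(total events, total follow-up) and fit log-link rate models with a
log-exposure offset through statsmodels: Poisson GLM, and NB2 negative
binomial with maximum-likelihood dispersion.  Total follow-up equals the
sum of gap durations because the designs considered have no risk-free
intervals.

## Simulated trials

The generator draws each subject's successive gap times from Weibull
distributions: survival `S_k(t) = exp(−λ_k t^{q_k})` with
`λ_k = exp(−q_k (β0_k + A β + Xᵀγ))`, so within stratum k the treatment
hazard ratio is `HR = e^{−q_k β}` and each covariate's is
`HR_cov = e^{−q_k γ_p}`.  Defaults define the four study scenarios:

| parameter | value |
| --- | --- |
| shape q | (1.5, 1.5, 1.5, 1.5, 1.5), reused beyond k = 5 |
| baseline β0 | (6, 5.5, 5, 4, 3), reused beyond k = 5 |
| treatment | Bernoulli(0.5); HR 0.75 (scenarios 1–2) or 1 (3–4) |
| covariates | five iid N(0,1); HR_cov 0.9 (scenarios 1, 3) or 1.2 (2, 4) |
| follow-up | 730 days, administrative censoring only |

Falling β0_k means the baseline hazard rises steeply with the event
number — the progression pattern (falls, heart-failure readmissions) that
motivates stratified modelling in the first place.  Time is measured in
days: with a two-year horizon read as t = 2 the β0 values above would
produce essentially no events (cumulative hazard ≈ 2×10⁻⁴), whereas
t = 730 gives a baseline subject a ≈ 91% first-event probability and a
rich multi-event structure; the follow-up is configurable.  Gap k is
generated only for subjects whose event k − 1 was observed; the gap that
crosses the horizon is recorded as a censored interval truncated at the
remaining time (a switch can drop such partial gaps instead).  Sampling
is one inverse-transform draw per gap from a single per-trial generator
seeded by the trial seed; replicate seeds are spawned from the study seed
via `numpy.random.SeedSequence`, so studies are reproducible end to end.

What the generator does *not* emulate: informative or intermittent
censoring, risk-free intervals after events, unmeasured frailty,
event-specific treatment effects, or calendar-time baselines that differ
by stratum.  Passing tests therefore certify the estimators under
administrative censoring with measured, constant covariates — not
robustness to those departures.

## Monte Carlo evaluation

For each scenario × sample size × model, the harness simulates replicate
trials, fits, and reports: mean HR and bias (on both HR and log-HR
scales; the HR scale is the headline), and the rejection rate of the
nominal two-sided 0.05 Wald test (type I error under null scenarios,
power otherwise) with Monte Carlo SE `√(p̂(1−p̂)/n_sim)`.  A CI endpoint
exactly at 1 counts as non-rejection (measure-zero; documented
convention).  Replicates whose fit fails to converge are excluded from
the proportions, shrinking the effective n_sim, and counted separately.
Default study size is 1000 replicates — rates are then resolved to about
±0.015 at worst — with larger runs available by configuration.

## Design choices where the design was open

* The "partly weighted" variant balances the first three of the five
  covariates; the subset is configurable.
* Only first-moment balance constraints and the KL divergence are
  implemented; the moment functions and the divergence family are the
  natural extension points but higher moments/other Rényi members are out
  of scope.
* The bladder analyses use gap-time risk intervals for the PWP fits (the
  counting-process preset exists but is not the default), and the
  weighted fit uses the eligibility rule; on these data the SMD rule
  selects the same strata.
* The count-model offset is calendar follow-up, identical here to summed
  gap time.

## Known limitations

Weights are estimated but treated as fixed in the variance.  No frailty
or random-effects extension.  No time-varying covariates or coefficients,
no competing risks, no left truncation beyond counting-process entry.
The balancing restores only the *measured* covariates' first moments;
imbalance in unmeasured factors or higher moments can remain.
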