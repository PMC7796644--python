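# Methods

## Landmarking and the counting-process representation

The analysis origin is shifted to a landmark L after randomization
(default 182 days ≈ 6 months; "6 months" is ambiguous between 168 and
182 days, so L is configurable).  Patients who died, progressed, left
follow-up, or lacked required baseline covariates before L are excluded,
in that order of precedence, with per-category counts reported so that
n_input = n_analyzed + Σ exclusions always holds.  Remaining times are
re-expressed relative to L; doses given before L are *kept with negative
times*: "overall"-scope exposures use them, "CFI"-scope exposures drop
them (scope is operationalized purely by the sign of the shifted dose
time, so re-treatment doses given after the landmark count toward the
CFI scope as well).

Follow-up is cut into `(start, stop]` rows.  The default cut policy is
the union of all cohort death times and the patient's own dose and
covariate-update times.  Time-varying covariates are
last-observation-carried-forward onto each row (value = most recent
update at or before the row's start).  Exposure metrics are evaluated at
each row's **stop**: because every cohort death time is a cut point, the
row that enters the partial likelihood at a death time ends exactly
there, so stop-evaluation makes every metric — including the
continuously decaying ones — exact at the only times the likelihood
reads covariates.  (Start-evaluation would lag TBC/WCE by one inter-cut
gap; for step-constant CE the two coincide since dose times are also cut
points.)

Boundary convention throughout: a dose at time t_k affects the hazard
only at strictly later times (t_k < t).  This prevents same-day
reverse causation by construction.

## Exposure metrics

* **CE(t)** — running dose sum, right-continuous step function.
* **CEQ(t)** — categories recomputed within the risk set at every event
  time.  Tertile scheme ("model 3a", CFI scope): control arm is the
  reference regardless of its dose history; maintenance patients with
  CE(t)=0 form their own category; tertiles are computed among
  maintenance patients with non-zero CE(t).  Quartile scheme
  ("model 3b", overall scope): quartiles of the non-zero values over the
  whole risk set, zero values falling into the reference first quartile.
  Cutpoints use the linear-interpolation ("type 7") quantile convention;
  ties go to the lower category.  If a risk set at an event time has
  fewer distinct non-zero values than categories, the model is reported
  as failed for that analysis (degenerate risk set) rather than silently
  recoded.
* **StCE(t)** — z-scores over the risk set at each event time, sample
  (n−1) standard deviation; a zero-variance risk set maps to all zeros.
* **TBC(t)** — exponential decay with half-life h = 20 days (the drug's
  published pharmacokinetic half-life).  Doses are recorded in units of
  one cure; the pipeline reports TBC in mg/kg (5 mg/kg per cure) so the
  fitted hazard ratio reads "per 1 mg/kg of circulating drug".
* **WCE(t)** — cubic B-spline weight function on [0, window].  Interior
  knots (1 by default, up to 3) are placed at quantiles of the observed
  (event time − dose time) lags inside the window, falling back to
  equally spaced placement when lags are scarce.  The basis is
  unconstrained at the right end by default; a constrained variant drops
  the last two basis functions, forcing w(window)=0 smoothly.  Both can
  be compared by AIC.

## Cox engine

The partial likelihood is maximised by Newton–Raphson with step-halving
directly on the counting-process data (Efron tie handling by default,
Breslow available).  Covariates are centred and scaled internally (an
exact reparametrisation) so conditioning does not depend on covariate
units; estimates and covariance are mapped back.  Risk-set sums use a
difference-array accumulation — each row covers a contiguous range of
event indices — keeping each iteration O(rows × p²) without per-event
row scans.

Convergence: score infinity-norm below 1e−8; at most 100 iterations.
On large tables (~10⁵ rows) the log likelihood (magnitude ~10³)
flattens at double precision before the score reaches the strict
tolerance; a step-halving plateau with standardized score below 1e−4 is
then accepted as converged — the corresponding coefficient perturbation
is orders of magnitude below statistical precision (this mirrors the
relative-likelihood criterion of standard survival software).  Constant
or collinear designs raise a singular-design error; diverging
coefficients (monotone likelihood) raise a convergence error rather
than returning a spurious estimate.  Wald 95% intervals from the
inverse observed information are used throughout.

AIC = 2k − 2·loglik and deviance = −2·loglik, so AIC = deviance + 2k; a
WCE model with J basis functions counts k = J + (adjustment
covariates).  Window selection fits one WCE model per candidate window
and takes the arg-min AIC, preferring the smaller window on ties and
excluding (with a warning) candidates that fail to converge.

Hazard-ratio curves for dosing patterns: HR(t) = exp(Σ X(t_k)·ŵ(t−t_k))
against a zero-dose reference, with pointwise bands by the delta method
(var ŵ(u) = b(u)ᵀ Cov(θ̂) b(u)); for the concentration model,
HR = (unit HR)^TBC(t).

## Proportional-hazards diagnostic

The Grambsch–Therneau global test regresses Schoenfeld residuals on a
transform of event time (Kaplan–Meier 1−S(t) by default; identity and
rank available) and uses the classic pooled-variance approximation
V(t) ≈ I/d: global statistic d·Uᵀ I⁻¹ U / Σ(g−ḡ)², χ² with df = k.
Residuals use Breslow risk-set means; with continuous event times (the
case in all simulated data) this coincides with the Efron form.  Note
that recent versions of other survival software compute an exact-
information variant of this test; values agree in magnitude but not to
machine precision.

## Synthetic maintenance-trial generator

The generator reproduces the *structure* of a two-arm maintenance RCT:

* 1:1 allocation, baseline covariates with realistic marginals
  (age groups ~52/31/17%, 35% women, 18% elevated alkaline
  phosphatase, four tumour sites);
* 24-week biweekly induction in both arms, then alternating
  chemotherapy-free intervals (CFI) and 16-week re-treatment sequences;
  CFI lengths are log-normal with median 120 days (the true
  distribution is unpublished — this is a placeholder, configurable),
  snapped to whole 14-day cycles so dosing stays on the biweekly grid;
* during CFI only the maintenance arm doses, each scheduled cure taken
  with adherence probability 0.8 (placeholder); both arms dose during
  induction and re-treatment; dosing stops at protocol discontinuation
  (exponential, ~48% by four years, category weights 28.7/8.3/11.3%
  investigator/toxicity/other);
* 8-weekly covariate assessments: WHO performance status as an
  upward-drifting Markov chain on {0,1,2}, a toxicity indicator that can
  switch on after recent dosing, and bounded random walks for weight,
  hemoglobin, bilirubin and blood pressure;
* survival by inversion of a daily-piecewise-constant hazard
  h(t) = h₀(t)·exp(effect·Exposure(t) + γᵀZ(t)), exposure evaluated at
  day midpoints with the same code paths the estimators use; event
  times are continuous, so ties have probability zero.

Default truth: log-HR −0.22 per mg/kg of theoretical blood
concentration (hazard ratio 0.80/mg/kg, within the range reported for
this drug class), half-life 20 days, modest covariate effects
(performance status +0.3/level, female −0.15).  The baseline hazard is
piecewise constant (0.55·h₀ before day 182, h₀ = 0.003/day after),
soft-calibrated so that a default cohort shows ≈21% pre-landmark
exclusions, ≈84% deaths among analyzed patients and a median
post-landmark survival of 12–15 months.  These are descriptive
calibrations, not fitted quantities.

What the generator does **not** emulate: tumour progression dynamics
and post-progression treatment switching, competing risks,
multi-compartment pharmacokinetics, measurement error in covariates,
and informative censoring.  Consequently, passing recovery tests shows
the estimators are correct under a faithful data-generating mechanism;
it does not show that real-data estimates are free of the
reverse-causality and confounding-by-indication biases discussed in the
pharmacoepidemiology literature (an optional arm-level non-exposure
effect and adherence–status coupling knobs exist to explore those
qualitatively).

## Replicate studies and problem sizes

The validation suite uses: 20 cohorts of 500 patients for
concentration-effect recovery (mean bias < 10%, CI coverage within
binomial tolerance) and for the AIC ordering of weighted vs. unweighted
models; 20 cohorts of 500 for exposure-window selection (120-day truth,
≥14/20 picks); 100 replicates of n = 200 for the PH test's type-I error
(rejection rate in [0.01, 0.12] at α = 0.05); 50 random dose histories
for the spline-vs-decay consistency bound (< 1% relative error).  The
acceptance script runs one full 382-patient suite plus five 500-patient
recovery replicates — sizes chosen to make every check reproducible on
a laptop-class single core in minutes.

## Known limitations

* The Grambsch test's pooled-variance approximation can be
  anti-conservative with heavily tied data; simulated data here are
  tie-free.
* CEQ category models can legitimately fail on small cohorts (degenerate
  early risk sets); the pipeline records this per model instead of
  aborting the suite.
* Left truncation other than the single landmark, frailty terms,
  time-varying coefficients and penalized splines are out of scope.
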