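# wcetrial

Time-varying cumulative-exposure survival analysis for maintenance-trial
data: five exposure metrics of past drug dosing embedded in time-varying
Cox proportional-hazards models, with AIC model comparison,
spline-estimated weight functions and proportional-hazards diagnostics —
plus a synthetic maintenance-trial generator so the whole methodology can
be exercised and validated without patient data.

## The problem

Intention-to-treat analyses of maintenance trials (continue a biologic
during chemotherapy-free intervals vs. stop) compare randomized arms,
ignoring that actual drug exposure varies hugely between and within
patients over time.  A re-analysis strategy is to restart the clock at a
landmark (6 months post-randomization, the expected start of the first
chemotherapy-free interval), restrict to patients event-free until then,
and model death hazards with *updated* exposure summaries of the dosing
history X_i(t_k):

| metric | definition at time *t* |
|---|---|
| CE    | Σ_{t_k<t} X_i(t_k) — cumulative dose |
| CEQ   | quantile category (tertiles/quartiles) of CE(t) within the risk set at *t* |
| StCE  | risk-set z-score of CE(t) |
| TBC   | Σ X_i(t_k)·0.5^((t−t_k)/h) — one-compartment blood concentration, half-life h = 20 d |
| WCE   | Σ X_i(t_k)·w(t−t_k) — weight function w estimated from the data on a cubic B-spline basis |

Each metric enters an adjusted Cox model on counting-process data
(`(start, stop]` rows, covariates constant within rows).  The WCE weight
function is estimated via artificial covariates
D_j(t) = Σ_{0<t−t_k≤window} X_i(t_k)·B_j(t−t_k), so that the exposure
window (120 / 365 / 730 days) can be chosen by AIC and w(u) recovered
with delta-method pointwise bands.  A global Grambsch–Therneau test
(scaled Schoenfeld residuals vs. transformed event time) checks
proportional hazards for every model.

## Worked example

Simulate a 382-patient maintenance trial whose mortality hazard depends
on the true blood concentration (HR 0.80 per mg/kg, half-life 20 days),
then fit the ITT, cumulative-dose and concentration models:

```
wcetrial simulate --seed 3 --out data
printf 'run:\n  models: ["1", "2b", "5"]\n' > cfg.yaml
wcetrial suite --data data --config cfg.yaml --seed 3 --out out
```

which prints

```
model_id  k         aic  grambsch_p status
       1 15 2572.541798    0.907950     ok
      2b 16 2537.777653    0.079451     ok
       5 16 2412.818960    0.527144     ok
```

Reading the table: the ITT model (randomization arm + adjustment
covariates only) fits worst; adding the updated cumulative dose (model
2b) improves the AIC by ~35 points; the theoretical-blood-concentration
model (model 5) improves it by ~160 — time-weighted exposure carries far
more information about imminent mortality than either the arm label or
the unweighted dose sum, exactly the behaviour expected when effects of
past doses wane.  `hr_table.csv` shows the model-5 concentration hazard
ratio ≈ 0.80 per mg/kg, recovering the generating effect, and the
Grambsch p-values show no evidence against proportional hazards for the
correctly specified model.

The same pipeline is available from Python:

```python
from wcetrial import SimConfig, TrueModel, simulate_cohort, RunConfig, run_model_suite

c = simulate_cohort(SimConfig(n_patients=382), TrueModel(), seed=3)
res = run_model_suite(c.patients, c.doses, c.updates, c.outcomes, RunConfig())
print(res.comparison())            # all nine models 1, 2a/b, 3a/b, 4a/b, 5, 6
print(res.window_selection.aic_table)   # WCE window chosen by AIC
```

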