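# Methods

## Data model

One row per hip-fracture admission: `time` in days from surgery (day of
surgery is day 0), `event` ∈ {0 censored, 1 live discharge, 2 in-hospital
death}, the mobilisation-timing exposure (early = within 36 hours of
surgery, late = two or more days after), the depression stratum, and the
adjustment covariates (age, sex, ethnicity, deprivation decile, number of
comorbidities, ASA-grade band, prefracture residence, fracture type,
prefracture mobility, hospital volume, surgery timing, weekend admission,
admission year). Follow-up is administratively censored at a 30-day
horizon with a **closed boundary**: an event at exactly day 30 counts as
observed; times beyond it are set to 30 and relabelled censored.
Truncation is idempotent and never changes the number of records.

Transfers to other acute/rehabilitation units and loss to follow-up are a
single pooled censoring process, assumed independent of both causes. Missing
covariate values are carried as an explicit `NA` sentinel in files and as
missing values in memory; complete-case filtering is a separate, logged
operation, and file validation is collect-all (every bad row is reported
with its row number and reason) rather than fail-fast.

## Estimators

**Cumulative incidence.** Aalen–Johansen with all-cause Kaplan–Meier
survival: at each distinct event time `t_i` with risk set `n_i` and
cause-k events `d_ki`, `CIF_k` increments by `Ŝ(t_i−) d_ki / n_i`. Ties
across causes share the risk set; censorings at an event time leave the
risk set after the events. The three components satisfy
`CIF_1 + CIF_2 + Ŝ = 1` at every time (checked to 1e-10). An all-censored
cohort yields the degenerate zero estimate with a warning flag.

**Conditional probability of discharge.**
`CP(t) = CIF_discharge(t) / (1 − CIF_death(t))`. The alternative
conditioning set `CIF_1/(CIF_1 + CIF_2)` (probability of discharge among
those who have exited either way) is available behind the
`denominator="cif_sum"` option; the default follows the conditional
probability function as usually defined, conditioning on not having died.
Where the denominator is exhausted (everyone dead), the CPF is defined as
1 from that time on and flagged. `CP` is nondecreasing by construction.

**Confidence bands.** Pointwise 95% intervals by the delta method on the
ratio. The variances and covariance of `(CIF_1, CIF_2)` are estimated by
the leave-one-out jackknife — the same engine that produces the
pseudo-observations — and combined through the gradient of the ratio; the
interval is formed on the complementary log-log scale and back-transformed
(a `linear` option exists). The jackknife was chosen over a closed-form
counting-process variance to keep a single, exactly-testable mechanism for
all second-moment quantities; it is exact full recomputation, with
subjects sharing a (time, event) pattern deduplicated.

**Two-sample comparison.** The integrated weighted CPF difference
`U = ∫₀^τ w(t){CP_a(t) − CP_b(t)} dt` over the pooled event-time grid up
to the horizon τ = 30, scaled by `sqrt(n_a n_b / n)`, with the
censoring-based weight `w = C_a C_b / (p_a C_a + p_b C_b)` built from each
group's censoring-survivor Kaplan–Meier at `t−` (with no censoring, w ≡ 1;
an unweighted diagnostic variant exists). Inference defaults to seeded
label permutation (2,000 draws unless configured otherwise): the
large-sample variance is fragile in small groups. The `analytic` method
standardises `U` by its grouped leave-one-out variance and refers it to
the normal distribution; a non-positive variance estimate falls back to
permutation with a notice. Both methods agree on large samples. The
permutation engine processes observations one at a time in
(time, events-first) order; within a tied time the one-at-a-time factors
telescope to exactly the tied KM/Aalen–Johansen aggregates, which a test
verifies against the unique-time reference estimator to 1e-10.

**Pseudo-value GEE.** Jackknife pseudo-observations
`PV_i(t) = n·ĈP(t) − (n−1)·ĈP^{(−i)}(t)` on the default grid
{3, 4, 6, 8, 12, 16, 20, 24, 30} days; values outside [0, 1] are expected.
The stacked subject × grid table is modelled with logit link, independence
working correlation, and subject-clustered sandwich covariance
(statsmodels GEE is the solver). Time enters as one intercept per grid
time; the exposure effect is shared across the grid by default, with a
time-varying-effect parametrisation (`C(grid_time):early`) for per-day
odds ratios — day-30 contrasts use that parametrisation, since with
exponential hazards the true CPF odds ratio varies over the grid.
Estimation starts from least squares on the empirical logit (the default
GLM start can diverge on wide dummy designs), converges on mean parameter
change below 1e-8 within 100 iterations, and reports non-convergence as a
flag rather than failing silently. Collinear design columns are detected
by pivoted QR, dropped, and reported. Exposure and stratum enter as 0/1
indicators (`early`, `late`, `depression`) so that relabelling the
reference level inverts odds ratios exactly. Complete-case filtering on
the model's columns happens before the jackknife and logs per-column drop
counts. The Wald chi-squared for the depression-by-mobilisation block uses
the robust covariance.

## Synthetic registry generator

Constant (exponential) cause-specific hazards per (stratum, exposure)
cell, optionally modulated multiplicatively by covariates (proportional
hazards per cause); censoring is an independent exponential per cell; the
observed record is the minimum of event, censoring and horizon. Closed
forms `CIF_k(t) = λ_k/λ (1 − e^{−λt})`, `CP(t) = CIF_1/(1 − CIF_2)` and the
implied odds ratios provide exact oracles. All randomness flows from one
integer seed; times are continuous by default (no ties) with a
`round_days` flag for registry-resolution day ties. Piecewise-constant
hazards are not implemented; non-constant specifications are rejected.

Scenarios:

- `nhfd_like_scenario(n_total)` — cell composition 8.31% depression,
  76.7%/78.9% early mobilisation with/without depression; per-cell hazards
  solved so the expected 30-day shares of discharge/death/still-in-hospital
  match the published registry margins (overall ≈52% discharged, ≈4% dead,
  ≈1/3 transfer-censored, with late mobilisers remaining longer). Covariates
  follow registry-style marginals, with care-home admission more common in
  late mobilisers; they do not modulate hazards here, so cell-level closed
  forms stay exact.
- `null_scenario(n_per_group)` — equal hazards in both arms
  (discharge 0.05/day, death 0.005/day, censoring 0.02/day), for test
  calibration.
- `or_recovery_scenario(n_total, target_or)` — the early-arm discharge
  hazard is solved (Brent) so the true day-30 CPF odds ratio equals the
  target exactly (late arm: discharge 0.032, death 0.005, censoring
  0.015 per day; 75% early).
- `confounded_scenario(n_total, target_or)` — care-home admission is far
  more common among late mobilisers (45% vs 12%) and lowers the discharge
  hazard (log HR −0.7); the truth is the day-30 odds ratio at the
  reference (own-home) profile.

What the generator does **not** emulate: within-hospital clustering,
calendar/seasonal effects, non-exponential length-of-stay shapes, and
covariate-outcome dependence beyond the configured multiplicative hazards.
Passing tests therefore demonstrate correctness of the estimators under
independent censoring and proportional cause-specific hazards, not
robustness to violations of those assumptions in real registry data.

## Descriptive outputs

Characteristics table (count and percent within column on non-missing
denominators; median and IQR for age and comorbidity count; chi-square and
Mann–Whitney U early-vs-late comparisons within stratum; optional
small-cell suppression, off by default for synthetic data). Discharge
table per stratum and arm: n, 30-day deaths and live discharges (counts
and percentages of the stratum total), and the live-discharge rate per
1,000 patient-days with an exact Poisson interval. Patient-days accrue on
`[0, t)` — a subject discharged on day 10 contributes 10 days; the
convention is documented here because registries do not fix one.
Percentages print to one decimal; machine-readable frames keep full
precision.

## Validation studies and sizes

The `studies` module fixes the problem sizes used by the acceptance
script and the end-to-end tests: 500 random uncensored cohorts (n ≤ 50)
for the exact counting-oracle identity; one n = 5,000 exponential cohort
(λ₁ = 0.10, λ₂ = 0.01, λ_c = 0.02/day) against the analytic
CP(30) = 0.9596; a 400-subject single-cause cohort for the
logistic-regression identity (tolerance 1e-6); 2,000 null replicates of
200 + 200 subjects with 500 permutations each for the type-I error;
200 replicates of n = 2,000 for day-30 odds-ratio recovery and coverage;
200 confounded replicates of n = 2,000 for the adjusted-vs-unadjusted
comparison; and two identically-seeded n = 600 pipeline runs for
determinism.

## Known limitations

- The analytic two-sample variance is a jackknife estimate, not the
  original closed-form derivation; permutation is the recommended and
  default inference path.
- The shared-effect GEE estimand is a grid-weighted blend of per-day odds
  ratios; when the true odds ratio varies over time (as under exponential
  hazards) it is not the day-30 odds ratio — use the time-varying option
  for day-specific contrasts.
- Pointwise CPF bands at every distinct event time cost O(m²) in the
  number of distinct times; for very large cohorts compute intervals on a
  reduced grid or skip them (`ci_method=None`).
- Multiple imputation for missing covariates is out of scope; the package
  is complete-case by design and logs what it drops.
- No k-sample test, no cause-specific-hazard-scale tests, no left
  truncation, no parametric or spline incidence models.
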