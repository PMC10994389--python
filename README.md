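# cpfrisk

Competing-risks analysis of time to **live hospital discharge** after hip
fracture surgery, for epidemiologists and biostatisticians working with
registry-style admission records.

Discharge and in-hospital death compete: a patient who dies can never be
discharged, and large numbers of admissions are censored by transfer to
another unit or loss to follow-up, with follow-up administratively cut at
30 days after surgery. `cpfrisk` implements the full analysis chain for
comparing early mobilisation (first sitting/standing out of bed within 36
hours of surgery) with late mobilisation, overall and within strata defined
by a depression diagnosis:

1. **Aalen–Johansen cumulative incidence** for both causes,
   `CIF_k(t) = Σ_{t_i ≤ t} Ŝ(t_i−) d_ki / n_i`, with all-cause Kaplan–Meier
   survival `Ŝ`.
2. **Conditional probability function (CPF)** of live discharge,
   `CP(t) = CIF_discharge(t) / (1 − CIF_death(t))` — the probability of
   having been discharged by day *t* conditional on not having died in
   hospital — with pointwise delta-method confidence bands (cloglog scale,
   jackknife CIF covariances).
3. **Pepe–Mori two-sample test**: the integrated censoring-weighted
   difference `∫₀^τ w(t){CP_a(t) − CP_b(t)} dt`, inference by seeded label
   permutation (default) or a jackknife-variance normal approximation.
4. **Jackknife pseudo-observations** `PV_i(t) = n·ĈP(t) − (n−1)·ĈP^{(−i)}(t)`
   on the grid {3, 4, 6, 8, 12, 16, 20, 24, 30} days, modelled by a **GEE**
   with logit link, independence working correlation, and subject-clustered
   sandwich covariance — yielding early-vs-late odds ratios of the CPF,
   adjusted for the registry covariate set, with a
   depression-by-mobilisation Wald interaction test.
5. A **synthetic registry generator** with constant cause-specific hazards
   per (stratum, exposure) cell and closed-form ground truth
   (`CIF_k(t) = λ_k/λ (1 − e^{−λt})`), calibrated to the published registry
   margins, so every estimator is validated against known truth.

## Worked example

```python
import cpfrisk as ck

cfg = ck.nhfd_like_scenario(10_000, seed=4)      # registry-calibrated cells
cohort = ck.truncate_at_horizon(ck.simulate_cohort(cfg), 30)

curves = ck.cpf_by_group(cohort)                  # CPF per (stratum, exposure)
print(round(curves[("depression", "early")].cpf_at(30.0), 3),
      round(curves[("depression", "late")].cpf_at(30.0), 3))

tests = ck.run_stratified_tests(cohort, n_permutations=999, seed=17)
print(round(tests["no_depression"].p_value, 3))

report = ck.run_subgroup_and_interaction_analysis(cohort, adjustment="full")
print(report.per_stratum[["stratum", "model", "or", "ci_lower", "ci_upper"]]
      .round(3).to_string(index=False))
```

prints

```
0.751 0.664
0.001
       stratum      model    or  ci_lower  ci_upper
    depression unadjusted 1.641     1.187     2.268
    depression   adjusted 1.584     1.141     2.198
 no_depression unadjusted 1.810     1.632     2.006
 no_depression   adjusted 1.813     1.635     2.012
```

The day-30 conditional probability of discharge is higher for early
mobilisers in both strata; the shared-effect GEE puts the early-vs-late
odds ratio of the CPF near 1.6–1.8 with confidence intervals excluding 1,
and the interaction test (in `report.interaction`) finds no
depression-by-mobilisation effect modification — the configuration
simulates none.

The same pipeline is scriptable from the shell:

```bash
cpfrisk simulate --scenario nhfd --n-scale 10000 --seed 4 --out cohort.csv
cpfrisk cpf --in cohort.csv --out curves.csv --plot curves.png
cpfrisk test --in cohort.csv --perms 2000 --seed 17 --out tests.json
cpfrisk regress --in cohort.csv --adjust full --out ors.csv
```

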