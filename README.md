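# placenorm

Quantitative placental T2\* relaxometry and normative gestational modeling.

Placental T2\* measured by BOLD-sensitive multi-echo gradient-echo MRI is a
non-invasive marker of placental oxygenation: deoxyhemoglobin shortens T2\*,
so placentas with impaired maternal perfusion or raised oxygen extraction
show depressed T2\* well before clinical morbidity. `placenorm` implements
the full analysis chain for longitudinal placental T2\* studies:

1. **Relaxometry** — voxelwise nonlinear least-squares fits of
   mono-exponential decay, S(TE) = S₀·exp(−TE/T2\*), over a placental ROI;
   median aggregation with exclusion of fitted T2\* ≥ 250 ms
   (amniotic-fluid contamination); ROI volumetry with linear interpolation
   across motion-lost slices.
2. **Normative growth modeling** — candidate models of a biomarker y(t)
   versus gestational age t (constant, linear, quadratic, cubic, and the
   logistic sigmoid y(t) = p₁/(1 + e^{p₂(t−p₃)}) + p₄) fitted by nonlinear
   least squares and compared by BIC; delta-method 95% confidence and
   prediction bands; within-pregnancy rate-of-change pairs fitted with the
   analytic sigmoid derivative.
3. **Scoring** — per-scan z-scores
   z = (T2\* − μ̂_UN(GA)) / σ_pred(GA) against the uncomplicated-pregnancy
   (UN) reference curve, Gaussian percentiles 100·Φ(z), and the study
   statistics (two-sample KS, Cohen's d, chi-square proportion test with
   relative risk, 5%-wide percentile histograms).
4. **Discrimination** — ROC curves of T2\* percentile for adverse-outcome
   prediction (low percentile = positive call), AUC via the trapezoid rule
   (≡ Mann–Whitney concordance), Youden's J and the optimal cutoff C_opt,
   overall and per gestational window (10–20, 20–30, 30+ weeks).
5. **Synthetic data** — seeded generative twins of the reference study:
   longitudinal cohorts (316 subjects, outcome groups UN/PA/SA at
   62.6/22.2/15.2%, 1–3 scans per subject) and multi-echo phantoms with
   known ground-truth T2\* fields.

The package follows the statsmodels convention: a `GestationalModel` built
from data, whose `fit()` returns a `GestationalFit` carrying estimates,
covariance, BIC and band/score methods.

## Worked example

```python
import placenorm as pn

cohort = pn.simulate_cohort(pn.CohortConfig(seed=7))   # 801 scans, 316 subjects
un = cohort[cohort.group == "UN"]

best, fits = pn.select_model_bic(un.ga_weeks, un.t2star_ms, random_state=0)
print(best.summary())
print({f: round(r.bic, 1) for f, r in fits.items()})

scores = pn.score_cohort(cohort, best)                 # z + percentile per scan
for name, roc in pn.windowed_roc(scores).items():      # PA vs UN discrimination
    print(f"{name}: AUC={roc.auc:.2f} Jmax={roc.j_max:.2f} Copt={roc.c_opt:.1f}")
```

prints

```
Gestational sigmoid model fit
============================================
n obs                                    544
RMS residual                           9.764
BIC                                     2504
converged                               True
--------------------------------------------
param             estimate           std err
p1                -55.1939           2.96556
p2                -0.26612         0.0289114
p3                 28.7966          0.431039
p4                 83.8462            1.0949
============================================
{'constant': 3330.7, 'linear': 2605.1, 'quadratic': 2543.3, 'cubic': 2517.8, 'sigmoid': 2504.4}
overall: AUC=0.69 Jmax=0.34 Copt=14.6
10-20: AUC=0.71 Jmax=0.47 Copt=12.2
20-30: AUC=0.72 Jmax=0.39 Copt=40.5
30+: AUC=0.63 Jmax=0.30 Copt=14.3
```

The sigmoid wins model selection (lowest BIC); its parameters say placental
T2\* falls from an early plateau of ~84 ms through an inflection near 29
weeks toward a late plateau near 29 ms. Scans from primary-adverse (PA)
pregnancies sit low relative to the UN reference, giving an overall AUC of
about 0.7 for scan-level discrimination; a percentile at or below C_opt
flags a scan at the Youden-optimal operating point.

The same stages are scriptable from the shell:

```sh
placenorm simulate --n-subjects 316 --seed 7 --out cohort.csv
placenorm fit --cohort cohort.csv --group UN --out fit.json
placenorm score --cohort cohort.csv --reference fit.json --out scores.csv
placenorm roc --scores scores.csv --out roc.json
placenorm run --seed 7 --out rundir/        # full pipeline + report.json
```

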