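# combatcv

**ComBat harmonization inside leakage-safe cross-validation for
multi-scanner brain-morphometry classification.**

## The problem

Classifiers that separate Parkinson's disease (PD) patients from healthy
volunteers (HV) using structural-MRI morphometry need large cohorts, which
in practice means pooling data from many scanners. Every scanner imprints
its own additive shift and multiplicative scale on each feature (a *batch
effect* or *site effect*), and the clinical make-up of each site can differ
too, so scanner identity and diagnosis become confounded. The standard
remedy is ComBat harmonization — but inside a classification pipeline the
harmonizer is itself a fitted model, and *where* it is fit decides whether
the pipeline is honest:

* fit the harmonizer on the training fold only, without the diagnostic
  group as a covariate → leakage-safe;
* fit it with a group covariate → transforming a validation or test scan
  now **requires that scan's label**, which injects label information into
  the harmonized features and inflates apparent AUC, even when the features
  carry no disease signal at all.

`combatcv` implements the full pipeline — synthetic multi-scanner cohort
generation, a from-scratch ComBat harmonizer with explicit fit-split
strategies, train-fold-only class balancing (SMOTE / random undersampling /
left–right mirroring), stratified holdout + cross-validated random
hyperparameter search, and scanner-specific evaluation — so that this
leakage pathway can be demonstrated, measured, and avoided.

## The model

For feature $v$ of subject $j$ acquired on scanner $i$:

$$Y_{ijv} = \alpha_v + X_j \beta_v + \gamma_{iv} + \delta_{iv}\,\varepsilon_{ijv}$$

where $\alpha_v$ is the batch-size-weighted grand mean, $X$ holds the
covariates to preserve (age, sex, optionally group), and
$\gamma_{iv}, \delta_{iv}$ are the additive and multiplicative scanner
effects. Fitting standardizes the data to
$Z_{ijv} = (Y_{ijv} - \hat\alpha_v - X_j\hat\beta_v)/\hat\sigma_v$,
places empirical-Bayes priors across features —
$\gamma_{iv} \sim \mathcal N(\bar\gamma_i, \bar\tau_i^2)$,
$\delta_{iv}^2 \sim \text{InvGamma}(\bar\lambda_i, \bar\theta_i)$,
estimated by the method of moments — and iterates the conditional
posteriors to shrunken estimates $\gamma^*_{iv}, \delta^*_{iv}$. Harmonized
values are

$$Y^*_{ijv} = \frac{\hat\sigma_v}{\delta^*_{iv}}\left(Z_{ijv} - \gamma^*_{iv}\right) + \hat\alpha_v + X_j\hat\beta_v .$$

Numerical conventions follow the reference ComBat implementation
digit-for-digit (verified against Bioconductor `sva::ComBat` to below
1e-6 in the test suite).

## Worked example

```python
from combatcv import (default_cohort_config, generate_cohort, summarize_cohort,
                      fit_combat, apply_combat, CovariateDesign)

cohort = generate_cohort(default_cohort_config(seed=0))
print(summarize_cohort(cohort).loc[["scanner_01", "scanner_02", "TOTAL"],
                                   ["n_pd", "n_hv", "age_pd_mean", "age_hv_mean"]].round(1))

model = fit_combat(cohort, CovariateDesign(use_age=True, use_sex=True))
harmonized = apply_combat(model, cohort)
```

```
            n_pd  n_hv  age_pd_mean  age_hv_mean
scanner
scanner_01    24    12         60.9         58.0
scanner_02    17    19         64.1         63.4
TOTAL        216   155         62.9         62.6
```

The default cohort mirrors a pooled public + institutional PD study: 11
scanners, 216 PD / 155 HV, with realistic age/sex distributions and
scanner effects. Harmonization collapses the scanner signature — in this
run the cross-scanner standard deviation of per-scanner feature means drops
from 0.813 to 0.101.

The leakage demonstration runs from the command line:

```bash
$ combatcv leakage-demo --reps 5 --seed 1
leakage-safe   (fit train, no group): mean test AUC 0.425
label-dependent (fit train, group):   mean test AUC 0.671
inflation from leaked labels:         +0.246
```

Both pipelines saw cohorts with **no group effect whatsoever** — every
feature is pure scanner effect plus noise, with PD prevalence confounded
with scanner. The leakage-safe fit scores at chance; the pipeline whose
harmonizer used the group covariate appears to classify well above chance
purely because test labels entered the transform. Other subcommands:
`simulate`, `harmonize`, `run`, `report` (see `combatcv --help`).

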