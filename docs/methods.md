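# Methods

## The harmonization model

`combatcv.combat` implements the empirical-Bayes location–scale model for
multi-batch data. For feature `v`, subject `j`, scanner (batch) `i`:

    Y_ijv = alpha_v + X_j beta_v + gamma_iv + delta_iv * eps_ijv

Estimation follows the classical three steps: least-squares standardization
with per-batch intercepts, method-of-moments hyperpriors across features
(normal for the additive effects, inverse-gamma for the squared scale
effects), and a conditional-posterior fixed-point iteration to the shrunken
per-batch parameters.

Numerical conventions were chosen to match the reference ComBat
implementation exactly, because digit-level comparability is the only way
to make an oracle test meaningful:

* the pooled residual variance uses a `1/n` denominator; per-batch
  variances of the standardized data use `n-1`;
* cross-feature moments for the hyperpriors use sample (n−1) variances;
* `alpha_v` is the batch-size-weighted grand mean, equivalent to the
  constraint `sum_i (n_i/N) gamma_hat_iv = 0`;
* the EB iteration stops when the maximum relative parameter change drops
  below `tol = 1e-4` (`max_iter = 500`, non-convergence returns the last
  iterate with a warning), using the reference implementation's exact
  change measure.

A consequence worth documenting: with these conventions, single-batch
harmonization in `no_eb` mode is *not* an exact identity — centred values
contract by exactly `sqrt((n-1)/n)`. The test suite freezes this closed
form rather than an approximate identity.

Parametric empirical Bayes is the default (`eb_mode="parametric_eb"`),
matching the reference software's default; `no_eb` (no shrinkage,
`gamma* = gamma_hat`, `delta* = delta_hat`) exists for oracle testing and
for the two-batch mean/variance-alignment equivalence check. Non-parametric
EB, longitudinal variants and reference-batch variants are out of scope.
The minimum batch size defaults to 20 subjects (the ~20-scans-per-scanner
guidance for stable batch parameters) and is overridable; the pipeline
drivers use 5 because cross-validation training folds of realistic scanners
drop below 20.

### Fit-split strategies and the leakage pathway

`harmonize_splits` fits the model on a declared subset — the training fold
(`FIT_TRAIN_ONLY`), all non-test rows (`FIT_TRAIN_VALID`), everything
(`FIT_ALL`), or nothing (`NONE`) — and transforms all rows.
`FIT_TRAIN_ONLY_GROUP` additionally places the diagnostic group in the
covariate design. Algebraically, a transformed row then carries the term
`beta_group,v * (1 - 1/delta*_iv) * x_group`: the group coefficient
estimated on the training rows is deterministically re-injected into every
transformed row *scaled by how far the batch scale estimate sits from 1*.
Under a null group effect `beta_group` is pure estimation noise — but it is
the *same* noise vector for every transformed subject, added with the
subject's true label as the multiplier, which is exactly what a classifier
can exploit. At the final refit the "training" set is train+valid, so the
train-only strategies fit their harmonizer on all non-test rows there.

## The synthetic cohort generator

`combatcv.cohort` draws cohorts from

    y_ijv = baseline_v + group_j*effect_v + (age_j - 62)*a_v + male_j*s_v
            + gamma_iv + delta_iv*eps_ijv,     eps ~ N(0, noise_sd^2)

with per-feature scanner effects `gamma_iv ~ N(gamma_loc_i,
0.25*|gamma_loc_i| + 0.05)` and `delta_iv ~ LogNormal(log delta_scale_i,
0.1)` — batch effects must vary across features for the EB priors to have
anything to estimate. Exactly `round(group_effect_fraction * p)` features
carry a group effect of magnitude `group_effect_size * noise_sd` with
random sign. Age and sex coefficients are jittered 25% around their family
values; sex is encoded M→1/F→0 and group PD→1/HV→0 everywhere. eTIV is
drawn log-normally around 1.5e6 mm³, uncorrelated with group. Feature
values are in standardized morphometry units (not raw mm³); the eTIV
column is the exception. Generation is a pure function of the config seed,
and the returned table records the realized ground-truth effects for
recovery tests.

Scanner–group confounding is implemented through composition, not
features: when `confound_strength > 0`, per-scanner PD prevalence becomes
an increasing function of the scanner's additive effect rank,
`p_i = 0.5 + c*(r_i - 0.5)`, with per-scanner totals preserved. This
isolates "the site population differs" from "the scanner measures
differently" — the former is what makes a site effect masquerade as
biology.

What the generator does **not** emulate: correlated feature blocks
(anatomy makes real morphometry heavily correlated), non-Gaussian tails,
site-specific age ranges interacting with disease stage, longitudinal
structure, or missing data. Passing tests therefore show that the
*mechanisms* (batch-effect removal, leakage, balancing) behave as modelled,
not that real cohorts would yield these exact numbers.

### Packaged study conditions

* **Default cohort** (`default_cohort_config`): 11 scanners with PD/HV
  counts (216 PD / 155 HV, 371 subjects), age distributions and sex ratios
  typical of a pooled public + institutional PD cohort; additive shifts
  within ±1.3 residual SD, scale factors 0.7–1.6; 40 FS + 60 DOJ features,
  60% emitted as left/right pairs.
* **Leakage demo** (`leakage_demo_config`): 6 scanners × 30 subjects,
  250 features, *no* group effect, maximal prevalence confounding
  (`confound_strength = 1`), mild scale effects (0.85–1.2). Small
  per-scanner samples are deliberate: the re-injected group coefficient is
  scaled by `(1 - 1/delta*)`, and when true scanner-level scale differences
  are large that factor's sign is scanner-determined and the pooled AUC
  inflation partially cancels; with mild scanner scales and ~24 training
  scans per scanner, the estimation noise of `delta*` supplies
  feature-level heterogeneity and the inflation is expressed robustly.
  This is also precisely the regime practitioners operate in when they
  quote the ~20-scan minimum.
* **Benefit demo** (`benefit_demo_config`): the default cohort with doubled
  additive shifts and a real group effect of 0.5 SD on 30% of features, no
  confounding.

## Resampling

SMOTE (synthetic rows `x + u*(x_nn - x)`, `u ~ U(0,1)`, `k = 5` neighbors
by Euclidean distance on the prepared features, no rescaling — harmonized
output is already variance-aligned), random undersampling to the minimum
stratum, and left/right mirroring that swaps every `_L`/`_R` column pair.
Balancing operates by group or by group × scanner cell and is applied to
training rows only; the API shape enforces this (`balance_training_set` is
the only pipeline entry point and only ever receives the training fold).
Mirroring runs before balancing so mirrored rows take part in the neighbor
search and the stratum counts; the ordering is this package's choice and is
not claimed to be canonical.

## Evaluation protocol

20% stratified holdout (scanner × age-tertile × sex × group; age binned
into cohort-wide tertiles because continuous stratification needs a
discretization; strata under 2 subjects merge by dropping the age bin, then
sex). Test slots are allocated to strata by largest remainder so the total
equals `round(0.2 N)` while every stratum stays within one subject of the
target share. Group-stratified 5-fold CV on the remainder for multi-scanner
runs; LOOCV for single-scanner runs (strategy forced to NONE — one site has
no batch variable). Random hyperparameter search scores each sampled
configuration by mean validation AUC (harmonizer re-fit inside every fold);
ties break to the earliest trial; only the winner is refit on all non-test
rows and scored once on the held-out test set. The default search budget is
200 trials (configurable; the simulation studies use 2 — with a single
classifier family the search is cheap and the studies compare strategies,
not classifiers). Classifier hyperparameter ranges are repository defaults:
log-uniform regularization for logistic regression and SVM, 50–500 trees
and depth 2–8 for the ensemble models.

AUC is the Mann–Whitney probability with ties credited ½; balanced
accuracy is (sensitivity + specificity)/2; scanner-specific reports
aggregate per-scanner AUCs as mean ± sample SD (n−1), with single-class
scanners flagged and excluded.

## Simulation studies and problem sizes

`leakage_comparison` draws a fresh cohort per replicate and runs the full
multi-scanner pipeline once per harmonization strategy; every strategy arm
sees identical trial configurations and splits, so per-replicate
differences are paired. The packaged studies use 20 replicates, logistic
regression, 2 search trials, 5-fold CV:

* leakage study (null effect + confounding): leakage-safe test AUC ~0.50,
  label-dependent ~0.71–0.73;
* benefit study (real effect + strong shifts): harmonization gains
  ~0.01–0.02 validation AUC, positive in ~19/20 replicates (paired
  Wilcoxon p < 1e-4).

The eligibility filter in the leakage study keeps all scanners
(`min_hv = min_pd = 1`): extreme prevalence is the object of study there,
whereas the default thresholds (10/10) reflect ordinary practice.

## Known limitations

* Novel scanners cannot be transformed — per-batch parameters must have
  been estimated during the fit; this is inherent to the model.
* The generator's independence across features understates the
  effectiveness of multivariate classifiers on real data and overstates
  the sharpness of the EB priors.
* Balanced accuracy is computed from hard predictions and is reported only
  where a predict rule exists; model selection uses AUC throughout.
* The simulation studies' effect sizes are study conditions, not estimates
  of any real cohort's batch effects.
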