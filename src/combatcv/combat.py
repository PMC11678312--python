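"""Empirical-Bayes location-scale harmonization (ComBat) with explicit fit splits.

The model for feature ``v`` of subject ``j`` acquired on scanner (batch) ``i``::

    Y_ijv = alpha_v + X_j beta_v + gamma_iv + delta_iv eps_ijv

where ``alpha_v`` is the batch-size-weighted grand mean, ``X`` holds the
biological covariates to preserve (age, sex, optionally the diagnostic
group), and ``gamma_iv`` / ``delta_iv`` are the additive and multiplicative
batch effects.  Fitting proceeds in the classical three steps:

1. standardize: least squares with per-batch intercepts, pooled residual
   scale ``sigma_v`` (1/n denominator), standardized residuals ``Z``;
2. empirical-Bayes hyperpriors: per batch, a normal prior on ``gamma_iv``
   and an inverse-gamma prior on ``delta_iv^2``, both estimated across
   features by the method of moments;
3. conditional-posterior iteration to the shrunken ``gamma*_iv``,
   ``delta*_iv`` and reconstruction
   ``Y*_ijv = sigma_v / delta*_iv (Z_ijv - gamma*_iv) + alpha_v + X_j beta_v``.

Numerical conventions (pooled variance denominator, sample variances across
features, the relative-change stopping rule of the fixed-point iteration)
follow the reference ComBat implementation so that outputs are comparable
digit-for-digit.

The fit-split machinery at the bottom is the point of the package: the model
may be fit on the training fold only, on train+valid, or on everything, and
optionally with the group label as a covariate.  The latter requires labels
at transform time -- the leakage pathway this package exists to demonstrate.
Transforming a row whose label feeds the design matrix leaks that label into
every harmonized feature.
"""

from __future__ import annotations

import dataclasses
import logging
import warnings
from dataclasses import dataclass, field
from enum import Enum

import numpy as np
import pandas as pd

from .cohort import FeatureTable, AGE_REFERENCE

logger = logging.getLogger(__name__)

__all__ = [
    "CovariateDesign",
    "CombatModel",
    "HarmonizationStrategy",
    "fit_standardization",
    "estimate_eb_hyperpriors",
    "eb_adjustments",
    "fit_combat",
    "apply_combat",
    "harmonize_splits",
]


class HarmonizationStrategy(str, Enum):
    """Which rows the harmonization model is fit on (it transforms all rows)."""

    FIT_TRAIN_ONLY = "train_only"
    FIT_TRAIN_VALID = "train_valid"
    FIT_ALL = "all"
    NONE = "none"
    FIT_TRAIN_ONLY_GROUP = "train_only_group"


@dataclass(frozen=True)
class CovariateDesign:
    """Covariates preserved by harmonization; batch is always the scanner.

    ``use_group=True`` marks the design as label-dependent: the fitted model
    then needs group labels for every row it transforms, including test rows.
    """

    use_age: bool = True
    use_sex: bool = True
    use_group: bool = False
    batch_column: str = "scanner"

    def matrix(self, table: FeatureTable) -> np.ndarray:
        """Covariate columns (no intercept; batch indicators play that role)."""
        cols = []
        if self.use_age:
            cols.append(np.asarray(table.age, dtype=float) - AGE_REFERENCE)
        if self.use_sex:
            cols.append(np.asarray(table.sex_codes(), dtype=float))
        if self.use_group:
            g = table.group_codes()
            if g.isna().any():
                raise ValueError(
                    "design uses the group covariate but group labels are "
                    "missing for some rows; a label-dependent harmonization "
                    "model cannot transform unlabeled data")
            cols.append(np.asarray(g, dtype=float))
        if not cols:
            return np.empty((table.n_subjects, 0))
        return np.column_stack(cols)

    @property
    def covariate_names(self) -> list[str]:
        names = []
        if self.use_age:
            names.append("age")
        if self.use_sex:
            names.append("sex")
        if self.use_group:
            names.append("group")
        return names


@dataclass
class CombatModel:
    """Everything needed to harmonize new rows from known scanners."""

    feature_names: list[str]
    batch_ids: list[str]
    n_per_batch: np.ndarray          # (B,)
    alpha_hat: np.ndarray            # (p,)
    beta_hat: np.ndarray             # (k, p)
    sigma_hat: np.ndarray            # (p,) pooled residual SD
    gamma_hat: np.ndarray            # (B, p) raw batch locations (Z units)
    delta2_hat: np.ndarray           # (B, p) raw batch variances (Z units)
    gamma_star: np.ndarray           # (B, p) EB-adjusted locations
    delta2_star: np.ndarray          # (B, p) EB-adjusted variances
    hyperpriors: dict                # gamma_bar, tau2, lambda_bar, theta_bar (B,)
    design: CovariateDesign = field(default_factory=CovariateDesign)
    eb_mode: str = "parametric_eb"

    @property
    def delta_star(self) -> np.ndarray:
        """EB-adjusted multiplicative batch effects on the SD scale."""
        return np.sqrt(self.delta2_star)

    def to_dict(self) -> dict:
        return {
            "feature_names": self.feature_names,
            "batch_ids": self.batch_ids,
            "n_per_batch": self.n_per_batch.tolist(),
            "alpha_hat": self.alpha_hat.tolist(),
            "beta_hat": self.beta_hat.tolist(),
            "sigma_hat": self.sigma_hat.tolist(),
            "gamma_hat": self.gamma_hat.tolist(),
            "delta2_hat": self.delta2_hat.tolist(),
            "gamma_star": self.gamma_star.tolist(),
            "delta2_star": self.delta2_star.tolist(),
            "hyperpriors": {k: np.asarray(v).tolist()
                            for k, v in self.hyperpriors.items()},
            "design": dataclasses.asdict(self.design),
            "eb_mode": self.eb_mode,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CombatModel":
        return cls(
            feature_names=list(d["feature_names"]),
            batch_ids=list(d["batch_ids"]),
            n_per_batch=np.asarray(d["n_per_batch"]),
            alpha_hat=np.asarray(d["alpha_hat"]),
            beta_hat=np.asarray(d["beta_hat"]),
            sigma_hat=np.asarray(d["sigma_hat"]),
            gamma_hat=np.asarray(d["gamma_hat"]),
            delta2_hat=np.asarray(d["delta2_hat"]),
            gamma_star=np.asarray(d["gamma_star"]),
            delta2_star=np.asarray(d["delta2_star"]),
            hyperpriors={k: np.asarray(v) for k, v in d["hyperpriors"].items()},
            design=CovariateDesign(**d["design"]),
            eb_mode=d["eb_mode"],
        )


# ---------------------------------------------------------------------------
# step 1: standardization
# ---------------------------------------------------------------------------

def fit_standardization(Y: np.ndarray, X: np.ndarray, batch,
                        feature_names=None):
    """Least-squares location-scale standardization.

    Fits per-batch intercepts plus covariate effects, forms the
    batch-size-weighted grand mean ``alpha_v`` (so that
    ``sum_i n_i/N gamma_hat_iv = 0``), the pooled residual SD ``sigma_v``
    (1/n denominator) and the standardized residuals
    ``Z = (Y - alpha - X beta) / sigma``.

    Returns ``(alpha_hat, beta_hat, sigma_hat, Z)`` with ``beta_hat`` of
    shape (k, p).
    """
    Y = np.asarray(Y, dtype=float)
    X = np.empty((len(Y), 0)) if X is None else np.asarray(X, dtype=float)
    batch = np.asarray(batch)
    n, p = Y.shape
    if feature_names is None:
        feature_names = [f"f{v}" for v in range(p)]
    levels, inv = np.unique(batch, return_inverse=True)
    counts = np.bincount(inv)
    if (counts < 2).any():
        small = [str(levels[i]) for i in np.where(counts < 2)[0]]
        raise ValueError(f"each batch needs >= 2 subjects; too small: {small}")
    onehot = np.zeros((n, len(levels)))
    onehot[np.arange(n), inv] = 1.0
    design = np.hstack([onehot, X])
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise ValueError("design matrix is rank deficient "
                         "(a covariate is confounded with batch?)")
    B = np.linalg.solve(design.T @ design, design.T @ Y)   # (B+k, p)
    batch_coef, beta = B[:len(levels)], B[len(levels):]
    w = counts / n
    alpha = w @ batch_coef
    resid = Y - design @ B
    var_pooled = np.einsum("ij,ij->j", resid, resid) / n
    if (var_pooled <= 1e-12).any():
        bad = [feature_names[v] for v in np.where(var_pooled <= 1e-12)[0]]
        raise ValueError(f"zero residual variance for feature(s) {bad[:5]}; "
                         "constant features cannot be standardized")
    sigma = np.sqrt(var_pooled)
    Z = (Y - alpha - X @ beta) / sigma
    return alpha, beta, sigma, Z


# ---------------------------------------------------------------------------
# step 2: hyperpriors
# ---------------------------------------------------------------------------

def estimate_eb_hyperpriors(gamma_hat: np.ndarray, delta2_hat: np.ndarray) -> dict:
    """Method-of-moments hyperpriors from the cross-feature spread of estimates.

    Per batch ``i``: ``gamma_iv ~ Normal(gamma_bar_i, tau2_i)`` with
    ``gamma_bar``/``tau2`` the cross-feature mean and (sample) variance of
    ``gamma_hat_iv``; ``delta2_iv ~ InvGamma(lambda_bar_i, theta_bar_i)``
    with, for ``m``/``s2`` the cross-feature mean and variance of
    ``delta2_hat_iv``::

        lambda_bar = (m^2 + 2 s2) / s2        theta_bar = (m^3 + m s2) / s2

    A batch whose ``delta2_hat`` has zero cross-feature variance gets
    ``no_eb=True`` in the returned mask (its moments are degenerate) and
    NaN hyperpriors.
    """
    gamma_hat = np.atleast_2d(np.asarray(gamma_hat, dtype=float))
    delta2_hat = np.atleast_2d(np.asarray(delta2_hat, dtype=float))
    if gamma_hat.shape[1] < 2:
        raise ValueError("need >= 2 features to estimate cross-feature moments")
    gamma_bar = gamma_hat.mean(axis=1)
    tau2 = gamma_hat.var(axis=1, ddof=1)
    m = delta2_hat.mean(axis=1)
    s2 = delta2_hat.var(axis=1, ddof=1)
    no_eb = s2 <= 0
    if no_eb.any():
        warnings.warn("cross-feature variance of delta^2 is zero for "
                      f"{int(no_eb.sum())} batch(es); falling back to no_eb "
                      "for those batches")
    with np.errstate(divide="ignore", invalid="ignore"):
        lambda_bar = np.where(no_eb, np.nan, (m ** 2 + 2 * s2) / s2)
        theta_bar = np.where(no_eb, np.nan, (m ** 3 + m * s2) / s2)
    return {"gamma_bar": gamma_bar, "tau2": tau2,
            "lambda_bar": lambda_bar, "theta_bar": theta_bar, "no_eb": no_eb}


# ---------------------------------------------------------------------------
# step 3: conditional-posterior iteration
# ---------------------------------------------------------------------------

def _fixed_point(Zi, g_hat, d2_hat, g_bar, tau2, a, b, tol, max_iter):
    """One batch's shrinkage iteration (reference stopping rule).

    Alternates the conditional posterior means::

        gamma* = (n tau2 g_hat + delta2* gamma_bar) / (n tau2 + delta2*)
        delta2* = (theta_bar + 1/2 sum_j (Z_ij - gamma*)^2) / (n/2 + lambda_bar - 1)

    stopping when the maximum relative parameter change drops below ``tol``.
    """
    n = Zi.shape[0]
    g_old, d_old = g_hat.copy(), d2_hat.copy()
    for it in range(max_iter):
        g_new = (tau2 * n * g_hat + d_old * g_bar) / (tau2 * n + d_old)
        sum2 = ((Zi - g_new) ** 2).sum(axis=0)
        d_new = (0.5 * sum2 + b) / (n / 2.0 + a - 1.0)
        # reference stopping rule: absolute change over the *signed* previous
        # value; negative ratios simply never win the max
        with np.errstate(divide="ignore", invalid="ignore"):
            change = max((np.abs(g_new - g_old) / g_old).max(),
                         (np.abs(d_new - d_old) / d_old).max())
        g_old, d_old = g_new, d_new
        if change < tol:
            return g_new, d_new, it + 1
    warnings.warn(f"EB adjustment did not converge in {max_iter} iterations "
                  f"(last relative change {change:.3g}); returning last iterate")
    return g_old, d_old, max_iter


def eb_adjustments(Z: np.ndarray, batch, hyperpriors: dict,
                   tol: float = 1e-4, max_iter: int = 500):
    """Shrink per-batch location/scale estimates toward their EB priors.

    Returns ``(gamma_star, delta2_star)`` of shape (B, p), batches ordered by
    sorted batch label.  Batches flagged ``no_eb`` keep their raw estimates.
    """
    if tol <= 0:
        raise ValueError("tol must be > 0")
    Z = np.asarray(Z, dtype=float)
    batch = np.asarray(batch)
    levels = np.unique(batch)
    B, p = len(levels), Z.shape[1]
    gamma_star = np.empty((B, p))
    delta2_star = np.empty((B, p))
    for i, lev in enumerate(levels):
        Zi = Z[batch == lev]
        g_hat = Zi.mean(axis=0)
        d2_hat = Zi.var(axis=0, ddof=1)
        if hyperpriors.get("no_eb", np.zeros(B, bool))[i]:
            gamma_star[i], delta2_star[i] = g_hat, d2_hat
            continue
        g, d2, n_it = _fixed_point(
            Zi, g_hat, d2_hat,
            hyperpriors["gamma_bar"][i], hyperpriors["tau2"][i],
            hyperpriors["lambda_bar"][i], hyperpriors["theta_bar"][i],
            tol, max_iter)
        logger.debug("batch %s: EB fixed point in %d iterations", lev, n_it)
        gamma_star[i], delta2_star[i] = g, d2
    return gamma_star, delta2_star


# ---------------------------------------------------------------------------
# full fit / apply
# ---------------------------------------------------------------------------

def fit_combat(table: FeatureTable, design: CovariateDesign | None = None,
               eb_mode: str = "parametric_eb", min_batch_size: int = 20,
               tol: float = 1e-4, max_iter: int = 500) -> CombatModel:
    """Fit the full harmonization model on a feature table.

    ``min_batch_size`` guards parameter stability: location/scale estimates
    from very small scanners fluctuate wildly, and roughly 20 scans per
    scanner are needed for reliable ComBat fits.  Lower it explicitly (e.g.
    to 4) for toy problems.
    """
    if design is None:
        design = CovariateDesign()
    if eb_mode not in ("parametric_eb", "no_eb"):
        raise ValueError(f"unknown eb_mode {eb_mode!r}")
    counts = table.scanner.value_counts()
    small = counts[counts < min_batch_size]
    if len(small):
        raise ValueError(
            f"scanner(s) {sorted(small.index.tolist())} have fewer than "
            f"{min_batch_size} subjects; ComBat needs ~20 scans per scanner "
            "for stable batch parameters (pass min_batch_size to override)")
    Y = table.features.to_numpy(dtype=float)
    X = design.matrix(table)
    batch = np.asarray(table.scanner)
    alpha, beta, sigma, Z = fit_standardization(Y, X, batch,
                                                feature_names=table.feature_names)
    levels = np.unique(batch)
    g_hat = np.vstack([Z[batch == lev].mean(axis=0) for lev in levels])
    d2_hat = np.vstack([Z[batch == lev].var(axis=0, ddof=1) for lev in levels])
    hp = estimate_eb_hyperpriors(g_hat, d2_hat)
    if eb_mode == "parametric_eb":
        g_star, d2_star = eb_adjustments(Z, batch, hp, tol=tol, max_iter=max_iter)
    else:
        g_star, d2_star = g_hat.copy(), d2_hat.copy()
    return CombatModel(
        feature_names=table.feature_names,
        batch_ids=[str(l) for l in levels],
        n_per_batch=np.array([(batch == lev).sum() for lev in levels]),
        alpha_hat=alpha, beta_hat=beta, sigma_hat=sigma,
        gamma_hat=g_hat, delta2_hat=d2_hat,
        gamma_star=g_star, delta2_star=d2_star,
        hyperpriors=hp, design=design, eb_mode=eb_mode)


def apply_combat(model: CombatModel, table: FeatureTable) -> FeatureTable:
    """Harmonize rows from scanners the model was fit on.

    ``Y* = sigma/delta* (Z - gamma*) + alpha + X beta`` with ``Z`` rebuilt
    from the stored standardization.  Scanners absent from the fit cannot be
    transformed (their batch parameters were never estimated).  If the model
    was fit with the group covariate, group labels are required here too --
    this is the leakage pathway, and it is logged whenever it is exercised.
    """
    unseen = set(table.scanner.unique()) - set(model.batch_ids)
    if unseen:
        raise ValueError(
            f"scanner(s) {sorted(unseen)} were not in the harmonization fit; "
            "novel scanners outside the fitted batches cannot be harmonized")
    if model.design.use_group:
        logger.info("label-dependent harmonization: transforming %d rows "
                    "USING their group labels (leakage pathway)",
                    table.n_subjects)
    if list(table.feature_names) != list(model.feature_names):
        if set(table.feature_names) != set(model.feature_names):
            raise ValueError("feature names do not match the fitted model")
        table = table.with_features(table.features[model.feature_names])
    Y = table.features.to_numpy(dtype=float)
    X = model.design.matrix(table)           # raises if group needed but absent
    idx = np.array([model.batch_ids.index(s) for s in table.scanner])
    Z = (Y - model.alpha_hat - X @ model.beta_hat) / model.sigma_hat
    Zadj = (Z - model.gamma_star[idx]) / np.sqrt(model.delta2_star[idx])
    Ystar = Zadj * model.sigma_hat + model.alpha_hat + X @ model.beta_hat
    out = pd.DataFrame(Ystar, index=table.data.index, columns=model.feature_names)
    return table.with_features(out)


def harmonize_splits(strategy: HarmonizationStrategy, table: FeatureTable,
                     plan, design: CovariateDesign | None = None,
                     fold_index: int = 0, eb_mode: str = "parametric_eb",
                     min_batch_size: int = 20, **fit_kwargs) -> FeatureTable:
    """Fit on the strategy's subset of a split plan; transform every row.

    * ``FIT_TRAIN_ONLY`` / ``FIT_TRAIN_ONLY_GROUP`` -- fit on the training
      rows of fold ``fold_index`` (the latter forces the group covariate);
    * ``FIT_TRAIN_VALID`` -- fit on all non-test rows;
    * ``FIT_ALL`` -- fit on everything, including the test rows;
    * ``NONE`` -- no model, rows pass through unchanged.
    """
    strategy = HarmonizationStrategy(strategy)
    if design is None:
        design = CovariateDesign()
    if strategy is HarmonizationStrategy.NONE:
        return table.copy()
    if strategy is HarmonizationStrategy.FIT_TRAIN_ONLY_GROUP:
        design = dataclasses.replace(design, use_group=True)
    if strategy in (HarmonizationStrategy.FIT_TRAIN_ONLY,
                    HarmonizationStrategy.FIT_TRAIN_ONLY_GROUP):
        fit_ids = list(plan.folds[fold_index][0])
    elif strategy is HarmonizationStrategy.FIT_TRAIN_VALID:
        fit_ids = [s for s in table.subject_ids if s not in set(plan.test_ids)]
    else:  # FIT_ALL
        fit_ids = table.subject_ids
    model = fit_combat(table.select_subjects(fit_ids), design=design,
                       eb_mode=eb_mode, min_batch_size=min_batch_size,
                       **fit_kwargs)
    return apply_combat(model, table)
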