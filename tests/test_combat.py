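"""Harmonizer: standardization, EB machinery, fit/apply, split strategies."""

import dataclasses

import numpy as np
import pandas as pd
import pytest

from combatcv.cohort import CohortConfig, ScannerSpec, generate_cohort
from combatcv.combat import (CovariateDesign, HarmonizationStrategy,
                             apply_combat, eb_adjustments,
                             estimate_eb_hyperpriors, fit_combat,
                             fit_standardization, harmonize_splits)
from combatcv.pipeline import SplitPlan

from conftest import make_table


class TestFitStandardization:
    def test_two_batch_weighted_mean_closed_form(self):
        rng = np.random.default_rng(0)
        Y = np.concatenate([rng.normal(10, 1, (50, 3)),
                            rng.normal(20, 1, (50, 3))])
        batch = ["a"] * 50 + ["b"] * 50
        alpha, beta, sigma, Z = fit_standardization(Y, None, batch)
        # equal n: alpha is the midpoint of the two batch means
        means = (Y[:50].mean(axis=0) + Y[50:].mean(axis=0)) / 2
        assert np.allclose(alpha, means)
        za, zb = Z[:50].mean(axis=0), Z[50:].mean(axis=0)
        assert np.allclose(za, -zb)

    def test_constant_feature_rejected_by_name(self):
        Y = np.column_stack([np.random.default_rng(1).normal(size=20),
                             np.full(20, 7.0)])
        with pytest.raises(ValueError, match="f1"):
            fit_standardization(Y, None, ["a"] * 10 + ["b"] * 10)

    def test_standard_normal_input_recovered(self):
        rng = np.random.default_rng(2)
        n = 10_000
        Y = rng.standard_normal((n, 5))
        alpha, beta, sigma, Z = fit_standardization(Y, None, ["a"] * n)
        assert (np.abs(alpha) < 3 / np.sqrt(n)).all()
        assert (np.abs(sigma - 1) < 3 / np.sqrt(2 * n)).all()
        assert np.allclose(Z.mean(axis=0), 0, atol=1e-12)
        assert np.allclose(Z.var(axis=0), 1, atol=1e-2)

    def test_batch_of_one_rejected(self):
        Y = np.random.default_rng(3).normal(size=(5, 2))
        with pytest.raises(ValueError, match="2 subjects"):
            fit_standardization(Y, None, ["a", "a", "a", "a", "b"])

    def test_confounded_covariate_rejected(self):
        Y = np.random.default_rng(4).normal(size=(20, 2))
        batch = np.array(["a"] * 10 + ["b"] * 10)
        X = (batch == "a").astype(float)[:, None]     # identical to a batch dummy
        with pytest.raises(ValueError, match="rank"):
            fit_standardization(Y, X, batch)


class TestHyperpriors:
    def test_inverse_gamma_moment_closed_form(self):
        # cross-feature mean 2 and variance 1 of delta^2  ->  IG(6, 10),
        # whose mean 10/(6-1)=2 and variance 100/(25*4)=1 round-trip
        d2 = np.array([[2.0 - 1.0, 2.0, 2.0 + 1.0]])
        d2 = d2 - d2.mean() + 2.0
        assert np.isclose(d2.mean(), 2.0) and np.isclose(d2.var(ddof=1), 1.0)
        hp = estimate_eb_hyperpriors(np.zeros((1, 3)), d2)
        lam, theta = hp["lambda_bar"][0], hp["theta_bar"][0]
        assert np.isclose(lam, 6.0) and np.isclose(theta, 10.0)
        assert np.isclose(theta / (lam - 1), 2.0)                      # IG mean
        assert np.isclose(theta ** 2 / ((lam - 1) ** 2 * (lam - 2)), 1.0)  # IG var

    def test_gamma_bar_monte_carlo(self):
        rng = np.random.default_rng(5)
        g = rng.normal(0.5, 0.2, (1, 5000))
        hp = estimate_eb_hyperpriors(g, np.abs(rng.normal(1, 0.1, (1, 5000))))
        assert abs(hp["gamma_bar"][0] - 0.5) < 3 * 0.2 / np.sqrt(5000)

    def test_degenerate_delta_triggers_no_eb(self):
        with pytest.warns(UserWarning, match="no_eb"):
            hp = estimate_eb_hyperpriors(np.array([[0.1, 0.2, 0.3]]),
                                         np.ones((1, 3)))
        assert hp["no_eb"][0]


def _oracle_fixed_point(Zi, g_bar, tau2, a, b, n_steps=20_000):
    """Independent shrinkage iteration: plain loop, fixed step count."""
    n = Zi.shape[0]
    g_hat = Zi.mean(axis=0)
    d = Zi.var(axis=0, ddof=1)
    g = g_hat.copy()
    for _ in range(n_steps):
        g = (tau2 * n * g_hat + d * g_bar) / (tau2 * n + d)
        d = (0.5 * ((Zi - g) ** 2).sum(axis=0) + b) / (n / 2 + a - 1)
    return g, d


class TestEBAdjustments:
    def _instance(self, seed=6, n=60, p=20, n_batches=3):
        rng = np.random.default_rng(seed)
        Z = rng.standard_normal((n * n_batches, p))
        Z += np.repeat(rng.normal(0, 0.5, (n_batches, p)), n, axis=0)
        batch = np.repeat([f"b{i}" for i in range(n_batches)], n)
        g_hat = np.vstack([Z[batch == l].mean(axis=0) for l in np.unique(batch)])
        d2 = np.vstack([Z[batch == l].var(axis=0, ddof=1) for l in np.unique(batch)])
        return Z, batch, estimate_eb_hyperpriors(g_hat, d2)

    def test_matches_independent_fixed_point_iteration(self):
        Z, batch, hp = self._instance()
        g_star, d2_star = eb_adjustments(Z, batch, hp, tol=1e-12, max_iter=50_000)
        for i, lev in enumerate(np.unique(batch)):
            g_o, d_o = _oracle_fixed_point(Z[batch == lev], hp["gamma_bar"][i],
                                           hp["tau2"][i], hp["lambda_bar"][i],
                                           hp["theta_bar"][i])
            assert np.abs(g_star[i] - g_o).max() < 1e-8
            assert np.abs(d2_star[i] - d_o).max() < 1e-8

    def test_shrinkage_vanishes_for_huge_batches(self):
        rng = np.random.default_rng(7)
        n = 100_000
        Z = rng.standard_normal((n, 10)) + rng.normal(0, 0.5, 10)
        batch = np.array(["a"] * n)
        g_hat = Z.mean(axis=0, keepdims=True)
        hp = estimate_eb_hyperpriors(g_hat, Z.var(axis=0, ddof=1, keepdims=True))
        g_star, _ = eb_adjustments(Z, batch, hp)
        assert np.abs(g_star[0] - g_hat[0]).max() < 1e-3

    def test_zero_prior_variance_gives_full_shrinkage(self):
        Z, batch, hp = self._instance(seed=8)
        hp = dict(hp)
        hp["tau2"] = np.zeros_like(hp["tau2"])
        g_star, _ = eb_adjustments(Z, batch, hp)
        for i in range(len(g_star)):
            assert np.allclose(g_star[i], hp["gamma_bar"][i])

    def test_gamma_star_lies_between_estimate_and_prior_mean(self):
        Z, batch, hp = self._instance(seed=9)
        g_star, _ = eb_adjustments(Z, batch, hp)
        for i, lev in enumerate(np.unique(batch)):
            g_hat = Z[batch == lev].mean(axis=0)
            side = (g_star[i] - g_hat) * (g_star[i] - hp["gamma_bar"][i])
            assert (side <= 1e-12).all()


class TestFitApply:
    def test_single_batch_no_eb_roundtrip_closed_form(self):
        """One batch, no covariates: harmonization reduces to the exact
        standardize/destandardize round-trip, which contracts centred values
        by sqrt((n-1)/n) (pooled variance uses 1/n, batch variance n-1)."""
        rng = np.random.default_rng(10)
        n = 30
        Y = rng.normal(5, 2, (n, 4))
        t = make_table(Y, ["A"] * n, ["PD"] * 15 + ["HV"] * 15)
        design = CovariateDesign(use_age=False, use_sex=False)
        model = fit_combat(t, design, eb_mode="no_eb", min_batch_size=4)
        out = apply_combat(model, t).features.to_numpy()
        expected = Y.mean(axis=0) + (Y - Y.mean(axis=0)) * np.sqrt((n - 1) / n)
        assert np.abs(out - expected).max() < 1e-10

    def test_small_batch_rejected_with_guidance(self, small_cohort):
        with pytest.raises(ValueError, match="20 scans per scanner"):
            fit_combat(small_cohort, CovariateDesign(), min_batch_size=30)

    def test_injected_shift_and_scale_recovered(self):
        rng = np.random.default_rng(11)
        n, p = 500, 40
        Y = np.concatenate([rng.normal(0, 1, (n, p)),
                            rng.normal(2, 2, (n, p))])
        t = make_table(Y, ["A"] * n + ["B"] * n, (["PD", "HV"] * n)[:2 * n])
        design = CovariateDesign(use_age=False, use_sex=False)
        model = fit_combat(t, design, eb_mode="no_eb", min_batch_size=4)
        shift = (model.gamma_hat[1] - model.gamma_hat[0]) * model.sigma_hat
        scale = np.sqrt(model.delta2_hat[1] / model.delta2_hat[0])
        assert abs(shift.mean() - 2.0) < 0.1
        assert 0.9 * 2.0 < scale.mean() < 1.1 * 2.0

    def test_unseen_scanner_rejected(self, small_cohort):
        model = fit_combat(small_cohort, CovariateDesign(), min_batch_size=4)
        novel = small_cohort.copy()
        novel.data.loc[novel.data.index[:3], "scanner"] = "mystery"
        with pytest.raises(ValueError, match="mystery"):
            apply_combat(model, novel)

    def test_apply_is_deterministic_and_consistent(self, small_cohort):
        model = fit_combat(small_cohort, CovariateDesign(), min_batch_size=4)
        a = apply_combat(model, small_cohort)
        b = apply_combat(model, small_cohort)
        assert a.data.equals(b.data)

    def test_label_free_design_ignores_group_labels(self, small_cohort):
        model = fit_combat(small_cohort, CovariateDesign(use_group=False),
                           min_batch_size=4)
        shuffled = small_cohort.copy()
        rng = np.random.default_rng(12)
        shuffled.data["group"] = rng.permutation(shuffled.data["group"].to_numpy())
        a = apply_combat(model, small_cohort)
        b = apply_combat(model, shuffled)
        assert np.array_equal(a.features.to_numpy(), b.features.to_numpy())

    def test_group_design_requires_labels(self, small_cohort):
        model = fit_combat(small_cohort, CovariateDesign(use_group=True),
                           min_batch_size=4)
        stripped = small_cohort.copy()
        stripped.data.loc[stripped.data.index[:5], "group"] = np.nan
        with pytest.raises(ValueError, match="group"):
            apply_combat(model, stripped)

    def test_no_eb_equals_independent_mean_variance_alignment(self):
        """Two-batch no-EB harmonization == align each batch to the pooled
        location/scale, computed from scratch here."""
        rng = np.random.default_rng(13)
        Y = np.concatenate([rng.normal(3, 1.5, (40, 6)),
                            rng.normal(-1, 0.6, (60, 6))])
        t = make_table(Y, ["A"] * 40 + ["B"] * 60,
                       (["PD"] * 20 + ["HV"] * 20) + (["PD"] * 30 + ["HV"] * 30))
        design = CovariateDesign(use_age=False, use_sex=False)
        out = apply_combat(fit_combat(t, design, eb_mode="no_eb",
                                      min_batch_size=4), t).features.to_numpy()
        # oracle: batch z-score (n-1 sd), rescale to pooled sd (1/n), recentre
        mA, mB = Y[:40].mean(axis=0), Y[40:].mean(axis=0)
        alpha = 0.4 * mA + 0.6 * mB
        resid = np.concatenate([Y[:40] - mA, Y[40:] - mB])
        pooled_sd = np.sqrt((resid ** 2).mean(axis=0))
        oracle = np.concatenate([
            (Y[:40] - mA) / Y[:40].std(axis=0, ddof=1) * pooled_sd + alpha,
            (Y[40:] - mB) / Y[40:].std(axis=0, ddof=1) * pooled_sd + alpha])
        assert np.abs(out - oracle).max() < 1e-10


class TestHarmonizationInvariants:
    def _null_batch_cohort(self, seed=14, n=100):
        return generate_cohort(CohortConfig(
            scanners=(ScannerSpec("A", n // 2, n // 2, gamma_loc=1.0,
                                  delta_scale=0.5),
                      ScannerSpec("B", n // 2, n // 2, gamma_loc=-0.8,
                                  delta_scale=2.0),
                      ScannerSpec("C", n // 2, n // 2, gamma_loc=0.3,
                                  delta_scale=1.2)),
            n_features_fs=8, n_features_doj=8, group_effect_size=0.0,
            seed=seed))

    def test_batch_means_removed(self):
        t = self._null_batch_cohort()
        model = fit_combat(t, CovariateDesign(), min_batch_size=4)
        out = apply_combat(model, t)
        X = out.features.to_numpy()
        design = CovariateDesign().matrix(out)
        # covariate-adjusted residuals per scanner should share one mean
        beta = np.linalg.lstsq(design, X, rcond=None)[0]
        resid = X - design @ beta
        batch = np.asarray(out.scanner)
        grand = resid.mean(axis=0)
        for lev in np.unique(batch)[:2]:
            sub = resid[batch == lev]
            se = sub.std(axis=0, ddof=1) / np.sqrt(len(sub))
            assert (np.abs(sub.mean(axis=0) - grand) < 4 * se).all()

    def test_batch_scales_equalized(self):
        t = self._null_batch_cohort(seed=15)
        model = fit_combat(t, CovariateDesign(), min_batch_size=4)
        out = apply_combat(model, t)
        X = out.features.to_numpy()
        batch = np.asarray(out.scanner)
        variances = np.vstack([X[batch == lev].var(axis=0, ddof=1)
                               for lev in np.unique(batch)])
        ratios = variances.max(axis=0) / variances.min(axis=0)
        assert (ratios < 1.25 / 0.8).all()


class TestHarmonizeSplits:
    def _plan(self, table):
        # stride-based assignment so every scanner appears in every part
        ids = table.subject_ids
        test = ids[::8]
        valid = ids[1::8] + ids[2::8]
        train = [s for s in ids if s not in set(test) | set(valid)]
        return SplitPlan(test_ids=test, folds=[(train, valid)])

    def test_none_strategy_is_identity(self, small_cohort):
        plan = self._plan(small_cohort)
        out = harmonize_splits(HarmonizationStrategy.NONE, small_cohort, plan)
        assert out.data.equals(small_cohort.data)

    def test_train_only_fit_is_independent_of_test_rows(self, small_cohort):
        plan = self._plan(small_cohort)
        train_ids = plan.folds[0][0]
        model_a = fit_combat(small_cohort.select_subjects(train_ids),
                             CovariateDesign(), min_batch_size=4)
        mutated = small_cohort.copy()
        cols = mutated.feature_names
        mutated.data.loc[plan.test_ids, cols] = 999.0
        model_b = fit_combat(mutated.select_subjects(train_ids),
                             CovariateDesign(), min_batch_size=4)
        assert np.array_equal(model_a.gamma_star, model_b.gamma_star)
        assert np.array_equal(model_a.alpha_hat, model_b.alpha_hat)

    def test_group_strategy_fails_without_test_labels(self, small_cohort):
        plan = self._plan(small_cohort)
        stripped = small_cohort.copy()
        stripped.data.loc[plan.test_ids, "group"] = np.nan
        with pytest.raises(ValueError, match="group"):
            harmonize_splits(HarmonizationStrategy.FIT_TRAIN_ONLY_GROUP,
                             stripped, plan, min_batch_size=4)

    def test_fit_all_uses_every_row(self, small_cohort):
        plan = self._plan(small_cohort)
        out_all = harmonize_splits(HarmonizationStrategy.FIT_ALL, small_cohort,
                                   plan, min_batch_size=4)
        full_model = fit_combat(small_cohort, CovariateDesign(), min_batch_size=4)
        expected = apply_combat(full_model, small_cohort)
        assert np.array_equal(out_all.features.to_numpy(),
                              expected.features.to_numpy())
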