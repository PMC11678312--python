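"""Splits, hyperparameter search, and the experiment drivers.

The evaluation protocol: a stratified 20% test holdout is frozen first;
the remaining subjects are split into group-stratified cross-validation
folds; each sampled configuration (classifier kind + hyperparameters +
balancing recipe + feature set + harmonization strategy) is scored by its
mean validation AUC across folds; only the single best configuration is
refit on all non-test rows and scored once on the held-out test set.

Harmonization is re-fit *inside* every fold on that fold's training rows
(for the train-only strategies), so no validation or test measurement ever
influences the harmonization parameters of a leakage-safe run.
"""

from __future__ import annotations

import dataclasses
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import GradientBoostingClassifier, RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import LeaveOneOut, StratifiedKFold
from sklearn.svm import SVC

from .cohort import FeatureTable, filter_eligible_scanners, prepare_features
from .combat import CovariateDesign, HarmonizationStrategy, harmonize_splits
from .metrics import roc_auc, scanner_specific_report
from .resampling import BalanceConfig, balance_training_set

logger = logging.getLogger(__name__)

__all__ = ["SplitPlan", "SearchSpace", "TrialResult", "stratified_holdout",
           "make_cv_folds", "train_classifier", "random_search",
           "run_single_scanner", "run_multi_scanner"]


# ---------------------------------------------------------------------------
# splits
# ---------------------------------------------------------------------------

@dataclass
class SplitPlan:
    """Disjoint assignment of subjects to a test holdout and CV folds."""

    test_ids: list
    folds: list                       # list of (train_ids, valid_ids)
    strata_spec: str = ""
    seed: int = 0
    stratum_of: dict = field(default_factory=dict)   # subject -> realized stratum

    def validate(self, all_ids) -> None:
        all_ids = set(all_ids)
        test = set(self.test_ids)
        rest = all_ids - test
        seen_valid = set()
        for train, valid in self.folds:
            train, valid = set(train), set(valid)
            if train & valid:
                raise ValueError("train/valid overlap within a fold")
            if (train | valid) != rest:
                raise ValueError("fold does not cover the non-test subjects")
            if valid & seen_valid:
                raise ValueError("validation folds overlap")
            seen_valid |= valid
        if self.folds and seen_valid != rest:
            raise ValueError("validation folds do not partition the non-test set")


def stratified_holdout(table: FeatureTable, test_fraction: float = 0.2,
                       seed: int = 0) -> SplitPlan:
    """Reserve a test set stratified by scanner x age-tertile x sex x group.

    Age is binned into cohort-wide tertiles.  Strata with fewer than 2
    subjects are merged up the hierarchy: the age bin is dropped first, then
    sex, leaving scanner x group.  Test slots are allocated to strata by
    largest remainder so that the total equals ``round(test_fraction * N)``
    while every stratum's share stays within one subject of the target
    fraction; subjects are then drawn without replacement per stratum.
    """
    if not 0.0 <= test_fraction < 1.0:
        raise ValueError("test_fraction must be in [0, 1)")
    df = table.data
    if test_fraction == 0.0:
        return SplitPlan(test_ids=[], folds=[],
                         strata_spec="scanner*age_bin*sex*group", seed=seed)
    age_bin = pd.qcut(df["age"], 3, labels=["young", "mid", "old"],
                      duplicates="drop").astype(str)
    levels = [
        df["scanner"].astype(str) + "|" + age_bin + "|"
        + df["sex"].astype(str) + "|" + df["group"].astype(str),
        df["scanner"].astype(str) + "|" + df["sex"].astype(str) + "|"
        + df["group"].astype(str),
        df["scanner"].astype(str) + "|" + df["group"].astype(str),
    ]
    key = levels[0].copy()
    for coarser in levels[1:]:
        sizes = key.value_counts()
        too_small = key.map(sizes) < 2
        key[too_small] = coarser[too_small]
    strata = {k: np.sort(np.array(df.index[key == k]))
              for k in sorted(key.unique())}
    target_total = int(round(test_fraction * len(df)))
    alloc = {k: int(np.floor(test_fraction * len(ids)))
             for k, ids in strata.items()}
    remainder = sorted(strata,
                       key=lambda k: (-(test_fraction * len(strata[k])
                                        - alloc[k]), k))
    i = 0
    while sum(alloc.values()) < target_total and i < len(remainder):
        k = remainder[i]
        if alloc[k] < len(strata[k]):
            alloc[k] += 1
        i += 1
    rng = np.random.default_rng(seed)
    test_ids = []
    for k, ids in strata.items():
        if alloc[k] > 0:
            test_ids.extend(rng.choice(ids, size=alloc[k], replace=False))
    return SplitPlan(test_ids=sorted(test_ids), folds=[],
                     strata_spec="scanner*age_bin*sex*group", seed=seed,
                     stratum_of=dict(zip(key.index, key)))


def make_cv_folds(table: FeatureTable, k, seed: int = 0,
                  plan: SplitPlan | None = None) -> SplitPlan:
    """Group-stratified k-fold (or LOOCV) folds over the non-test subjects.

    ``k`` may be an integer or the string ``"loocv"``.  When ``plan`` is
    given its test holdout is respected and carried into the returned plan.
    """
    test_ids = list(plan.test_ids) if plan is not None else []
    rest = [s for s in table.subject_ids if s not in set(test_ids)]
    sub = table.select_subjects(rest)
    y = sub.group_codes().to_numpy()
    ids = np.array(rest)
    folds = []
    if isinstance(k, str) and k.lower() == "loocv":
        for train_idx, valid_idx in LeaveOneOut().split(ids):
            folds.append((ids[train_idx].tolist(), ids[valid_idx].tolist()))
    else:
        k = int(k)
        if k > len(ids):
            raise ValueError(f"k={k} exceeds {len(ids)} non-test subjects")
        skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
        for train_idx, valid_idx in skf.split(ids, y):
            if len(np.unique(y[valid_idx])) < 2:
                warnings.warn(f"a fold's validation split is single-class at k={k}")
            folds.append((ids[train_idx].tolist(), ids[valid_idx].tolist()))
    out = SplitPlan(test_ids=test_ids, folds=folds,
                    strata_spec=(plan.strata_spec if plan else "group"),
                    seed=seed)
    out.validate(table.subject_ids)
    return out


# ---------------------------------------------------------------------------
# classifiers
# ---------------------------------------------------------------------------

CLASSIFIER_KINDS = ("LOGREG", "SVM", "RANDOM_FOREST", "GRADIENT_BOOSTING")


class ScoringModel:
    """A fitted classifier exposing one continuous PD-score per subject."""

    def __init__(self, estimator):
        self.estimator = estimator

    def scores(self, X) -> np.ndarray:
        est = self.estimator
        if hasattr(est, "predict_proba"):
            return est.predict_proba(np.asarray(X, dtype=float))[:, 1]
        return est.decision_function(np.asarray(X, dtype=float))

    def predict(self, X) -> np.ndarray:
        return self.estimator.predict(np.asarray(X, dtype=float))


def train_classifier(kind: str, hyperparams: dict, X, y,
                     seed: int = 0) -> ScoringModel:
    """Fit one of the supported classifier families (a thin sklearn adapter)."""
    y = np.asarray(y)
    if len(np.unique(y)) < 2:
        raise ValueError("training labels contain a single class")
    hp = dict(hyperparams or {})
    if kind == "LOGREG":
        est = LogisticRegression(C=hp.get("C", 1.0), max_iter=5000)
    elif kind == "SVM":
        est = SVC(C=hp.get("C", 1.0), gamma=hp.get("gamma", "scale"),
                  kernel=hp.get("kernel", "rbf"), random_state=seed)
    elif kind == "RANDOM_FOREST":
        est = RandomForestClassifier(
            n_estimators=hp.get("n_estimators", 200),
            max_depth=hp.get("max_depth"), random_state=seed, n_jobs=1)
    elif kind == "GRADIENT_BOOSTING":
        est = GradientBoostingClassifier(
            n_estimators=hp.get("n_estimators", 100),
            max_depth=hp.get("max_depth", 3),
            learning_rate=hp.get("learning_rate", 0.1), random_state=seed)
    else:
        raise ValueError(f"unknown classifier kind {kind!r}")
    est.fit(np.asarray(X, dtype=float), y)
    return ScoringModel(est)


# ---------------------------------------------------------------------------
# search
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SearchSpace:
    """What the random hyperparameter search may sample.

    The hyperparameter ranges are repository defaults (log-uniform
    regularization for the linear models, modest tree counts/depths for the
    ensembles); they are deliberately configurable because sensible ranges
    are problem-dependent.
    """

    classifier_kinds: tuple = ("LOGREG",)
    n_iter: int = 200
    seed: int = 0
    balance_options: tuple = (BalanceConfig(),)
    feature_set_options: tuple = ("DOJ_PLUS_FS",)
    strategy_options: tuple = (HarmonizationStrategy.FIT_TRAIN_ONLY,)
    etiv_correct: bool = False
    design: CovariateDesign = field(default_factory=CovariateDesign)
    min_batch_size: int = 5

    def __post_init__(self) -> None:
        if self.n_iter < 1:
            raise ValueError("n_iter must be >= 1")
        for kind in self.classifier_kinds:
            if kind not in CLASSIFIER_KINDS:
                raise ValueError(f"unknown classifier kind {kind!r}")

    def sample_trials(self, rng: np.random.Generator, n: int) -> list[dict]:
        """Draw ``n`` fully specified configurations."""
        trials = []
        for _ in range(n):
            kind = str(rng.choice(self.classifier_kinds))
            if kind == "LOGREG":
                hp = {"C": float(10 ** rng.uniform(-3, 2))}
            elif kind == "SVM":
                hp = {"C": float(10 ** rng.uniform(-2, 2)),
                      "gamma": float(10 ** rng.uniform(-4, 0)),
                      "kernel": "rbf"}
            elif kind == "RANDOM_FOREST":
                hp = {"n_estimators": int(rng.integers(50, 501)),
                      "max_depth": int(rng.integers(2, 9))}
            else:
                hp = {"n_estimators": int(rng.integers(50, 301)),
                      "max_depth": int(rng.integers(2, 9)),
                      "learning_rate": float(10 ** rng.uniform(-2, -0.3))}
            trials.append({
                "classifier": kind,
                "hyperparams": hp,
                "balance": self.balance_options[rng.integers(len(self.balance_options))],
                "feature_set": str(self.feature_set_options[
                    rng.integers(len(self.feature_set_options))]),
                "strategy": HarmonizationStrategy(self.strategy_options[
                    rng.integers(len(self.strategy_options))]),
                "seed": int(rng.integers(0, 2 ** 31 - 1)),
            })
        return trials


@dataclass
class TrialResult:
    """One sampled configuration and its cross-validated performance."""

    config: dict
    fold_aucs: list
    mean_auc: float
    sd_auc: float
    test_auc: float | None = None
    per_scanner: dict | None = None
    failed: bool = False
    error: str | None = None

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        cfg = dict(self.config)
        cfg["balance"] = dataclasses.asdict(cfg["balance"])
        cfg["strategy"] = str(cfg["strategy"].value)
        d["config"] = cfg
        return d


def _evaluate_fold(table, plan, fold_index, trial, design, min_batch_size,
                   etiv_correct=False):
    strategy = trial["strategy"]
    prepared = prepare_features(table, trial["feature_set"], etiv_correct)
    harmonized = harmonize_splits(strategy, prepared, plan, design=design,
                                  fold_index=fold_index,
                                  min_batch_size=min_batch_size)
    train_ids, valid_ids = plan.folds[fold_index]
    train = balance_training_set(harmonized.select_subjects(train_ids),
                                 trial["balance"])
    model = train_classifier(trial["classifier"], trial["hyperparams"],
                             train.features.to_numpy(),
                             train.group_codes().to_numpy(),
                             seed=trial["seed"])
    valid = harmonized.select_subjects(valid_ids)
    return roc_auc(model.scores(valid.features.to_numpy()), valid.group)


def _evaluate_test(table, plan, trial, design, min_batch_size,
                   etiv_correct=False):
    """Refit the selected configuration on all non-test rows; score the test set.

    The final "training" set is train+valid, so the train-only strategies fit
    their harmonizer on all non-test rows here.
    """
    strategy = trial["strategy"]
    prepared = prepare_features(table, trial["feature_set"], etiv_correct)
    non_test = [s for s in table.subject_ids if s not in set(plan.test_ids)]
    final_plan = SplitPlan(test_ids=list(plan.test_ids),
                           folds=[(non_test, [])], seed=plan.seed)
    harmonized = harmonize_splits(strategy, prepared, final_plan,
                                  design=design, fold_index=0,
                                  min_batch_size=min_batch_size)
    train = balance_training_set(harmonized.select_subjects(non_test),
                                 trial["balance"])
    model = train_classifier(trial["classifier"], trial["hyperparams"],
                             train.features.to_numpy(),
                             train.group_codes().to_numpy(),
                             seed=trial["seed"])
    test = harmonized.select_subjects(plan.test_ids)
    scores = model.scores(test.features.to_numpy())
    auc = roc_auc(scores, test.group)
    report = scanner_specific_report(scores, test.group, test.scanner,
                                     strategy=strategy)
    return auc, report


def random_search(space: SearchSpace, table: FeatureTable,
                  plan: SplitPlan) -> tuple[list[TrialResult], TrialResult]:
    """Random configuration search scored by mean validation AUC.

    Every trial harmonizes each fold independently (the fold's training rows
    are the fit set for the train-only strategies) and balances the training
    fold only.  The winning trial -- argmax mean validation AUC, earliest
    trial on ties -- is refit on all non-test rows and scored once on the
    held-out test set.
    """
    rng = np.random.default_rng(space.seed)
    trials = space.sample_trials(rng, space.n_iter)
    results = []
    for trial in trials:
        try:
            fold_aucs = [
                _evaluate_fold(table, plan, f, trial, space.design,
                               space.min_batch_size, space.etiv_correct)
                for f in range(len(plan.folds))]
            mean = float(np.mean(fold_aucs))
            sd = float(np.std(fold_aucs, ddof=1)) if len(fold_aucs) > 1 else 0.0
            results.append(TrialResult(config=trial, fold_aucs=fold_aucs,
                                       mean_auc=mean, sd_auc=sd))
        except Exception as exc:                      # noqa: BLE001
            logger.warning("trial failed: %s", exc)
            results.append(TrialResult(config=trial, fold_aucs=[],
                                       mean_auc=float("nan"), sd_auc=float("nan"),
                                       failed=True, error=str(exc)))
    ok = [r for r in results if not r.failed]
    if not ok:
        raise RuntimeError("all trials failed")
    best = max(ok, key=lambda r: r.mean_auc)          # max is stable: first wins ties
    if plan.test_ids:
        best.test_auc, report = _evaluate_test(table, plan, best.config,
                                               space.design,
                                               space.min_batch_size,
                                               space.etiv_correct)
        best.per_scanner = report.per_scanner
    return results, best


# ---------------------------------------------------------------------------
# experiment drivers
# ---------------------------------------------------------------------------

def run_single_scanner(table: FeatureTable, scanner_id: str,
                       space: SearchSpace, min_per_class: int = 4) -> TrialResult:
    """Single-scanner classifier: one site's rows, LOOCV, no harmonization.

    With a single site there is no batch variable to model, so any
    harmonization strategy other than NONE is an error.  The reported AUC
    pools the leave-one-out scores.
    """
    for s in space.strategy_options:
        if HarmonizationStrategy(s) is not HarmonizationStrategy.NONE:
            raise ValueError("single-scanner classification cannot use "
                             "harmonization: there is only one site")
    sub = table.select_subjects(
        table.data.index[table.scanner == scanner_id])
    if sub.n_subjects == 0:
        raise ValueError(f"unknown scanner {scanner_id!r}")
    counts = sub.group.value_counts()
    if len(counts) < 2:
        raise ValueError(f"scanner {scanner_id!r} has a single class")
    if counts.min() < min_per_class:
        raise ValueError(f"scanner {scanner_id!r} has fewer than "
                         f"{min_per_class} subjects in a class")
    plan = make_cv_folds(sub, "loocv", seed=space.seed)
    rng = np.random.default_rng(space.seed)
    trials = space.sample_trials(rng, space.n_iter)
    best = None
    for trial in trials:
        prepared = prepare_features(sub, trial["feature_set"],
                                    space.etiv_correct)
        scores = np.empty(prepared.n_subjects)
        order = []
        for f, (train_ids, valid_ids) in enumerate(plan.folds):
            train = balance_training_set(prepared.select_subjects(train_ids),
                                         trial["balance"])
            model = train_classifier(trial["classifier"], trial["hyperparams"],
                                     train.features.to_numpy(),
                                     train.group_codes().to_numpy(),
                                     seed=trial["seed"])
            scores[f] = model.scores(
                prepared.select_subjects(valid_ids).features.to_numpy())[0]
            order.append(valid_ids[0])
        auc = roc_auc(scores, prepared.select_subjects(order).group)
        result = TrialResult(config=trial, fold_aucs=[auc], mean_auc=auc,
                             sd_auc=0.0)
        if best is None or result.mean_auc > best.mean_auc:
            best = result
    return best


def run_multi_scanner(table: FeatureTable, strategy, space: SearchSpace,
                      test_fraction: float = 0.2, k: int = 5,
                      min_hv: int = 10, min_pd: int = 10) -> TrialResult:
    """Full multi-scanner pipeline for one harmonization strategy.

    Eligibility filter -> stratified test holdout -> group-stratified k-fold
    CV -> random search (strategy forced) -> best-trial test evaluation with
    a per-scanner report.
    """
    strategy = HarmonizationStrategy(strategy)
    eligible = filter_eligible_scanners(table, min_hv=min_hv, min_pd=min_pd)
    if eligible.scanner.nunique() < 2:
        raise ValueError("multi-scanner classification needs >= 2 eligible scanners")
    plan = stratified_holdout(eligible, test_fraction, seed=space.seed)
    plan = make_cv_folds(eligible, k, seed=space.seed, plan=plan)
    space = dataclasses.replace(space, strategy_options=(strategy,))
    _, best = random_search(space, eligible, plan)
    return best
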