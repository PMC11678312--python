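"""Evaluation metrics, scanner-specific reporting, and the leakage experiment.

AUC is the Mann-Whitney probability that a randomly chosen PD subject scores
above a randomly chosen HV subject (ties credited 1/2); balanced accuracy is
the mean of sensitivity and specificity.  Scanner-specific reporting
evaluates one multi-scanner classifier separately on each scanner's
subjects, aggregating as mean +- sample SD across scanners -- the view that
exposes how unevenly a pooled classifier treats individual sites.
"""

from __future__ import annotations

import dataclasses

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from sklearn.metrics import balanced_accuracy_score, roc_auc_score

__all__ = ["roc_auc", "balanced_accuracy", "EvaluationReport",
           "aggregate_scanner_aucs", "scanner_specific_report",
           "LeakageReport", "leakage_comparison"]


def _binary_labels(labels) -> np.ndarray:
    y = np.asarray(labels)
    if y.dtype.kind in "OU":
        mapped = pd.Series(y).map({"PD": 1, "HV": 0})
        if mapped.isna().any():
            raise ValueError("labels must be PD/HV or binary 0/1")
        y = mapped.to_numpy()
    return y.astype(int)


def roc_auc(scores, labels) -> float:
    """Area under the ROC curve; NaN when only one class is present."""
    y = _binary_labels(labels)
    if len(np.unique(y)) < 2:
        return float("nan")
    return float(roc_auc_score(y, np.asarray(scores, dtype=float)))


def balanced_accuracy(predictions, labels) -> float:
    """(sensitivity + specificity) / 2; NaN when only one class is present."""
    y = _binary_labels(labels)
    if len(np.unique(y)) < 2:
        return float("nan")
    return float(balanced_accuracy_score(y, _binary_labels(predictions)))


def aggregate_scanner_aucs(values) -> tuple[float, float]:
    """Mean and sample SD (n-1 denominator) over per-scanner AUC values.

    NaN entries (single-class scanners) are excluded; the SD is NaN when
    fewer than two defined values remain.
    """
    v = np.asarray(list(values), dtype=float)
    v = v[~np.isnan(v)]
    if len(v) == 0:
        return float("nan"), float("nan")
    mean = float(v.mean())
    sd = float(v.std(ddof=1)) if len(v) > 1 else float("nan")
    return mean, sd


@dataclass
class EvaluationReport:
    """Per-scanner AUCs with their cross-scanner aggregate."""

    per_scanner: dict
    overall_mean: float
    overall_sd: float
    strategy: str | None = None
    n_reps: int | None = None

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def scanner_specific_report(scores, labels, scanner,
                            strategy=None) -> EvaluationReport:
    """AUC of one score vector evaluated within each scanner's subjects.

    Scanners whose subjects are single-class get AUC NaN (flagged, excluded
    from the aggregate).
    """
    scores = np.asarray(scores, dtype=float)
    y = _binary_labels(labels)
    scanner = np.asarray(scanner)
    if len(scores) == 0:
        raise ValueError("empty input")
    per = {}
    for sid in pd.unique(scanner):
        m = scanner == sid
        per[str(sid)] = roc_auc(scores[m], y[m])
    mean, sd = aggregate_scanner_aucs(per.values())
    return EvaluationReport(per_scanner=per, overall_mean=mean, overall_sd=sd,
                            strategy=str(strategy) if strategy else None)


# ---------------------------------------------------------------------------
# the leakage-comparison experiment
# ---------------------------------------------------------------------------

@dataclass
class LeakageReport:
    """Replicate-level AUCs per harmonization strategy, with aggregates."""

    strategies: list
    test_auc: dict          # strategy -> list of per-replicate test AUCs
    valid_auc: dict         # strategy -> list of per-replicate mean valid AUCs
    n_reps: int
    seed: int

    @staticmethod
    def _key(strategy) -> str:
        return str(getattr(strategy, "value", strategy))

    def mean_test_auc(self, strategy) -> float:
        return float(np.mean(self.test_auc[self._key(strategy)]))

    def sd_test_auc(self, strategy) -> float:
        return float(np.std(self.test_auc[self._key(strategy)], ddof=1))

    def mean_valid_auc(self, strategy) -> float:
        return float(np.mean(self.valid_auc[self._key(strategy)]))

    def pairwise_test_gap(self, a, b) -> float:
        """Mean over replicates of (test AUC under a) - (test AUC under b)."""
        da = np.asarray(self.test_auc[self._key(a)])
        db = np.asarray(self.test_auc[self._key(b)])
        return float((da - db).mean())

    def paired_valid_diffs(self, a, b) -> np.ndarray:
        return (np.asarray(self.valid_auc[self._key(a)])
                - np.asarray(self.valid_auc[self._key(b)]))

    def to_dict(self) -> dict:
        out = {"n_reps": self.n_reps, "seed": self.seed, "strategies": []}
        for s in self.strategies:
            s = str(s)
            out["strategies"].append({
                "strategy": s,
                "test_auc": list(map(float, self.test_auc[s])),
                "valid_auc": list(map(float, self.valid_auc[s])),
                "mean_test_auc": self.mean_test_auc(s),
                "sd_test_auc": self.sd_test_auc(s) if self.n_reps > 1 else None,
                "mean_valid_auc": self.mean_valid_auc(s),
            })
        out["pairwise_test_gaps"] = {
            f"{a} - {b}": self.pairwise_test_gap(a, b)
            for a in map(str, self.strategies) for b in map(str, self.strategies)
            if a != b}
        return out


def leakage_comparison(config, strategies, n_reps: int = 20, seed: int = 0,
                       space=None, **run_kwargs) -> LeakageReport:
    """Re-run the multi-scanner pipeline on fresh cohorts per strategy.

    For each replicate a new cohort is drawn from ``config`` (seed derived
    from ``seed``), then :func:`combatcv.pipeline.run_multi_scanner` is
    executed once per harmonization strategy with a small fixed search
    budget; the selected model's held-out test AUC and mean validation AUC
    are collected.  Comparing a label-dependent fit strategy against a
    label-free one on cohorts with *no* group effect measures how much
    apparent performance the leaked labels buy.
    """
    from .cohort import generate_cohort
    from .pipeline import SearchSpace, run_multi_scanner

    strategies = [str(getattr(s, "value", s)) for s in strategies]
    if not strategies:
        raise ValueError("need at least one strategy")
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    rng = np.random.default_rng(seed)
    rep_seeds = rng.integers(0, 2 ** 31 - 1, size=n_reps)
    test_auc = {s: [] for s in strategies}
    valid_auc = {s: [] for s in strategies}
    for r, rs in enumerate(rep_seeds):
        cohort = generate_cohort(replace(config, seed=int(rs)))
        # every strategy arm sees identical trial configurations and splits,
        # so per-replicate differences are paired at the trial level
        sp = space if space is not None else SearchSpace(
            classifier_kinds=("LOGREG",), n_iter=2)
        sp = dataclasses.replace(sp, seed=int(rs) % 100000)
        for s in strategies:
            result = run_multi_scanner(cohort, s, sp, **run_kwargs)
            test_auc[s].append(result.test_auc)
            valid_auc[s].append(result.mean_auc)
    return LeakageReport(strategies=strategies, test_auc=test_auc,
                         valid_auc=valid_auc, n_reps=n_reps, seed=seed)
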