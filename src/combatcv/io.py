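"""File formats and experiment configuration.

Canonical on-disk formats: TSV for feature tables (columns ``subject_id``,
``scanner``, ``group``, ``age``, ``sex``, ``etiv``, then features), JSON for
fitted models, split plans and results, YAML for experiment configs.  Every
CLI run emits a manifest (config hash, seeds, package version, stage) so a
result can be reproduced exactly.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import platform
from dataclasses import dataclass, field

import pandas as pd
import yaml

from .cohort import (META_COLUMNS, CohortConfig, FeatureTable, ScannerSpec,
                     default_cohort_config)
from .combat import HarmonizationStrategy
from .pipeline import SearchSpace, SplitPlan
from .resampling import BalanceConfig

__all__ = ["read_feature_table", "write_feature_table", "ExperimentConfig",
           "read_split_plan", "write_split_plan", "run_manifest"]

_REQUIRED = ("scanner", "group", "age", "sex")


def _sep_for(path: str) -> str:
    return "," if str(path).endswith(".csv") else "\t"


def write_feature_table(table: FeatureTable, path: str) -> None:
    meta = [c for c in META_COLUMNS if c in table.data.columns]
    table.data[meta + table.feature_names].to_csv(path, sep=_sep_for(path))


def read_feature_table(path: str) -> FeatureTable:
    """Read and validate a TSV/CSV feature table (dialect from extension)."""
    df = pd.read_csv(path, sep=_sep_for(path))
    if "subject_id" not in df.columns:
        raise ValueError(f"{path}: missing 'subject_id' column")
    missing = [c for c in _REQUIRED if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s) {missing}")
    dup = df["subject_id"][df["subject_id"].duplicated()]
    if len(dup):
        raise ValueError(f"{path}: duplicate subject_id {dup.iloc[0]!r}")
    df = df.set_index("subject_id")
    feature_cols = [c for c in df.columns if c not in META_COLUMNS]
    for col in feature_cols:
        bad = pd.to_numeric(df[col], errors="coerce").isna() & df[col].notna()
        if bad.any():
            row = df.index[bad][0]
            raise ValueError(f"{path}: non-numeric value in feature column "
                             f"{col!r}, row {row!r}")
        df[col] = pd.to_numeric(df[col])
    return FeatureTable(df)


def write_split_plan(plan: SplitPlan, path: str) -> None:
    with open(path, "w") as fh:
        json.dump({"test_ids": list(plan.test_ids),
                   "folds": [[list(t), list(v)] for t, v in plan.folds],
                   "strata_spec": plan.strata_spec, "seed": plan.seed},
                  fh, indent=1)


def read_split_plan(path: str) -> SplitPlan:
    with open(path) as fh:
        d = json.load(fh)
    return SplitPlan(test_ids=d["test_ids"],
                     folds=[tuple(f) for f in d["folds"]],
                     strata_spec=d.get("strata_spec", ""),
                     seed=d.get("seed", 0))


@dataclass
class ExperimentConfig:
    """A full experiment: cohort source, preparation, splits, search, balance."""

    cohort: CohortConfig | str = field(default_factory=default_cohort_config)
    feature_set: str = "DOJ_PLUS_FS"
    etiv_correct: bool = False
    strategies: tuple = (HarmonizationStrategy.FIT_TRAIN_ONLY,)
    balance: BalanceConfig = field(default_factory=BalanceConfig)
    search: SearchSpace = field(default_factory=SearchSpace)
    test_fraction: float = 0.2
    k: int = 5
    seed: int = 0
    min_hv: int = 10
    min_pd: int = 10

    def to_dict(self) -> dict:
        d = {
            "cohort": (self.cohort if isinstance(self.cohort, str)
                       else _cohort_to_dict(self.cohort)),
            "feature_set": self.feature_set,
            "etiv_correct": self.etiv_correct,
            "strategies": [str(HarmonizationStrategy(s).value)
                           for s in self.strategies],
            "balance": dataclasses.asdict(self.balance),
            "search": _search_to_dict(self.search),
            "test_fraction": self.test_fraction,
            "k": self.k,
            "seed": self.seed,
            "min_hv": self.min_hv,
            "min_pd": self.min_pd,
        }
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ExperimentConfig":
        kwargs = dict(d)
        if isinstance(kwargs.get("cohort"), dict):
            kwargs["cohort"] = _cohort_from_dict(kwargs["cohort"])
        if "balance" in kwargs and isinstance(kwargs["balance"], dict):
            kwargs["balance"] = BalanceConfig(**kwargs["balance"])
        if "search" in kwargs and isinstance(kwargs["search"], dict):
            kwargs["search"] = _search_from_dict(kwargs["search"])
        if "strategies" in kwargs:
            kwargs["strategies"] = tuple(HarmonizationStrategy(s)
                                         for s in kwargs["strategies"])
        return cls(**kwargs)

    def to_yaml(self, path: str) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path: str) -> "ExperimentConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def _cohort_to_dict(cfg: CohortConfig) -> dict:
    d = dataclasses.asdict(cfg)
    d["scanners"] = [dataclasses.asdict(s) for s in cfg.scanners]
    return d


def _cohort_from_dict(d: dict) -> CohortConfig:
    d = dict(d)
    d["scanners"] = tuple(ScannerSpec(**s) for s in d["scanners"])
    return CohortConfig(**d)


def _search_to_dict(space: SearchSpace) -> dict:
    d = dataclasses.asdict(space)
    d["classifier_kinds"] = list(space.classifier_kinds)
    d["balance_options"] = [dataclasses.asdict(b) for b in space.balance_options]
    d["feature_set_options"] = list(space.feature_set_options)
    d["strategy_options"] = [str(HarmonizationStrategy(s).value)
                             for s in space.strategy_options]
    return d


def _search_from_dict(d: dict) -> SearchSpace:
    from .combat import CovariateDesign
    d = dict(d)
    d["classifier_kinds"] = tuple(d.get("classifier_kinds", ("LOGREG",)))
    d["balance_options"] = tuple(BalanceConfig(**b)
                                 for b in d.get("balance_options",
                                                [dataclasses.asdict(BalanceConfig())]))
    d["feature_set_options"] = tuple(d.get("feature_set_options", ("DOJ_PLUS_FS",)))
    d["strategy_options"] = tuple(HarmonizationStrategy(s)
                                  for s in d.get("strategy_options", ("train_only",)))
    if isinstance(d.get("design"), dict):
        d["design"] = CovariateDesign(**d["design"])
    return SearchSpace(**d)


def run_manifest(stage: str, config_obj, seed: int) -> dict:
    """Reproducibility manifest: stage, seed, config hash, versions."""
    try:
        from importlib.metadata import version
        pkg_version = version("combatcv")
    except Exception:                                  # pragma: no cover
        pkg_version = "unknown"
    blob = json.dumps(config_obj, sort_keys=True, default=str).encode()
    return {
        "stage": stage,
        "seed": seed,
        "config_sha256": hashlib.sha256(blob).hexdigest(),
        "package_version": pkg_version,
        "python": platform.python_version(),
    }
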