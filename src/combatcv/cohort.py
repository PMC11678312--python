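"""Synthetic multi-scanner morphometry cohorts.

Real multi-site structural-MRI studies pool feature tables (regional volumes,
thicknesses, deformation determinants) acquired on different scanners.  Each
scanner imprints an additive shift and a multiplicative scale on every
feature -- the "batch effect" that ComBat-style harmonization removes -- and
the clinical composition of each site may differ, so scanner identity and
diagnosis can be confounded.  This module generates cohorts with exactly that
statistical structure so the harmonization and classification stages can be
exercised, and their failure modes demonstrated, without access-restricted
clinical data.

Generative model for feature ``v`` of subject ``j`` scanned on scanner ``i``::

    y_ijv = baseline_v + group_j * effect_v + (age_j - 62) * a_v
            + male_j * s_v + gamma_iv + delta_iv * eps_ijv

with ``eps ~ Normal(0, noise_sd^2)``.  Per-feature scanner effects are drawn
around each scanner's location/scale so that batch effects are heterogeneous
across features, matching the empirical-Bayes assumption of the ComBat model:
``gamma_iv ~ Normal(gamma_loc_i, 0.25*|gamma_loc_i| + 0.05)`` and
``delta_iv ~ LogNormal(log delta_scale_i, 0.1)``.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "META_COLUMNS",
    "AGE_REFERENCE",
    "ScannerSpec",
    "CohortConfig",
    "FeatureTable",
    "generate_cohort",
    "filter_eligible_scanners",
    "prepare_features",
    "summarize_cohort",
    "default_scanner_specs",
    "default_cohort_config",
    "leakage_demo_config",
    "benefit_demo_config",
]

#: Metadata columns every feature table carries, in canonical order.
META_COLUMNS = ("scanner", "group", "age", "sex", "etiv")

#: Age (years) around which covariate effects are centred.
AGE_REFERENCE = 62.0

GROUP_LEVELS = ("PD", "HV")
SEX_LEVELS = ("M", "F")


@dataclass(frozen=True)
class ScannerSpec:
    """One scanner: its cohort composition and its true batch effect.

    ``gamma_loc`` / ``delta_scale`` are the location of the additive shift and
    the multiplicative residual scale this scanner imprints on features (the
    quantities ComBat's gamma/delta estimate).
    """

    scanner_id: str
    n_pd: int
    n_hv: int
    gamma_loc: float = 0.0
    delta_scale: float = 1.0
    age_mean: float = 62.0
    age_sd: float = 8.0
    male_fraction: float = 0.6

    def __post_init__(self) -> None:
        if self.n_pd < 0 or self.n_hv < 0:
            raise ValueError(f"{self.scanner_id}: subject counts must be >= 0")
        if self.delta_scale <= 0:
            raise ValueError(f"{self.scanner_id}: delta_scale must be > 0")
        if not 0.0 <= self.male_fraction <= 1.0:
            raise ValueError(f"{self.scanner_id}: male_fraction must be in [0, 1]")


@dataclass(frozen=True)
class CohortConfig:
    """Full recipe for a synthetic multi-scanner cohort."""

    scanners: tuple[ScannerSpec, ...]
    n_features_fs: int = 40
    n_features_doj: int = 60
    lr_pair_fraction: float = 0.6
    group_effect_size: float = 0.0
    group_effect_fraction: float = 0.3
    age_slope: float = -0.01
    sex_shift: float = 0.15
    confound_strength: float = 0.0
    noise_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "scanners", tuple(self.scanners))
        if self.n_features_fs < 0 or self.n_features_doj < 0:
            raise ValueError("feature counts must be >= 0")
        for name in ("lr_pair_fraction", "group_effect_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be > 0")
        if not 0.0 <= self.confound_strength <= 1.0:
            raise ValueError("confound_strength must be in [0, 1]")

    @property
    def n_features(self) -> int:
        return self.n_features_fs + self.n_features_doj


class FeatureTable:
    """Subjects x features matrix with per-subject metadata.

    The universal currency of the pipeline.  Backed by a single pandas
    DataFrame indexed by subject id whose first columns are
    :data:`META_COLUMNS` followed by the (numeric) feature columns.  Feature
    names start with a family tag (``FS_`` or ``DOJ_``) and may end in
    ``_L``/``_R`` for homologous left/right region pairs.
    """

    def __init__(self, data: pd.DataFrame, truth: dict | None = None,
                 validate: bool = True):
        self.data = data
        self.truth = truth
        if validate:
            self._validate()

    # -- validation -----------------------------------------------------
    def _validate(self) -> None:
        df = self.data
        if df.index.name != "subject_id":
            raise ValueError("index must be named 'subject_id'")
        if not df.index.is_unique:
            dupes = df.index[df.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate subject_id values: {dupes[:5]}")
        missing = [c for c in META_COLUMNS if c not in df.columns and c != "etiv"]
        if missing:
            raise ValueError(f"missing metadata columns: {missing}")
        if not df.columns.is_unique:
            raise ValueError("duplicate column names")
        bad_group = set(df["group"].dropna().unique()) - set(GROUP_LEVELS)
        if bad_group:
            raise ValueError(f"group values outside {GROUP_LEVELS}: {sorted(bad_group)}")
        bad_sex = set(df["sex"].dropna().unique()) - set(SEX_LEVELS)
        if bad_sex:
            raise ValueError(f"sex values outside {SEX_LEVELS}: {sorted(bad_sex)}")
        for name in self.feature_names:
            if not pd.api.types.is_numeric_dtype(df[name]):
                raise ValueError(f"feature column {name!r} is not numeric")
        # left/right pairing must be complete in both directions
        names = set(self.feature_names)
        for name in names:
            if name.endswith("_L") and name[:-2] + "_R" not in names:
                raise ValueError(f"feature {name!r} has no matching _R column")
            if name.endswith("_R") and name[:-2] + "_L" not in names:
                raise ValueError(f"feature {name!r} has no matching _L column")

    # -- accessors ------------------------------------------------------
    @property
    def subject_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def n_subjects(self) -> int:
        return len(self.data)

    @property
    def feature_names(self) -> list[str]:
        return [c for c in self.data.columns if c not in META_COLUMNS]

    @property
    def features(self) -> pd.DataFrame:
        return self.data[self.feature_names]

    @property
    def scanner(self) -> pd.Series:
        return self.data["scanner"]

    @property
    def group(self) -> pd.Series:
        return self.data["group"]

    @property
    def age(self) -> pd.Series:
        return self.data["age"]

    @property
    def sex(self) -> pd.Series:
        return self.data["sex"]

    @property
    def etiv(self) -> pd.Series | None:
        return self.data["etiv"] if "etiv" in self.data.columns else None

    def group_codes(self) -> pd.Series:
        """{PD, HV} -> {1, 0}; the one label encoding used everywhere."""
        return self.group.map({"PD": 1, "HV": 0})

    def sex_codes(self) -> pd.Series:
        """{M, F} -> {1, 0}; the one sex encoding used everywhere."""
        return self.sex.map({"M": 1, "F": 0})

    def lr_pairs(self) -> list[tuple[str, str]]:
        names = set(self.feature_names)
        return sorted(
            (n, n[:-2] + "_R") for n in names if n.endswith("_L")
        )

    # -- manipulation ---------------------------------------------------
    def select_subjects(self, ids) -> "FeatureTable":
        return FeatureTable(self.data.loc[list(ids)].copy(), truth=self.truth,
                            validate=False)

    def with_features(self, features: pd.DataFrame) -> "FeatureTable":
        """Replace the feature block, keeping metadata (row-aligned)."""
        meta_cols = [c for c in META_COLUMNS if c in self.data.columns]
        out = pd.concat([self.data[meta_cols], features], axis=1)
        out.index.name = "subject_id"
        return FeatureTable(out, truth=self.truth, validate=False)

    def copy(self) -> "FeatureTable":
        return FeatureTable(self.data.copy(), truth=self.truth, validate=False)

    def equals(self, other: "FeatureTable") -> bool:
        return self.data.equals(other.data)

    def __repr__(self) -> str:  # pragma: no cover
        return (f"FeatureTable({self.n_subjects} subjects x "
                f"{len(self.feature_names)} features, "
                f"{self.scanner.nunique()} scanners)")


# ---------------------------------------------------------------------------
# generation
# ---------------------------------------------------------------------------

def _feature_names(config: CohortConfig) -> tuple[list[str], list[str]]:
    """Deterministic feature name lists (FS family, DOJ family)."""
    def family(tag: str, n: int) -> list[str]:
        n_paired = int(round(n * config.lr_pair_fraction / 2.0)) * 2
        n_paired = min(n_paired, n if n % 2 == 0 else n - 1)
        names = []
        for k in range(n_paired // 2):
            names += [f"{tag}_roi{k:03d}_L", f"{tag}_roi{k:03d}_R"]
        for k in range(n - n_paired):
            names.append(f"{tag}_mid{k:03d}")
        return names

    return family("FS", config.n_features_fs), family("DOJ", config.n_features_doj)


def _confounded_counts(config: CohortConfig) -> list[tuple[int, int]]:
    """Per-scanner (n_pd, n_hv) after applying the confounding knob.

    Confounding is implemented as scanner-dependent PD prevalence: scanners
    are ranked by their additive batch effect and prevalence increases with
    that rank, so scanner identity carries label information while the
    features themselves carry no direct group effect.  Totals per scanner are
    preserved.
    """
    counts = [(s.n_pd, s.n_hv) for s in config.scanners]
    c = config.confound_strength
    if c == 0 or len(config.scanners) < 2:
        return counts
    order = np.argsort([s.gamma_loc for s in config.scanners], kind="stable")
    rank = np.empty(len(order), dtype=float)
    rank[order] = np.linspace(0.0, 1.0, len(order))
    out = []
    for (n_pd, n_hv), r in zip(counts, rank):
        n_tot = n_pd + n_hv
        p = 0.5 + c * (r - 0.5)
        new_pd = int(np.clip(round(n_tot * p), 1, max(n_tot - 1, 1)))
        out.append((new_pd, n_tot - new_pd))
    return out


def generate_cohort(config: CohortConfig) -> FeatureTable:
    """Draw a complete synthetic cohort; a pure function of ``config.seed``.

    The returned table's ``truth`` dict records the realized per-scanner,
    per-feature batch effects and the per-feature group/covariate
    coefficients, so recovery tests can compare estimates against ground
    truth.
    """
    ids = [s.scanner_id for s in config.scanners]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate scanner_id in config")
    n_total = sum(s.n_pd + s.n_hv for s in config.scanners)
    if n_total == 0:
        raise ValueError("cohort has zero subjects")

    rng = np.random.default_rng(config.seed)
    fs_names, doj_names = _feature_names(config)
    names = fs_names + doj_names
    p = len(names)
    is_fs = np.array([n.startswith("FS_") for n in names])

    # per-feature baselines: FS in arbitrary standardized volume units,
    # DOJ centred at 1 (no deformation)
    baseline = np.where(is_fs, rng.normal(3.0, 1.0, p), 1.0 + rng.normal(0.0, 0.1, p))

    # which features carry a group effect, and with what (signed) size
    n_affected = int(round(config.group_effect_fraction * p))
    affected = np.zeros(p, dtype=bool)
    affected[rng.choice(p, size=n_affected, replace=False)] = True
    signs = rng.choice([-1.0, 1.0], size=p)
    effect = np.where(affected, signs * config.group_effect_size * config.noise_sd, 0.0)

    # per-feature covariate coefficients, jittered around the family value
    age_coef = config.age_slope * (1.0 + 0.25 * rng.standard_normal(p))
    sex_coef = config.sex_shift * (1.0 + 0.25 * rng.standard_normal(p))

    # realized per-scanner, per-feature batch effects
    gamma = np.empty((len(config.scanners), p))
    delta = np.empty((len(config.scanners), p))
    for i, s in enumerate(config.scanners):
        gamma[i] = rng.normal(s.gamma_loc, 0.25 * abs(s.gamma_loc) + 0.05, p)
        delta[i] = rng.lognormal(np.log(s.delta_scale), 0.1, p)

    counts = _confounded_counts(config)
    rows, meta = [], []
    for i, (spec, (n_pd, n_hv)) in enumerate(zip(config.scanners, counts)):
        groups = np.array(["PD"] * n_pd + ["HV"] * n_hv)
        n = len(groups)
        age = rng.normal(spec.age_mean, spec.age_sd, n)
        male = rng.random(n) < spec.male_fraction
        etiv = rng.lognormal(np.log(1.5e6), 0.08, n)
        g01 = (groups == "PD").astype(float)
        eps = rng.standard_normal((n, p)) * config.noise_sd
        y = (baseline
             + np.outer(g01, effect)
             + np.outer(age - AGE_REFERENCE, age_coef)
             + np.outer(male.astype(float), sex_coef)
             + gamma[i]
             + delta[i] * eps)
        rows.append(y)
        meta.append(pd.DataFrame({
            "subject_id": [f"{spec.scanner_id}_s{k:03d}" for k in range(n)],
            "scanner": spec.scanner_id,
            "group": groups,
            "age": age,
            "sex": np.where(male, "M", "F"),
            "etiv": etiv,
        }))

    meta_df = pd.concat(meta, ignore_index=True).set_index("subject_id")
    feat_df = pd.DataFrame(np.vstack(rows), index=meta_df.index, columns=names)
    truth = {
        "gamma": pd.DataFrame(gamma, index=ids, columns=names),
        "delta": pd.DataFrame(delta, index=ids, columns=names),
        "group_effect": pd.Series(effect, index=names),
        "age_coef": pd.Series(age_coef, index=names),
        "sex_coef": pd.Series(sex_coef, index=names),
        "baseline": pd.Series(baseline, index=names),
        "counts": dict(zip(ids, counts)),
    }
    return FeatureTable(pd.concat([meta_df, feat_df], axis=1), truth=truth)


# ---------------------------------------------------------------------------
# cohort-level operations
# ---------------------------------------------------------------------------

def filter_eligible_scanners(table: FeatureTable, min_hv: int = 10,
                             min_pd: int = 10) -> FeatureTable:
    """Keep only scanners with at least ``min_hv`` HV and ``min_pd`` PD subjects.

    Scanners with too few subjects of either class cannot support per-batch
    location/scale estimation, so they are dropped wholesale.  Row order is
    preserved.
    """
    if min_hv < 0 or min_pd < 0:
        raise ValueError("thresholds must be >= 0")
    counts = (table.data.groupby(["scanner", "group"], observed=True)
              .size().unstack(fill_value=0))
    for col in GROUP_LEVELS:
        if col not in counts.columns:
            counts[col] = 0
    keep = counts.index[(counts["HV"] >= min_hv) & (counts["PD"] >= min_pd)]
    mask = table.scanner.isin(keep)
    return FeatureTable(table.data.loc[mask].copy(), truth=table.truth,
                        validate=False)


def prepare_features(table: FeatureTable, feature_set: str = "DOJ_PLUS_FS",
                     etiv_correct: bool = False) -> FeatureTable:
    """Feature preparation: family selection, eTIV normalization, DOJ centring.

    * ``FS_`` volumetric features are divided by each subject's estimated
      total intracranial volume when ``etiv_correct`` is set, and the eTIV
      itself is appended as an additional FS feature.
    * ``DOJ_`` deformation features are shifted by -1 so that "no local
      expansion or contraction" maps to 0.
    * ``feature_set`` restricts columns to one family (``FS_ONLY``,
      ``DOJ_ONLY``) or keeps both (``DOJ_PLUS_FS``).

    Not idempotent: the DOJ shift is applied unconditionally.
    """
    if feature_set not in ("FS_ONLY", "DOJ_ONLY", "DOJ_PLUS_FS"):
        raise ValueError(f"unknown feature_set {feature_set!r}")
    X = table.features.copy()
    fs_cols = [c for c in X.columns if c.startswith("FS_")]
    doj_cols = [c for c in X.columns if c.startswith("DOJ_")]
    if doj_cols:
        X[doj_cols] = X[doj_cols] - 1.0
    keep_fs = feature_set in ("FS_ONLY", "DOJ_PLUS_FS")
    keep_doj = feature_set in ("DOJ_ONLY", "DOJ_PLUS_FS")
    if keep_fs and etiv_correct:
        etiv = table.etiv
        if etiv is None or etiv.isna().any():
            raise ValueError("etiv_correct requires an etiv column without missing values")
        if (etiv <= 0).any():
            raise ValueError("etiv_correct requires strictly positive etiv")
        X[fs_cols] = X[fs_cols].div(etiv, axis=0)
        X["FS_eTIV"] = etiv.astype(float)
    cols = (fs_cols + (["FS_eTIV"] if keep_fs and etiv_correct else []) if keep_fs else [])
    cols = cols + (doj_cols if keep_doj else [])
    return table.with_features(X[cols])


def summarize_cohort(table: FeatureTable) -> pd.DataFrame:
    """Per-scanner demographic summary with a TOTAL row.

    Columns: PD/HV counts, age mean +- sd per group, male/female counts per
    group -- the shape of a standard cohort-demographics table.
    """
    if table.n_subjects == 0:
        raise ValueError("empty table")
    rows = {}
    frames = [(sid, g) for sid, g in table.data.groupby("scanner", observed=True)]
    frames.append(("TOTAL", table.data))
    for sid, g in frames:
        pd_rows = g[g["group"] == "PD"]
        hv_rows = g[g["group"] == "HV"]
        rows[sid] = {
            "n_pd": len(pd_rows),
            "n_hv": len(hv_rows),
            "age_pd_mean": pd_rows["age"].mean(),
            "age_pd_sd": pd_rows["age"].std(ddof=1),
            "age_hv_mean": hv_rows["age"].mean(),
            "age_hv_sd": hv_rows["age"].std(ddof=1),
            "male_pd": int((pd_rows["sex"] == "M").sum()),
            "female_pd": int((pd_rows["sex"] == "F").sum()),
            "male_hv": int((hv_rows["sex"] == "M").sum()),
            "female_hv": int((hv_rows["sex"] == "F").sum()),
        }
    out = pd.DataFrame.from_dict(rows, orient="index")
    out.index.name = "scanner"
    out["n_scanners"] = np.nan
    out.loc["TOTAL", "n_scanners"] = len(frames) - 1
    return out


# ---------------------------------------------------------------------------
# packaged default cohorts
# ---------------------------------------------------------------------------

# PD/HV counts, age distributions and sex ratios of an 11-scanner PD/HV
# cohort typical of pooled public + institutional datasets (216 PD, 155 HV).
# gamma_loc/delta_scale are the package's defaults for realistic scanner
# effects: additive shifts within +-1.3 residual SD, scales within [0.7, 1.6].
_DEFAULT_SCANNERS = [
    # id,           n_pd, n_hv, gamma, delta, age_mu, age_sd, male_frac
    ("scanner_01", 24, 12, 0.9, 1.00, 61.2, 8.8, 0.64),
    ("scanner_02", 17, 19, -0.6, 1.40, 62.7, 7.0, 0.75),
    ("scanner_03", 23, 20, 0.2, 0.80, 60.2, 7.7, 0.49),
    ("scanner_04", 16, 12, -1.1, 1.60, 62.6, 10.2, 0.79),
    ("scanner_05", 22, 12, 0.5, 0.70, 60.9, 8.5, 0.65),
    ("scanner_06", 21, 13, 1.3, 1.20, 60.1, 10.5, 0.65),
    ("scanner_07", 14, 10, -0.3, 0.90, 63.4, 7.5, 0.54),
    ("scanner_08", 14, 11, -0.9, 1.50, 59.5, 8.5, 0.72),
    ("scanner_09", 19, 10, 0.7, 0.75, 63.9, 8.7, 0.55),
    ("scanner_10", 26, 16, -0.2, 1.10, 68.3, 11.2, 0.69),
    ("scanner_11", 20, 20, 0.4, 1.30, 65.0, 5.0, 0.58),
]


def default_scanner_specs() -> tuple[ScannerSpec, ...]:
    """The 11 default scanners (216 PD / 155 HV, 371 subjects in total)."""
    return tuple(
        ScannerSpec(scanner_id=sid, n_pd=npd, n_hv=nhv, gamma_loc=g,
                    delta_scale=d, age_mean=mu, age_sd=sd, male_fraction=mf)
        for sid, npd, nhv, g, d, mu, sd, mf in _DEFAULT_SCANNERS
    )


def default_cohort_config(**overrides) -> CohortConfig:
    """Default cohort: 11 scanners, 100 features, realistic batch effects."""
    kwargs = dict(scanners=default_scanner_specs())
    kwargs.update(overrides)
    return CohortConfig(**kwargs)


def leakage_demo_config(**overrides) -> CohortConfig:
    """Study conditions for the leakage demonstration.

    Null group effect (no feature separates PD from HV) but maximal
    scanner-group confounding: PD prevalence tracks each scanner's batch
    effect, so scanner identity is label-informative while the features carry
    no biology.  Six scanners of 30 subjects each -- close to the ~20-scan
    floor practitioners quote for ComBat -- with a full morphometry panel of
    250 features and mild, feature-heterogeneous scale effects.  Small
    per-scanner samples are deliberate: noisy per-batch location/scale and
    group-coefficient estimates are precisely the regime in which fitting the
    harmonizer with a group covariate injects label information into the
    transformed features.
    """
    scanners = tuple(
        ScannerSpec(f"scanner_{i+1:02d}", 15, 15, gamma_loc=g, delta_scale=d)
        for i, (g, d) in enumerate(
            [(1.2, 1.00), (-0.8, 1.20), (0.4, 0.85),
             (-1.4, 1.10), (0.9, 0.90), (-0.3, 1.05)]))
    kwargs = dict(scanners=scanners, n_features_fs=100, n_features_doj=150,
                  group_effect_size=0.0, confound_strength=1.0)
    kwargs.update(overrides)
    return CohortConfig(**kwargs)


def benefit_demo_config(**overrides) -> CohortConfig:
    """Study conditions for the harmonization-benefit demonstration.

    A real group effect (0.5 residual SD on 30% of features) on the default
    11-scanner cohort with doubled additive scanner shifts (strongly
    batch-shifted data) and no confounding; removing scanner effects should
    make the signal easier to learn.
    """
    scanners = tuple(dataclasses.replace(s, gamma_loc=2.0 * s.gamma_loc)
                     for s in default_scanner_specs())
    kwargs = dict(scanners=scanners, group_effect_size=0.5,
                  group_effect_fraction=0.3, confound_strength=0.0)
    kwargs.update(overrides)
    return CohortConfig(**kwargs)
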