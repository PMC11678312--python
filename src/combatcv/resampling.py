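"""Class/scanner balancing and augmentation for training folds.

Multi-scanner disease cohorts are doubly imbalanced: patients usually
outnumber controls, and some scanners contribute twice as many subjects as
others.  These operations equalize strata either by diagnostic group alone
or by group x scanner cell, and optionally augment with left/right mirrored
copies of each brain.  They are applied to the *training* rows only --
:func:`balance_training_set` is the single pipeline entry point and never
sees validation or test rows.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.neighbors import NearestNeighbors

from .cohort import FeatureTable

__all__ = ["BalanceConfig", "random_undersample", "smote", "flip_augment",
           "balance_training_set"]


@dataclass(frozen=True)
class BalanceConfig:
    """Balancing recipe: what to equalize, over which strata, plus mirroring."""

    method: str = "NONE"            # NONE | SMOTE | RUS
    by: str = "GROUP"               # GROUP | GROUP_X_SCANNER
    flip: bool = False
    smote_k: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.method not in ("NONE", "SMOTE", "RUS"):
            raise ValueError(f"unknown method {self.method!r}")
        if self.by not in ("GROUP", "GROUP_X_SCANNER"):
            raise ValueError(f"unknown stratification {self.by!r}")
        if self.smote_k < 1:
            raise ValueError("smote_k must be >= 1")


def _strata(table: FeatureTable, by: str) -> pd.Series:
    if by == "GROUP":
        return table.group.astype(str)
    return table.group.astype(str) + "|" + table.scanner.astype(str)


def random_undersample(table: FeatureTable, by: str = "GROUP",
                       seed: int = 0) -> FeatureTable:
    """Subsample every stratum down to the smallest stratum size.

    Uniform without replacement; surviving rows keep their original order.
    """
    strata = _strata(table, by)
    sizes = strata.value_counts()
    n_min = int(sizes.min())
    rng = np.random.default_rng(seed)
    keep = []
    for key in sizes.index:
        ids = np.array(table.data.index[strata == key])
        keep.extend(rng.choice(ids, size=n_min, replace=False))
    keep = set(keep)
    mask = table.data.index.isin(keep)
    return FeatureTable(table.data.loc[mask].copy(), truth=table.truth,
                        validate=False)


def smote(table: FeatureTable, by: str = "GROUP", k: int = 5,
          seed: int = 0) -> FeatureTable:
    """Upsample minority strata with synthetic nearest-neighbor interpolants.

    Each synthetic row is ``x + u * (x_nn - x)`` for a uniformly drawn
    ``u in (0, 1)``, where ``x`` is a minority row and ``x_nn`` one of its
    ``k`` nearest minority neighbors (Euclidean distance on the feature
    block).  Metadata is copied from ``x``; the synthetic subject id is
    tagged ``_syn<j>``.  Every stratum is raised to the largest stratum size.
    """
    strata = _strata(table, by)
    sizes = strata.value_counts()
    n_max = int(sizes.max())
    rng = np.random.default_rng(seed)
    synth_frames = []
    for key in sizes.index:
        n_need = n_max - int(sizes[key])
        if n_need == 0:
            continue
        sub = table.data.loc[strata == key]
        if len(sub) < 2:
            raise ValueError(
                f"stratum {key!r} has a single row; SMOTE cannot interpolate "
                "-- use RUS or NONE instead")
        k_eff = min(k, len(sub) - 1)
        if k_eff < k:
            warnings.warn(f"stratum {key!r}: lowering smote_k from {k} to "
                          f"{k_eff} (stratum size {len(sub)})")
        X = sub[table.feature_names].to_numpy(dtype=float)
        nn = NearestNeighbors(n_neighbors=k_eff + 1).fit(X)
        neigh = nn.kneighbors(X, return_distance=False)[:, 1:]
        base = rng.integers(0, len(sub), size=n_need)
        pick = neigh[base, rng.integers(0, k_eff, size=n_need)]
        u = rng.random((n_need, 1))
        Xs = X[base] + u * (X[pick] - X[base])
        rows = sub.iloc[base].copy()
        rows[table.feature_names] = Xs
        rows.index = [f"{i}_syn{j}" for j, i in enumerate(rows.index)]
        rows.index.name = "subject_id"
        synth_frames.append(rows)
    if not synth_frames:
        return table.copy()
    out = pd.concat([table.data] + synth_frames)
    return FeatureTable(out, truth=table.truth, validate=False)


def flip_augment(table: FeatureTable) -> FeatureTable:
    """Append one left/right-mirrored copy of every row.

    Every ``_L``/``_R`` column pair is swapped; midline (unpaired) columns
    are copied unchanged; labels and covariates are preserved.  Doubles the
    row count.
    """
    names = set(table.feature_names)
    for n in names:
        if n.endswith("_L") and n[:-2] + "_R" not in names:
            raise ValueError(f"dangling left column {n!r} without _R partner")
        if n.endswith("_R") and n[:-2] + "_L" not in names:
            raise ValueError(f"dangling right column {n!r} without _L partner")
    mirrored = table.data.copy()
    for left, right in table.lr_pairs():
        mirrored[left], mirrored[right] = (table.data[right].to_numpy(),
                                           table.data[left].to_numpy())
    mirrored.index = [f"{i}_flip" for i in mirrored.index]
    mirrored.index.name = "subject_id"
    out = pd.concat([table.data, mirrored])
    return FeatureTable(out, truth=table.truth, validate=False)


def balance_training_set(train: FeatureTable, cfg: BalanceConfig) -> FeatureTable:
    """Apply the balancing recipe to a training fold.

    Mirroring (if enabled) runs first so mirrored rows take part in the
    neighbor search and the stratum counts; the balance method follows.
    """
    out = train
    if cfg.flip:
        out = flip_augment(out)
    if cfg.method == "RUS":
        out = random_undersample(out, by=cfg.by, seed=cfg.seed)
    elif cfg.method == "SMOTE":
        out = smote(out, by=cfg.by, k=cfg.smote_k, seed=cfg.seed)
    elif out is train:
        out = train.copy()
    return out
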