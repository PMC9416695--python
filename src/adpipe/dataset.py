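"""Labeling, cleaning, scaling and splitting of windowed feature tables.

The gold-standard label follows the experimental rule: a window is AD
(positive) only when it lies inside a trigger (colorectal distension)
episode AND its systolic pressure is at least ``delta`` (default 20 mmHg)
above the subject's trigger-free baseline mean. The fixed preparation order
is label -> drop missing -> remove outliers (|z| > 3 on raw features) ->
min-max scale -> stratified 70/15/15 split with 10 stratified CV folds over
the training partition. Scaling parameters are fitted on the cleaned table
and stored for reuse on held-out data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold, train_test_split

from .features import FEATURE_COLUMNS, WindowSpec, associate_readings

__all__ = [
    "LABEL_AD", "LABEL_NON_AD", "ScalerParams", "SplitPlan", "LabeledTable",
    "label_windows", "minmax_scale", "apply_scaler", "inverse_scale",
    "remove_outliers", "drop_missing", "stratified_split", "prepare_dataset",
]

LABEL_AD = 1
LABEL_NON_AD = 0


@dataclass
class ScalerParams:
    """Per-feature min/max fitted on training data; constant features map
    to 0 and are flagged."""

    min_: pd.Series
    max_: pd.Series

    @property
    def constant_features(self) -> list[str]:
        return list(self.min_.index[self.max_ == self.min_])


@dataclass
class SplitPlan:
    """Disjoint, exhaustive stratified row partition with CV folds.

    70% train / 15% test / 15% validation; ``cv_folds`` are 10 stratified
    (train_idx, val_idx) pairs over the training rows only, for model
    selection without touching the test partition.
    """

    train_idx: np.ndarray
    test_idx: np.ndarray
    val_idx: np.ndarray
    cv_folds: list[tuple[np.ndarray, np.ndarray]]
    seed: int


@dataclass
class LabeledTable:
    """Prepared analysis table plus provenance of the cleaning steps."""

    table: pd.DataFrame           # scaled features + subject/window/label
    scaler: ScalerParams
    n_missing_removed: int = 0
    n_outliers_removed: int = 0
    outlier_fraction: float = 0.0
    feature_columns: list[str] = field(default_factory=list)


def _feature_cols(df: pd.DataFrame) -> list[str]:
    return [c for c in df.columns if c in FEATURE_COLUMNS or
            c not in ("subject", "window_start_s", "label")]


def label_windows(feature_table: pd.DataFrame,
                  trigger_events: list[tuple[float, float]],
                  bp: pd.DataFrame, delta_mmhg: float = 20.0,
                  window_len_s: float = 15.0) -> pd.Series:
    """Gold-standard AD labels for each window row.

    AD requires conjunction: the window contained in a trigger episode and
    the associated SBP at least ``delta_mmhg`` above the trigger-free
    baseline mean. Raises when no trigger-free baseline exists.
    """
    starts = feature_table["window_start_s"].to_numpy(dtype=float)
    t = bp["time_s"].to_numpy()
    if trigger_events:
        first = min(s for s, _ in trigger_events)
        base_mask = t < first
    else:
        base_mask = np.ones(t.size, dtype=bool)
    if not base_mask.any():
        raise ValueError("no trigger-free baseline period for SBP reference")
    baseline_sbp = float(bp.loc[base_mask, "sbp"].mean())

    labels = np.full(starts.size, LABEL_NON_AD, dtype=int)
    for i, s in enumerate(starts):
        w = WindowSpec(s, s + window_len_s)
        in_trigger = any(ev_s <= w.start_s and w.end_s <= ev_e
                         for ev_s, ev_e in trigger_events)
        if not in_trigger:
            continue
        sub = associate_readings(bp, w)
        if len(sub) and float(sub["sbp"].mean()) >= baseline_sbp + delta_mmhg:
            labels[i] = LABEL_AD
    return pd.Series(labels, index=feature_table.index, name="label")


def minmax_scale(table: pd.DataFrame,
                 feature_columns: list[str] | None = None
                 ) -> tuple[pd.DataFrame, ScalerParams]:
    """Min-max scale features to [0, 1]; constant columns map to 0."""
    if len(table) < 2:
        raise ValueError("min-max scaling needs at least 2 rows")
    cols = feature_columns or _feature_cols(table)
    params = ScalerParams(table[cols].min(), table[cols].max())
    return apply_scaler(table, params), params


def apply_scaler(table: pd.DataFrame, params: ScalerParams) -> pd.DataFrame:
    out = table.copy()
    span = (params.max_ - params.min_).replace(0.0, 1.0)
    cols = list(params.min_.index)
    out[cols] = (table[cols] - params.min_) / span
    return out


def inverse_scale(table: pd.DataFrame, params: ScalerParams) -> pd.DataFrame:
    out = table.copy()
    span = (params.max_ - params.min_).replace(0.0, 1.0)
    cols = list(params.min_.index)
    out[cols] = table[cols] * span + params.min_
    return out


def remove_outliers(table: pd.DataFrame, z_max: float = 3.0,
                    feature_columns: list[str] | None = None
                    ) -> tuple[pd.DataFrame, pd.Index, float]:
    """Drop rows where any feature's |z| exceeds ``z_max``.

    z-scores use each feature's full-table mean/SD; zero-variance features
    are skipped. Returns (kept rows, removed index, removed fraction).
    Because min-max scaling is affine, computing z on raw or scaled
    features is equivalent.
    """
    if len(table) < 3:
        raise ValueError("outlier removal needs at least 3 rows")
    cols = feature_columns or _feature_cols(table)
    x = table[cols].to_numpy(dtype=float)
    mean = np.nanmean(x, axis=0)
    sd = np.nanstd(x, axis=0)
    ok = sd > 0
    z = np.zeros_like(x)
    z[:, ok] = (x[:, ok] - mean[ok]) / sd[ok]
    bad = (np.abs(z) > z_max).any(axis=1)
    removed = table.index[bad]
    return table.loc[~bad], removed, float(bad.mean())


def drop_missing(table: pd.DataFrame) -> tuple[pd.DataFrame, int]:
    """Drop rows containing any absent (NaN) marker."""
    kept = table.dropna()
    return kept, len(table) - len(kept)


def stratified_split(labels: pd.Series | np.ndarray,
                     fractions: tuple[float, float, float] = (0.70, 0.15, 0.15),
                     seed: int = 0, n_folds: int = 10,
                     groups: pd.Series | np.ndarray | None = None
                     ) -> SplitPlan:
    """Seeded stratified 70/15/15 partition plus stratified CV folds over
    the training rows. Requires each class to supply at least ``n_folds``
    training rows.

    Row-level splitting of windowed data leaks subject identity across
    partitions (windows from one subject are correlated); passing per-row
    ``groups`` (subject ids) switches to a group-aware split that assigns
    whole subjects to partitions, at the cost of only approximate class
    proportions.
    """
    y = np.asarray(labels)
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present to stratify")
    if groups is not None:
        return _grouped_split(y, np.asarray(groups), fractions, seed,
                              n_folds)
    idx = np.arange(y.size)
    f_train, f_test, f_val = fractions
    train, rest = train_test_split(idx, train_size=f_train, stratify=y,
                                   random_state=seed, shuffle=True)
    test, val = train_test_split(rest, train_size=f_test / (f_test + f_val),
                                 stratify=y[rest], random_state=seed,
                                 shuffle=True)
    counts = np.bincount(y[train])
    if counts.min() < n_folds:
        raise ValueError(
            f"cannot build {n_folds} stratified folds: a class has only "
            f"{counts.min()} training rows")
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    folds = [(train[a], train[b]) for a, b in skf.split(train, y[train])]
    return SplitPlan(np.sort(train), np.sort(test), np.sort(val), folds, seed)


def _grouped_split(y: np.ndarray, groups: np.ndarray,
                   fractions: tuple[float, float, float], seed: int,
                   n_folds: int) -> SplitPlan:
    """Assign whole groups (subjects) to partitions by shuffled
    round-robin over the cumulative row fractions; CV folds distribute
    training groups across folds."""
    uniq = np.unique(groups)
    if uniq.size < 3:
        raise ValueError("group-aware split needs at least 3 subjects")
    rng = np.random.default_rng(seed)
    order = rng.permutation(uniq)
    sizes = np.array([np.sum(groups == g) for g in order])
    cum = np.cumsum(sizes) / sizes.sum()
    f_train, f_test, _ = fractions
    parts: dict[str, list] = {"train": [], "test": [], "val": []}
    for g, c in zip(order, cum):
        dest = ("train" if c <= f_train
                else "test" if c <= f_train + f_test else "val")
        parts[dest].append(g)
    # every partition needs at least one group and both classes in train
    for name in parts:
        if not parts[name]:
            parts[name].append(parts["train"].pop())
    sel = {k: np.flatnonzero(np.isin(groups, v)) for k, v in parts.items()}
    if len(np.unique(y[sel["train"]])) < 2:
        raise ValueError("training partition lost a class; add subjects")
    train_groups = np.array(parts["train"], dtype=object)
    k = min(n_folds, len(train_groups))
    fold_assign = np.arange(len(train_groups)) % k
    folds = []
    for j in range(k):
        hold = train_groups[fold_assign == j]
        mask = np.isin(groups[sel["train"]], hold)
        folds.append((sel["train"][~mask], sel["train"][mask]))
    return SplitPlan(sel["train"], sel["test"], sel["val"], folds, seed)


def prepare_dataset(feature_table: pd.DataFrame, labels: pd.Series,
                    seed: int = 0, z_max: float = 3.0, n_folds: int = 10,
                    feature_columns: list[str] | None = None
                    ) -> tuple[LabeledTable, SplitPlan]:
    """Fixed preparation pipeline: drop missing -> remove outliers ->
    min-max scale -> stratified split."""
    df = feature_table.copy()
    df["label"] = np.asarray(labels)
    cols = feature_columns or [c for c in df.columns if c in FEATURE_COLUMNS]
    df, n_missing = drop_missing(df)
    df, _, frac = remove_outliers(df, z_max=z_max, feature_columns=cols)
    n_out = int(round(frac * (len(df) / (1 - frac)))) if frac < 1 else 0
    df = df.reset_index(drop=True)
    scaled, params = minmax_scale(df, feature_columns=cols)
    labeled = LabeledTable(scaled, params, n_missing, n_out, frac, cols)
    plan = stratified_split(scaled["label"], seed=seed, n_folds=n_folds)
    return labeled, plan
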