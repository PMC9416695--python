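"""Feature-selection cascade.

Five complementary routes to a reduced feature subset:

* univariate filters — per-feature two-sample t-test (Welch by default) and
  chi-squared association against the binary label, retaining p < alpha;
* redundancy pruning — iterative removal within feature pairs whose
  pairwise Pearson R^2 exceeds 0.7;
* tree importance — Gini (impurity-decrease) importances from a seeded
  decision tree, thresholded, optionally re-fit recursively;
* greedy stepwise search — backward (or forward) moves scored by
  cross-validated accuracy of a designated estimator;
* recursive feature elimination (RFE) — repeatedly fit an L2-regularized
  logistic regression on standardized features and drop the coefficient
  with the smallest magnitude until sigma features remain.

Each method returns a :class:`SelectionResult` carrying the retained
(ordered) names, per-feature scores and the parameters used, so a
consensus view across methods can be assembled with
:func:`consensus_report`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import cross_val_score
from sklearn.tree import DecisionTreeClassifier

__all__ = [
    "SelectionResult", "ttest_filter", "chi2_filter", "correlation_filter",
    "gini_importance_filter", "stepwise_search", "rfe_logistic",
    "consensus_report", "exhaustive_best_subset",
]


@dataclass
class SelectionResult:
    """Outcome of one selection method."""

    method: str
    retained: list[str]
    scores: dict[str, float] = field(default_factory=dict)
    params: dict = field(default_factory=dict)
    seed: int | None = None
    trajectory: list = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(set(self.retained)) != len(self.retained):
            raise ValueError("retained feature names must be unique")


def _as_xy(table: pd.DataFrame, labels) -> tuple[pd.DataFrame, np.ndarray]:
    X = table.drop(columns=[c for c in ("label", "subject", "window_start_s")
                            if c in table.columns])
    y = np.asarray(labels)
    return X, y


# ---------------------------------------------------------------------------
# univariate filters
# ---------------------------------------------------------------------------

def ttest_filter(table: pd.DataFrame, labels, alpha: float = 0.05,
                 equal_var: bool = False) -> SelectionResult:
    """Retain features whose two-sample t-test p-value is below ``alpha``.

    Welch's unequal-variance form by default; ``equal_var=True`` restores
    the pooled-variance Student form. Features with zero variance in both
    classes carry no p-value and are dropped.
    """
    X, y = _as_xy(table, labels)
    a = X[y == 1].to_numpy(dtype=float)
    b = X[y == 0].to_numpy(dtype=float)
    if min(len(a), len(b)) < 2:
        raise ValueError("each class needs at least 2 rows")
    with np.errstate(divide="ignore", invalid="ignore"):
        _, p = stats.ttest_ind(a, b, equal_var=equal_var, axis=0)
    scores = {c: float(pv) for c, pv in zip(X.columns, p)}
    retained = [c for c in X.columns
                if np.isfinite(scores[c]) and scores[c] < alpha]
    return SelectionResult("ttest", retained, scores,
                           {"alpha": alpha, "equal_var": equal_var})


def chi2_filter(table: pd.DataFrame, labels, alpha: float = 0.05,
                n_bins: int = 4) -> SelectionResult:
    """Retain features whose chi-squared association with the binary label
    has p < ``alpha``.

    Each feature is discretized into ``n_bins`` quantile bins and tested
    against the label in a contingency table, which keeps the test
    calibrated on continuous features (a count-style chi-squared score is
    not). Features must be non-negative (run after min-max scaling);
    constant features cannot be binned, carry no score and are dropped.
    """
    X, y = _as_xy(table, labels)
    if (X.to_numpy(dtype=float) < 0).any():
        raise ValueError(
            "chi2_filter requires non-negative features; min-max scale first")
    scores: dict[str, float] = {}
    stat: dict[str, float] = {}
    for c in X.columns:
        x = X[c].to_numpy(dtype=float)
        edges = np.unique(np.quantile(x, np.linspace(0, 1, n_bins + 1)))
        if edges.size < 3:
            scores[c] = np.nan
            stat[c] = np.nan
            continue
        binned = np.clip(np.searchsorted(edges, x, side="right") - 1,
                         0, edges.size - 2)
        contingency = pd.crosstab(binned, y).to_numpy()
        res = stats.chi2_contingency(contingency, correction=False)
        scores[c], stat[c] = float(res.pvalue), float(res.statistic)
    retained = [c for c in X.columns
                if np.isfinite(scores[c]) and scores[c] < alpha]
    return SelectionResult("chi2", retained, scores,
                           {"alpha": alpha, "n_bins": n_bins,
                            "chi2_statistic": stat})


def correlation_filter(table: pd.DataFrame,
                       r2_max: float = 0.7) -> SelectionResult:
    """Prune mutually redundant features until all pairwise Pearson R^2 are
    at or below ``r2_max``.

    At each round the most-correlated offending pair is considered and the
    member with the larger mean R^2 against the other remaining features is
    dropped (ties drop the later column).
    """
    X = table.drop(columns=[c for c in ("label", "subject", "window_start_s")
                            if c in table.columns])
    if X.shape[1] < 2:
        return SelectionResult("correlation", list(X.columns), {},
                               {"r2_max": r2_max})
    cols = list(X.columns)
    dropped: list[str] = []
    while True:
        with np.errstate(divide="ignore", invalid="ignore"):
            r = np.corrcoef(X[cols].to_numpy(dtype=float), rowvar=False)
        r2 = np.nan_to_num(r**2)  # constant columns correlate with nothing
        np.fill_diagonal(r2, 0.0)
        if r2.max() <= r2_max:
            break
        i, j = np.unravel_index(np.argmax(r2), r2.shape)
        i, j = min(i, j), max(i, j)
        mean_i = (r2[i].sum() - r2[i, j]) / max(len(cols) - 2, 1)
        mean_j = (r2[j].sum() - r2[i, j]) / max(len(cols) - 2, 1)
        victim = j if mean_j >= mean_i else i   # tie -> later column
        dropped.append(cols.pop(victim))
    scores = {c: 1.0 for c in cols}
    return SelectionResult("correlation", cols, scores,
                           {"r2_max": r2_max, "dropped": dropped})


# ---------------------------------------------------------------------------
# tree importance
# ---------------------------------------------------------------------------

def gini_importance_filter(table: pd.DataFrame, labels,
                           threshold: float | None = None, seed: int = 0,
                           n_trees: int = 1,
                           recursive: bool = True) -> SelectionResult:
    """Retain features whose Gini (impurity-decrease) importance meets
    ``threshold`` (default: the uniform share 1/p).

    Importances come from a seeded decision tree, or the average over a
    small forest of ``n_trees`` trees with distinct seeds. The recursive
    variant re-fits after each removal round until all survivors meet the
    threshold; an over-tight threshold yields an empty result with a
    warning.
    """
    X, y = _as_xy(table, labels)
    cols = list(X.columns)
    thr = 1.0 / len(cols) if threshold is None else threshold
    scores: dict[str, float] = {}
    while cols:
        imp = np.zeros(len(cols))
        for k in range(n_trees):
            tree = DecisionTreeClassifier(random_state=seed + k)
            tree.fit(X[cols].to_numpy(dtype=float), y)
            imp += tree.feature_importances_
        imp /= n_trees
        scores.update({c: float(v) for c, v in zip(cols, imp)})
        keep = [c for c, v in zip(cols, imp) if v >= thr]
        if keep == cols or not recursive:
            cols = keep
            break
        cols = keep
    if not cols:
        warnings.warn("gini importance threshold exceeded every importance; "
                      "empty selection", stacklevel=2)
    return SelectionResult("gini", cols, scores,
                           {"threshold": thr, "n_trees": n_trees,
                            "recursive": recursive}, seed=seed)


# ---------------------------------------------------------------------------
# greedy search
# ---------------------------------------------------------------------------

def _default_score_fn(seed: int, cv: int = 3) -> Callable:
    est = LogisticRegression(max_iter=500)

    def score(X: np.ndarray, y: np.ndarray) -> float:
        return float(np.mean(cross_val_score(est, X, y, cv=cv)))

    return score


def stepwise_search(table: pd.DataFrame, labels, direction: str = "backward",
                    score_fn: Callable | None = None,
                    target_dim: int | None = None,
                    seed: int = 0) -> SelectionResult:
    """Greedy stepwise feature search.

    Starting from the full model (backward, default) or the empty one
    (forward), one feature is removed/added per step, choosing the move
    that maximizes ``score_fn`` (default: 3-fold CV accuracy of logistic
    regression). With ``target_dim`` set, the search always runs to that
    dimension; otherwise it stops when no move improves the score. The full
    move trajectory (feature, score) is logged.
    """
    if direction not in ("backward", "forward"):
        raise ValueError("direction must be 'backward' or 'forward'")
    X, y = _as_xy(table, labels)
    score = score_fn or _default_score_fn(seed)
    cols = list(X.columns)
    current = list(cols) if direction == "backward" else []
    best_score = (score(X[current].to_numpy(dtype=float), y)
                  if current else -np.inf)
    trajectory: list[tuple[str, float]] = []

    def done() -> bool:
        if target_dim is not None:
            return len(current) == target_dim
        return False

    while not done():
        if direction == "backward":
            moves = [[c for c in current if c != drop] for drop in current]
            labels_ = list(current)
            if len(current) <= 1:
                break
        else:
            rest = [c for c in cols if c not in current]
            if not rest:
                break
            moves = [current + [c] for c in rest]
            labels_ = rest
        cand_scores = [score(X[m].to_numpy(dtype=float), y) for m in moves]
        k = int(np.argmax(cand_scores))
        if target_dim is None and cand_scores[k] <= best_score:
            break
        best_score = cand_scores[k]
        current = moves[k]
        trajectory.append((labels_[k], best_score))
    return SelectionResult(
        "stepwise", current, {c: best_score for c in current},
        {"direction": direction, "target_dim": target_dim},
        seed=seed, trajectory=trajectory)


def rfe_logistic(table: pd.DataFrame, labels, sigma: int,
                 C: float = 1.0, seed: int = 0) -> SelectionResult:
    """Recursive feature elimination with L2 logistic regression.

    Repeatedly fit on the surviving features, rank by |coefficient|, and
    eliminate the lowest-ranked feature (one per iteration, later column
    dropped on ties) until ``sigma`` remain. Ranks record the elimination
    order: retained features rank 1, the last-eliminated ranks 2, and so
    on. Non-convergence triggers a stronger-regularization refit with a
    warning.
    """
    X, y = _as_xy(table, labels)
    cols = list(X.columns)
    if sigma >= len(cols):
        raise ValueError("sigma must be smaller than the number of features")
    ranks: dict[str, float] = {}
    rank = len(cols) - sigma + 1
    while len(cols) > sigma:
        coef = _fit_logistic_coefs(X[cols].to_numpy(dtype=float), y, C)
        worst = _argmin_last(np.abs(coef))
        ranks[cols.pop(worst)] = rank
        rank -= 1
    ranks.update({c: 1.0 for c in cols})
    return SelectionResult("rfe", cols, ranks, {"sigma": sigma, "C": C},
                           seed=seed)


def _fit_logistic_coefs(X: np.ndarray, y: np.ndarray, C: float) -> np.ndarray:
    for c_try in (C, C / 10.0):
        model = LogisticRegression(C=c_try, max_iter=1000)
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always", ConvergenceWarning)
            model.fit(X, y)
        if not any(issubclass(w.category, ConvergenceWarning) for w in caught):
            return model.coef_.ravel()
        if c_try != C:
            warnings.warn("logistic regression did not converge; kept the "
                          "stronger-regularization fit", stacklevel=2)
    return model.coef_.ravel()


def _argmin_last(v: np.ndarray) -> int:
    """Index of the minimum; ties resolved to the later position."""
    m = v.min()
    return int(np.flatnonzero(v == m)[-1])


# ---------------------------------------------------------------------------
# consensus and testing oracle
# ---------------------------------------------------------------------------

def consensus_report(results: Sequence[SelectionResult]) -> pd.DataFrame:
    """Per-feature selection count across methods, most-selected first.

    Order is stable: ties keep the order of first appearance across the
    input results.
    """
    if not results:
        raise ValueError("at least one SelectionResult required")
    order: list[str] = []
    counts: dict[str, int] = {}
    methods: dict[str, list[str]] = {}
    for res in results:
        for name in res.retained:
            if name not in counts:
                counts[name] = 0
                methods[name] = []
                order.append(name)
            counts[name] += 1
            methods[name].append(res.method)
    rows = sorted(order, key=lambda n: -counts[n])
    return pd.DataFrame({
        "feature": rows,
        "n_selected": [counts[n] for n in rows],
        "methods": [",".join(methods[n]) for n in rows],
    })


def exhaustive_best_subset(table: pd.DataFrame, labels, k: int,
                           score_fn: Callable | None = None,
                           seed: int = 0) -> tuple[list[str], float]:
    """Enumerate every size-``k`` subset and return the best one.

    A testing oracle only: the 2^p explosion restricts it to p <= 15
    features.
    """
    X, y = _as_xy(table, labels)
    if X.shape[1] > 15:
        raise ValueError("exhaustive search is restricted to p <= 15")
    score = score_fn or _default_score_fn(seed)
    best, best_score = None, -np.inf
    for subset in combinations(X.columns, k):
        s = score(X[list(subset)].to_numpy(dtype=float), y)
        if s > best_score:
            best, best_score = list(subset), s
    return best, float(best_score)
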