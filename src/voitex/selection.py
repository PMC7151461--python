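"""Two-level feature selection.

Level 1 drops one member of every feature pair whose absolute Pearson
correlation exceeds a threshold (default 0.90). Level 2 runs recursive
feature elimination with an L2-penalized multinomial logistic-regression
base model on z-scored features, removing the single least-important
feature (smallest L2 coefficient norm across classes) per iteration
until k remain.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold, cross_val_score
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler

from .errors import SelectionError, TrainingError

__all__ = [
    "SelectionResult",
    "correlation_filter",
    "recursive_feature_elimination",
    "selection_sweep",
    "feature_columns",
]

logger = logging.getLogger(__name__)

_META_COLUMNS = ("scan_id", "class")


def feature_columns(table: pd.DataFrame) -> list[str]:
    return [c for c in table.columns if c not in _META_COLUMNS]


@dataclass
class SelectionResult:
    """Outcome of the two-level selection."""

    kept: list[str]  # ordered, rank 1 first
    dropped_by_correlation: list[tuple[str, str, float]]  # (dropped, partner, r)
    rfe_ranking: dict[str, int]  # feature -> rank, 1 = best
    k: int
    base_model_description: str = "z-scored multinomial logistic regression (L2)"

    def to_json(self) -> str:
        return json.dumps(
            {
                "kept": self.kept,
                "dropped_by_correlation": [
                    {"dropped": d, "partner": p, "r": r}
                    for d, p, r in self.dropped_by_correlation
                ],
                "rfe_ranking": self.rfe_ranking,
                "k": self.k,
                "base_model": self.base_model_description,
            },
            indent=2,
        )


def correlation_filter(
    table: pd.DataFrame, threshold: float = 0.90
) -> tuple[pd.DataFrame, list[tuple[str, str, float]]]:
    """Drop features until no surviving pair has |r| > threshold.

    Greedy rule: repeatedly take the worst-correlated surviving pair and
    drop its member with the larger mean |r| to all other surviving
    features (ties: drop the later column). Zero-variance features are
    excluded from the correlation computation and always retained.
    """
    if not 0 < threshold <= 1:
        raise SelectionError(f"threshold must be in (0, 1], got {threshold}")
    if len(table) < 2:
        raise SelectionError("correlation filter needs at least 2 scans")

    cols = feature_columns(table)
    values = table[cols].to_numpy(dtype=float)
    sd = values.std(axis=0)
    constant = [c for c, s in zip(cols, sd) if s == 0]
    if constant:
        logger.warning(
            "retaining %d zero-variance features without correlation check", len(constant)
        )
    active = [c for c in cols if c not in constant]

    corr = np.abs(np.corrcoef(table[active].to_numpy(dtype=float).T)) if active else None
    idx = {c: i for i, c in enumerate(active)}
    alive = list(active)
    drop_log: list[tuple[str, str, float]] = []

    while len(alive) > 1:
        ai = [idx[c] for c in alive]
        sub = corr[np.ix_(ai, ai)]
        np.fill_diagonal(sub, 0.0)
        worst = np.unravel_index(np.argmax(sub), sub.shape)
        r = float(sub[worst])
        if r <= threshold:
            break
        a, b = alive[worst[0]], alive[worst[1]]
        mean_r = sub.mean(axis=0) * len(alive) / max(len(alive) - 1, 1)
        ra, rb = mean_r[worst[0]], mean_r[worst[1]]
        if ra > rb or (ra == rb and alive.index(a) > alive.index(b)):
            dropped, partner = a, b
        else:
            dropped, partner = b, a
        drop_log.append((dropped, partner, r))
        alive.remove(dropped)

    surviving = [c for c in cols if c in set(alive) | set(constant)]
    kept_table = table[list(_META_COLUMNS) + surviving].copy()
    return kept_table, drop_log


def _standardize(x: np.ndarray) -> np.ndarray:
    mu = x.mean(axis=0)
    sd = x.std(axis=0)
    sd[sd == 0] = 1.0
    return (x - mu) / sd


def _fit_base_model(x: np.ndarray, y: np.ndarray, seed: int) -> LogisticRegression:
    for max_iter in (500, 5000):
        # default penalty is ridge (L2); C=1.0
        model = LogisticRegression(C=1.0, max_iter=max_iter, random_state=seed)
        model.fit(x, y)
        if np.all(model.n_iter_ < max_iter):
            return model
    raise TrainingError("logistic base model failed to converge")


def _elimination_order(
    x: np.ndarray, y: np.ndarray, names: list[str], stop_at: int, seed: int
) -> tuple[list[str], list[str]]:
    """Eliminate one feature per iteration until ``stop_at`` remain.

    Returns (eliminated in order, kept ordered by final-fit importance
    descending).
    """
    remaining = list(range(len(names)))
    eliminated: list[str] = []
    model = None
    while len(remaining) > stop_at:
        model = _fit_base_model(x[:, remaining], y, seed)
        importance = np.linalg.norm(model.coef_, axis=0)
        worst = int(np.argmin(importance))
        eliminated.append(names[remaining[worst]])
        remaining.pop(worst)
    model = _fit_base_model(x[:, remaining], y, seed)
    importance = np.linalg.norm(model.coef_, axis=0)
    order = np.argsort(-importance, kind="stable")
    kept = [names[remaining[i]] for i in order]
    return eliminated, kept


def recursive_feature_elimination(
    table: pd.DataFrame, k: int, seed: int = 0
) -> SelectionResult:
    """Select the k best features by recursive elimination.

    Ranks 1..k go to the kept features (ordered by final-model
    importance); eliminated features get ranks k+1, k+2, ... in reverse
    elimination order.
    """
    names = feature_columns(table)
    if k > len(names):
        raise SelectionError(f"k={k} exceeds the {len(names)} available features")
    if k < 1:
        raise SelectionError("k must be >= 1")
    x = _standardize(table[names].to_numpy(dtype=float))
    y = table["class"].to_numpy()

    eliminated, kept = _elimination_order(x, y, names, stop_at=k, seed=seed)
    ranking = {name: rank for rank, name in enumerate(kept, start=1)}
    for offset, name in enumerate(reversed(eliminated), start=1):
        ranking[name] = k + offset
    return SelectionResult(
        kept=kept, dropped_by_correlation=[], rfe_ranking=ranking, k=k
    )


def selection_sweep(
    table: pd.DataFrame,
    k_list: tuple[int, ...] = (10, 20, 30, 40),
    seed: int = 0,
    n_splits: int = 5,
) -> dict[int, float]:
    """Cross-validated base-model accuracy per candidate k.

    The greedy one-at-a-time elimination makes selections nested, so a
    single elimination pass serves every k in the list.
    """
    if not k_list:
        raise SelectionError("k_list must be nonempty")
    names = feature_columns(table)
    k_list = tuple(int(k) for k in k_list)
    if max(k_list) > len(names):
        raise SelectionError(
            f"max k={max(k_list)} exceeds the {len(names)} available features"
        )
    x = _standardize(table[names].to_numpy(dtype=float))
    y = table["class"].to_numpy()
    eliminated, kept_min = _elimination_order(
        x, y, names, stop_at=min(k_list), seed=seed
    )
    # survival order: first-eliminated last
    survival = kept_min + list(reversed(eliminated))

    scores: dict[int, float] = {}
    col_index = {n: i for i, n in enumerate(names)}
    cv = StratifiedKFold(n_splits=n_splits, shuffle=True, random_state=seed)
    for k in k_list:
        sel = [col_index[n] for n in survival[:k]]
        model = make_pipeline(
            StandardScaler(),
            LogisticRegression(C=1.0, max_iter=2000, random_state=seed),
        )
        scores[k] = float(
            np.mean(cross_val_score(model, x[:, sel], y, cv=cv, scoring="accuracy"))
        )
    return scores
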