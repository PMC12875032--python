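"""Boruta all-relevant feature selection around a random-forest classifier.

Each Boruta iteration doubles the design matrix with one independently
shuffled "shadow" copy of every real feature, trains a forest on the
doubled matrix, and scores a *hit* for every real feature whose impurity
importance strictly exceeds the maximum shadow importance.  After each
iteration, every still-undecided feature is tested against the null that
hits occur with probability 1/2: a two-sided binomial test, Bonferroni
corrected over the undecided features, confirms features with
significantly many hits and rejects those with significantly few.
Features never resolved within ``max_iter`` iterations stay tentative.

The classifiers mirror the published protocol: depth-5 forests, 5,000
trees for the stand-alone classifiers and the final re-ranking, 500
trees per Boruta iteration (the selection loop needs many fits, and the
hit statistic is insensitive to the tree count well below 5,000).
Importances are mean impurity decrease, deterministic given the seed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import binom
from sklearn.ensemble import RandomForestClassifier

__all__ = ["BorutaDecision", "train_forest", "boruta_select", "rerank_selected"]


@dataclass
class BorutaDecision:
    feature_id: str
    decision: str  # confirmed | rejected | tentative
    hits: int
    n_iter: int
    final_importance: float | None = None

    def __post_init__(self) -> None:
        if self.decision not in ("confirmed", "rejected", "tentative"):
            raise ValueError(f"bad decision {self.decision!r}")
        if not 0 <= self.hits <= self.n_iter:
            raise ValueError(f"{self.feature_id}: hits {self.hits} outside [0, {self.n_iter}]")


def _check_xy(X: np.ndarray, y: np.ndarray) -> None:
    if np.isnan(X).any():
        raise ValueError("X must not contain missing values")
    classes, counts = np.unique(y, return_counts=True)
    if classes.size < 2:
        raise ValueError("y must contain two classes")
    if counts.min() < 2:
        raise ValueError("each class needs >=2 samples")


def train_forest(
    X,
    y,
    n_trees: int = 5000,
    max_depth: int = 5,
    seed: int = 0,
) -> tuple[RandomForestClassifier, np.ndarray]:
    """Fit a depth-limited random forest; return it with impurity importances.

    Importances are non-negative and sum to 1 (up to floating error)
    whenever at least one split was made.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    _check_xy(X, y)
    clf = RandomForestClassifier(
        n_estimators=n_trees, max_depth=max_depth, random_state=seed, n_jobs=1
    )
    clf.fit(X, y)
    return clf, clf.feature_importances_.copy()


def _binom_two_sided(hits: int, n: int) -> float:
    # symmetric null (p = 1/2): two-sided p doubles the smaller tail
    lo = binom.cdf(hits, n, 0.5)
    hi = binom.sf(hits - 1, n, 0.5)
    return float(min(1.0, 2.0 * min(lo, hi)))


def boruta_select(
    X,
    y,
    feature_ids: list[str] | None = None,
    n_trees: int = 500,
    max_depth: int = 5,
    max_iter: int = 100,
    alpha: float = 0.05,
    seed: int = 0,
) -> list[BorutaDecision]:
    """Run Boruta shadow-feature selection; one decision per feature.

    Stops early once every feature is confirmed or rejected.
    """
    if max_iter < 5:
        raise ValueError("max_iter < 5 gives the binomial test no room to decide")
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    _check_xy(X, y)
    n_samples, n_feat = X.shape
    if feature_ids is None:
        feature_ids = [f"f{i}" for i in range(n_feat)]
    if len(feature_ids) != n_feat:
        raise ValueError("feature_ids length does not match X")

    rng = np.random.default_rng(seed)
    forest_seeds = rng.integers(0, 2**31 - 1, size=max_iter)
    hits = np.zeros(n_feat, dtype=int)
    decided = np.full(n_feat, "", dtype=object)
    it = 0
    for it in range(1, max_iter + 1):
        shadow = X.copy()
        for j in range(n_feat):
            rng.shuffle(shadow[:, j])
        doubled = np.hstack([X, shadow])
        clf = RandomForestClassifier(
            n_estimators=n_trees,
            max_depth=max_depth,
            random_state=int(forest_seeds[it - 1]),
            n_jobs=1,
        )
        clf.fit(doubled, y)
        imp = clf.feature_importances_
        shadow_max = imp[n_feat:].max()
        hits += (imp[:n_feat] > shadow_max).astype(int)

        undecided = np.flatnonzero(decided == "")
        if undecided.size == 0:
            break
        m = undecided.size
        for j in undecided:
            p = _binom_two_sided(int(hits[j]), it)
            if p * m < alpha:
                decided[j] = "confirmed" if hits[j] > it / 2 else "rejected"
        if (decided != "").all():
            break

    decisions = []
    for j, fid in enumerate(feature_ids):
        decisions.append(
            BorutaDecision(
                feature_id=fid,
                decision=decided[j] if decided[j] else "tentative",
                hits=int(hits[j]),
                n_iter=it,
            )
        )
    return decisions


def rerank_selected(
    X,
    y,
    confirmed_ids: list[str],
    feature_ids: list[str],
    n_trees: int = 5000,
    max_depth: int = 5,
    seed: int = 0,
) -> pd.DataFrame:
    """Re-rank confirmed features with a fresh (larger) forest.

    Returns a DataFrame (feature_id, importance) in descending importance
    order, ties broken by feature id.  Empty with a warning when nothing
    was confirmed.
    """
    if not confirmed_ids:
        warnings.warn("no confirmed features; returning empty ranking")
        return pd.DataFrame(columns=["feature_id", "importance"])
    idx = [feature_ids.index(fid) for fid in confirmed_ids]
    X = np.asarray(X, dtype=float)[:, idx]
    _, imp = train_forest(X, y, n_trees=n_trees, max_depth=max_depth, seed=seed)
    out = pd.DataFrame({"feature_id": confirmed_ids, "importance": imp})
    return out.sort_values(
        ["importance", "feature_id"], ascending=[False, True], kind="mergesort"
    ).reset_index(drop=True)
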