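"""Feature ranking and subset selection.

Three ranking criteria are implemented:

- **chi2**: each continuous feature is binarized at its global mean; the 2x2
  contingency of (binarized value x class) gives a 1-df chi-square statistic
  (no continuity correction) and p-value.
- **gbm**: impurity-based importances of a seeded gradient-boosted tree
  ensemble; the conventional cut keeps features with importance above the
  mean importance.
- **mrmd** (max-relevance-max-distance): |Pearson r(feature, label)| plus the
  mean pairwise distance from the feature column to all other columns
  (columns min-max scaled first); distance is Euclidean, cosine or Tanimoto.

Selection is either top-k or a p-value threshold (chi2 only).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from scipy.stats import chi2 as chi2_dist
from sklearn.ensemble import GradientBoostingClassifier


class SelectionError(ValueError):
    """Raised on degenerate inputs or invalid parameters."""


@dataclass
class RankedFeatureList:
    """Feature names ordered by decreasing score, with per-feature scores."""

    names: list[str]
    scores: np.ndarray
    method: str
    p_values: np.ndarray | None = None
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        if np.any(np.diff(self.scores) > 1e-12):
            raise SelectionError("scores must be non-increasing")
        if len(set(self.names)) != len(self.names):
            raise SelectionError("duplicate feature names in ranking")

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"name": self.names, "score": self.scores})
        if self.p_values is not None:
            df["p_value"] = self.p_values
        df["rank"] = np.arange(1, len(df) + 1)
        return df


def _check_xy(X: np.ndarray, y: np.ndarray, names: Sequence[str]) -> tuple[np.ndarray, np.ndarray]:
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    if X.shape[0] != y.shape[0]:
        raise SelectionError("X and y row counts differ")
    if X.shape[1] != len(names):
        raise SelectionError("column count does not match names")
    if len(np.unique(y)) < 2:
        raise SelectionError("labels are constant")
    return X, y


def _sort_desc(scores: np.ndarray) -> np.ndarray:
    # stable sort so ties keep original column order
    return np.argsort(-scores, kind="stable")


def chi2_statistic(a: int, b: int, c: int, d: int) -> float:
    """1-df chi-square for the 2x2 table [[a, b], [c, d]] via the closed form
    N (ad - bc)^2 / ((a+b)(c+d)(a+c)(b+d)); 0 when a margin is empty."""
    n = a + b + c + d
    denom = (a + b) * (c + d) * (a + c) * (b + d)
    if denom == 0:
        return 0.0
    return n * (a * d - b * c) ** 2 / denom


def chi2_rank(
    X: np.ndarray, y: np.ndarray, names: Sequence[str], binarize: str = "mean"
) -> RankedFeatureList:
    """Rank features by 2x2 chi-square association with the binary label.

    Continuous features are binarized at their global mean (``binarize='mean'``,
    default) or median.
    """
    X, y = _check_xy(X, y, names)
    if min(np.sum(y == 1), np.sum(y == 0)) < 2:
        raise SelectionError("need >=2 samples per class")
    if binarize == "mean":
        cut = X.mean(axis=0)
    elif binarize == "median":
        cut = np.median(X, axis=0)
    else:
        raise SelectionError(f"unknown binarization {binarize!r}")
    high = X > cut
    pos = y == 1
    stats = np.empty(X.shape[1])
    for j in range(X.shape[1]):
        a = int(np.sum(high[:, j] & pos))      # (pos, high)
        b = int(np.sum(~high[:, j] & pos))     # (pos, low)
        c = int(np.sum(high[:, j] & ~pos))     # (neg, high)
        d = int(np.sum(~high[:, j] & ~pos))    # (neg, low)
        stats[j] = chi2_statistic(a, b, c, d)
    pvals = chi2_dist.sf(stats, df=1)
    order = _sort_desc(stats)
    return RankedFeatureList(
        names=[names[i] for i in order],
        scores=stats[order],
        p_values=pvals[order],
        method="chi2",
        params={"binarize": binarize},
    )


def gbm_importance_rank(
    X: np.ndarray,
    y: np.ndarray,
    names: Sequence[str],
    seed: int = 0,
    n_estimators: int = 100,
    max_depth: int = 3,
) -> RankedFeatureList:
    """Rank features by gradient-boosted-tree importance.

    Fits a seeded :class:`~sklearn.ensemble.GradientBoostingClassifier` and
    ranks by its impurity-based importances; ``params['above_average']``
    lists the features whose importance exceeds the mean importance.
    """
    X, y = _check_xy(X, y, names)
    if min(np.sum(y == 1), np.sum(y == 0)) < 10:
        raise SelectionError("need >=10 samples per class for the tree ensemble")
    if np.all(X == X[0, :]):
        raise SelectionError("feature matrix is single-valued")
    model = GradientBoostingClassifier(
        n_estimators=n_estimators, max_depth=max_depth, random_state=seed
    )
    model.fit(X, y)
    imp = model.feature_importances_
    order = _sort_desc(imp)
    above = [names[i] for i in order if imp[i] > imp.mean()]
    return RankedFeatureList(
        names=[names[i] for i in order],
        scores=imp[order],
        method="gbm",
        params={"seed": seed, "n_estimators": n_estimators, "above_average": above},
    )


def _tanimoto_distance_matrix(cols: np.ndarray) -> np.ndarray:
    dots = cols @ cols.T
    norms = np.diag(dots)
    denom = norms[:, None] + norms[None, :] - dots
    with np.errstate(invalid="ignore", divide="ignore"):
        sim = np.where(denom > 0, dots / denom, 1.0)
    return 1.0 - sim


def mrmd_rank(
    X: np.ndarray, y: np.ndarray, names: Sequence[str], distance: str = "euclidean"
) -> RankedFeatureList:
    """Max-relevance-max-distance ranking.

    score_i = |Pearson r(feature_i, labels)| + mean_{j != i} dist(col_i, col_j),
    computed on min-max scaled columns; zero-variance features get relevance 0.
    """
    X, y = _check_xy(X, y, names)
    if X.shape[1] < 2:
        raise SelectionError("MRMD needs at least 2 features")
    span = X.max(axis=0) - X.min(axis=0)
    constant = span == 0
    scaled = np.where(constant, 0.0, (X - X.min(axis=0)) / np.where(constant, 1.0, span))

    yc = y - y.mean()
    sy = np.sqrt(np.sum(yc**2))
    xc = scaled - scaled.mean(axis=0)
    sx = np.sqrt(np.sum(xc**2, axis=0))
    with np.errstate(invalid="ignore", divide="ignore"):
        rel = np.abs(xc.T @ yc) / (sx * sy)
    rel = np.where((sx == 0) | (sy == 0), 0.0, rel)

    cols = scaled.T
    if distance == "euclidean":
        dmat = squareform(pdist(cols, metric="euclidean"))
    elif distance == "cosine":
        dmat = squareform(pdist(cols, metric="cosine"))
        dmat = np.nan_to_num(dmat, nan=0.0)
    elif distance == "tanimoto":
        dmat = _tanimoto_distance_matrix(cols)
    else:
        raise SelectionError(f"unknown distance {distance!r}")
    mean_dist = dmat.sum(axis=1) / (X.shape[1] - 1)

    score = rel + mean_dist
    order = _sort_desc(score)
    return RankedFeatureList(
        names=[names[i] for i in order],
        scores=score[order],
        method="mrmd",
        params={"distance": distance},
    )


def select_top(
    ranked: RankedFeatureList, k: int | None = None, p_threshold: float | None = None
) -> list[str]:
    """Retained column names: the top-k of the ranking, or (chi2) all features
    with p-value below ``p_threshold``.  Ties were already broken by original
    column order in the ranking."""
    if (k is None) == (p_threshold is None):
        raise SelectionError("specify exactly one of k or p_threshold")
    if k is not None:
        if k > len(ranked.names):
            raise SelectionError(f"k={k} exceeds {len(ranked.names)} ranked features")
        return ranked.names[:k]
    if ranked.p_values is None:
        raise SelectionError("p_threshold selection needs a ranking with p-values")
    return [n for n, p in zip(ranked.names, ranked.p_values) if p < p_threshold]
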