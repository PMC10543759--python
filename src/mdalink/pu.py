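"""Reliable-negative selection by positive-unlabeled (PU) learning.

Known associations form the positive set P; every other microbe-disease
pair is unlabeled (U).  The spy technique proceeds in three steps:

1. K-means clusters the positives; the positives closest to their own
   cluster centroid become spies S (a fraction t of P).  Central positives
   are chosen deliberately — a randomly drawn spy could be an outlier of P
   and would distort the score threshold.
2. A gradient-boosted tree ensemble (XGBoost) is fit with P - S as class 1
   and U + S as class 0, producing an association score A_x in [0, 1] for
   every pair.  Scores are computed out-of-fold: the pairs are split into
   score folds and each fold is scored by an ensemble fit on the others.
   Scoring pairs with a model that saw them in training would let the
   ensemble memorise the spies' provisional 0 labels, collapsing A_min to
   noise level and defeating the thresholding step; out-of-fold scores
   measure what the classifier believes about a pair, not what it was told.
3. A_min = min over spies of A; reliable negatives RN are the unlabeled
   pairs scoring strictly below A_min.

|RN| is data-driven (set by A_min), never forced to match |P|.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from sklearn.cluster import KMeans
from sklearn.model_selection import KFold
from xgboost import XGBClassifier

from .gate import PairDataset

__all__ = [
    "PUConfig",
    "PUResult",
    "select_spies",
    "score_all_pairs",
    "threshold_negatives",
    "run_pu",
]

logger = logging.getLogger(__name__)


@dataclass
class PUConfig:
    """Settings for spy selection and pair scoring.

    ``t_fraction`` is the fraction of P relabeled as spies (0.15 suits
    HMDAD-scale data; 0.20 suits larger Disbiome-scale data).
    """

    t_fraction: float = 0.15
    n_clusters: int = 5
    n_estimators: int = 100
    max_depth: int = 6
    learning_rate: float = 0.1
    n_score_folds: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.t_fraction < 1.0:
            raise ValueError("t_fraction must be in (0, 1)")
        if self.n_clusters < 1:
            raise ValueError("n_clusters must be >= 1")
        if self.n_score_folds < 2:
            raise ValueError("n_score_folds must be >= 2")


@dataclass
class PUResult:
    spies: np.ndarray       # dataset row indices moved P -> U
    scores: np.ndarray      # association score for every pair (dataset row)
    a_min: float            # minimum spy score
    reliable_negatives: np.ndarray  # dataset row indices, subset of U


def _positive_rows(dataset: PairDataset) -> np.ndarray:
    return np.flatnonzero(dataset.labels == 1)


def _unlabeled_rows(dataset: PairDataset) -> np.ndarray:
    return np.flatnonzero(dataset.labels == -1)


def select_spies(dataset: PairDataset, config: PUConfig) -> np.ndarray:
    """Spy set: the floor(t*|P|) positives (at least 1) closest to their own
    K-means centroid, ties broken toward the lower dataset row index."""
    pos = _positive_rows(dataset)
    if len(pos) < 2:
        raise ValueError("need at least 2 positives for spy selection")
    if len(pos) < config.n_clusters:
        raise ValueError(
            f"|P|={len(pos)} smaller than n_clusters={config.n_clusters}")
    Xp = dataset.X[pos]
    if not np.isfinite(Xp).all():
        raise ValueError("non-finite features among positives")
    km = KMeans(n_clusters=config.n_clusters, n_init=10,
                random_state=config.seed)
    assign = km.fit_predict(Xp)
    dist = np.linalg.norm(Xp - km.cluster_centers_[assign], axis=1)
    n_spies = max(1, int(np.floor(config.t_fraction * len(pos))))
    order = np.lexsort((pos, dist))  # distance asc, then row index asc
    return np.sort(pos[order[:n_spies]])


def _make_scorer(config: PUConfig) -> XGBClassifier:
    return XGBClassifier(
        n_estimators=config.n_estimators,
        max_depth=config.max_depth,
        learning_rate=config.learning_rate,
        tree_method="hist",
        n_jobs=1,
        random_state=config.seed,
        eval_metric="logloss",
    )


def score_all_pairs(dataset: PairDataset, spies: np.ndarray,
                    config: PUConfig) -> np.ndarray:
    """Class-1 probability for every pair, fit with P-S as positives and
    U+S as negatives, scored out-of-fold (see module docstring)."""
    pos = _positive_rows(dataset)
    unl = _unlabeled_rows(dataset)
    spies = np.asarray(spies, dtype=int)
    train_pos = np.setdiff1d(pos, spies)
    if len(train_pos) == 0:
        raise ValueError("t_fraction too large: no positives left after spies")
    train_neg = np.union1d(unl, spies)
    if len(train_neg) == 0:
        raise ValueError("no unlabeled pairs to score against")

    n = len(dataset.X)
    in_train = np.zeros(n, dtype=bool)
    in_train[train_pos] = True
    in_train[train_neg] = True
    y = np.zeros(n)
    y[train_pos] = 1.0

    scores = np.empty(n)
    kf = KFold(n_splits=min(config.n_score_folds, n), shuffle=True,
               random_state=config.seed)
    for fit_rows, score_rows in kf.split(dataset.X):
        fit_rows = fit_rows[in_train[fit_rows]]
        if len(np.unique(y[fit_rows])) < 2:
            raise ValueError("a score fold lost one class; reduce "
                             "n_score_folds")
        clf = _make_scorer(config)
        clf.fit(dataset.X[fit_rows], y[fit_rows])
        scores[score_rows] = clf.predict_proba(dataset.X[score_rows])[:, 1]
    return np.clip(scores.astype(float), 0.0, 1.0)


def threshold_negatives(scores: np.ndarray, spies: np.ndarray,
                        unlabeled: np.ndarray):
    """RN = unlabeled pairs with score strictly below the minimum spy score."""
    spies = np.asarray(spies, dtype=int)
    unlabeled = np.asarray(unlabeled, dtype=int)
    if len(spies) == 0:
        raise ValueError("spy set is empty")
    a_min = float(np.min(scores[spies]))
    rn = unlabeled[scores[unlabeled] < a_min]
    return np.sort(rn), a_min


def run_pu(dataset: PairDataset, config: PUConfig) -> PUResult:
    """Full spy pipeline: cluster, score, threshold."""
    unl = _unlabeled_rows(dataset)
    if len(unl) < 1:
        raise ValueError("need at least one unlabeled pair")
    spies = select_spies(dataset, config)
    scores = score_all_pairs(dataset, spies, config)
    rn, a_min = threshold_negatives(scores, spies, unl)
    logger.info("PU selection: |S|=%d, A_min=%.4f, |RN|=%d of |U|=%d",
                len(spies), a_min, len(rn), len(unl))
    return PUResult(spies=spies, scores=scores, a_min=a_min,
                    reliable_negatives=rn)
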