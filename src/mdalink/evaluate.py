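"""Cross-validation regimes, ranking metrics and the PU ablation.

Three five-fold schemes probe different generalisation questions:

* ``pair``     — hold out 20% of all microbe-disease pairs (the standard
                 link-prediction setting);
* ``disease``  — hold out whole diseases (cold start: can the model rank
                 microbes for a disease with no known links?);
* ``microbe``  — hold out whole microbes, analogously.

For every fold the held-out associations are zeroed in the training matrix
and everything downstream — kernel similarity, embeddings, PU selection,
the classifier — is recomputed from the masked matrix only, so no held-out
label can leak into training.  Held-out known associations are the test
positives; all other held-out pairs are test negatives.  AUC and AUPR
summarise each fold.
"""

from __future__ import annotations

import dataclasses
import difflib
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import average_precision_score, roc_auc_score

from .data_io import BipartiteAssociations
from .dnn import predict_scores
from .pipeline import (MDAPipeline, PipelineConfig, choose_negatives,
                       derive_seed, fit_pair_features, train_classifier)
from .pu import run_pu
from .similarity import SimilarityMatrix

__all__ = [
    "CVConfig",
    "CVResult",
    "AblationResult",
    "make_folds",
    "split_train_test",
    "compute_auc",
    "compute_aupr",
    "run_cv",
    "ablate_pu",
    "rank_candidates",
]

logger = logging.getLogger(__name__)

_SCHEMES = ("disease", "microbe", "pair")


@dataclass
class CVConfig:
    scheme: str = "pair"
    n_folds: int = 5
    repeats: int = 20
    seed: int = 0

    def __post_init__(self) -> None:
        if self.scheme not in _SCHEMES:
            raise ValueError(f"scheme must be one of {_SCHEMES}")
        if self.n_folds < 2:
            raise ValueError("n_folds must be >= 2")
        if self.repeats < 1:
            raise ValueError("repeats must be >= 1")


@dataclass
class CVResult:
    scheme: str
    aucs: np.ndarray   # (repeats, folds); NaN marks skipped folds
    auprs: np.ndarray
    config: CVConfig

    @property
    def mean_auc(self) -> float:
        return float(np.nanmean(self.aucs))

    @property
    def std_auc(self) -> float:
        return float(np.nanstd(self.aucs))

    @property
    def mean_aupr(self) -> float:
        return float(np.nanmean(self.auprs))

    @property
    def std_aupr(self) -> float:
        return float(np.nanstd(self.auprs))

    def summary(self) -> pd.DataFrame:
        reps, folds = np.where(~np.isnan(self.aucs))
        return pd.DataFrame({
            "repeat": reps, "fold": folds,
            "auc": self.aucs[reps, folds], "aupr": self.auprs[reps, folds],
        })


# ---------------------------------------------------------------------------
# folds and metrics


def make_folds(n_items: int, n_folds: int, seed: int) -> list[np.ndarray]:
    """Random partition into n_folds parts whose sizes differ by at most 1."""
    if n_items < n_folds:
        raise ValueError(f"cannot split {n_items} items into {n_folds} folds")
    rng = np.random.default_rng(seed)
    return list(np.array_split(rng.permutation(n_items), n_folds))


def split_train_test(Y: np.ndarray, scheme: str, test_items: np.ndarray):
    """Zero the held-out associations; return (Y_train, test row indices).

    Test rows are flat row-major pair indices (i*m + j).  For the disease
    and microbe schemes every pair touching a held-out entity is a test
    pair; for the pair scheme ``test_items`` already are flat pair indices.
    """
    Y = np.asarray(Y)
    n, m = Y.shape
    Y_train = Y.copy()
    test_items = np.asarray(test_items, dtype=int)
    if scheme == "disease":
        Y_train[test_items, :] = 0
        rows = (test_items[:, None] * m + np.arange(m)[None, :]).ravel()
    elif scheme == "microbe":
        Y_train[:, test_items] = 0
        rows = (np.arange(n)[:, None] * m + test_items[None, :]).ravel()
    elif scheme == "pair":
        Y_train.flat[test_items] = 0
        rows = np.sort(test_items)
    else:
        raise ValueError(f"scheme must be one of {_SCHEMES}")
    return Y_train, np.sort(rows)


def _check_two_classes(labels: np.ndarray) -> np.ndarray:
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("both classes required to compute a ranking metric")
    return labels


def compute_auc(scores, labels) -> float:
    """ROC AUC: the Mann-Whitney probability that a random positive
    outscores a random negative, ties counted half."""
    labels = _check_two_classes(labels)
    return float(roc_auc_score(labels, np.asarray(scores, dtype=float)))


def compute_aupr(scores, labels) -> float:
    """Area under the precision-recall curve (step interpolation over
    score-sorted thresholds, i.e. average precision)."""
    labels = _check_two_classes(labels)
    return float(average_precision_score(labels,
                                         np.asarray(scores, dtype=float)))


# ---------------------------------------------------------------------------
# cross-validation


def _fold_iterator(assoc: BipartiteAssociations, cv: CVConfig):
    n, m = assoc.Y.shape
    n_items = {"disease": n, "microbe": m, "pair": n * m}[cv.scheme]
    for rep in range(cv.repeats):
        folds = make_folds(n_items, cv.n_folds,
                           derive_seed(cv.seed, f"folds-rep{rep}"))
        for f, test_items in enumerate(folds):
            Y_train, test_rows = split_train_test(assoc.Y, cv.scheme,
                                                  test_items)
            yield rep, f, Y_train, test_rows


def _fold_pipeline_config(config: PipelineConfig, cv: CVConfig,
                          rep: int, fold: int) -> PipelineConfig:
    return dataclasses.replace(
        config, seed=derive_seed(config.seed, f"rep{rep}-fold{fold}"))


def run_cv(assoc: BipartiteAssociations, config: PipelineConfig,
           cv: CVConfig,
           functional_d: SimilarityMatrix | None = None,
           functional_m: SimilarityMatrix | None = None) -> CVResult:
    """Repeated k-fold CV with full per-fold retraining.

    Folds whose test set lacks positives (possible for cold-start schemes
    on sparse data) are skipped with a warning and recorded as NaN.
    """
    aucs = np.full((cv.repeats, cv.n_folds), np.nan)
    auprs = np.full((cv.repeats, cv.n_folds), np.nan)
    y_flat = assoc.Y.ravel()
    for rep, f, Y_train, test_rows in _fold_iterator(assoc, cv):
        test_labels = y_flat[test_rows]
        if test_labels.min() == test_labels.max():
            logger.warning("repeat %d fold %d: single-class test set, "
                           "skipping", rep, f)
            continue
        fold_cfg = _fold_pipeline_config(config, cv, rep, f)
        train_assoc = BipartiteAssociations(
            assoc.disease_names, assoc.microbe_names, Y_train)
        dataset, *_ = fit_pair_features(train_assoc, fold_cfg,
                                        functional_d, functional_m)
        pu_result = run_pu(dataset, fold_cfg.stage_config(fold_cfg.pu, "pu"))
        # held-out pairs never enter the negative training pool
        negatives = choose_negatives(dataset, pu_result, fold_cfg,
                                     exclude=test_rows)
        model, _ = train_classifier(dataset, negatives, fold_cfg)
        scores = predict_scores(model, dataset.X[test_rows])
        aucs[rep, f] = compute_auc(scores, test_labels)
        auprs[rep, f] = compute_aupr(scores, test_labels)
        logger.info("repeat %d fold %d: AUC=%.4f AUPR=%.4f",
                    rep, f, aucs[rep, f], auprs[rep, f])
    return CVResult(scheme=cv.scheme, aucs=aucs, auprs=auprs, config=cv)


@dataclass
class AblationResult:
    pu: CVResult
    random: CVResult
    rn_sizes: list[int]

    @property
    def mean_auc_delta(self) -> float:
        return self.pu.mean_auc - self.random.mean_auc


def ablate_pu(assoc: BipartiteAssociations, config: PipelineConfig,
              cv: CVConfig,
              functional_d: SimilarityMatrix | None = None,
              functional_m: SimilarityMatrix | None = None) -> AblationResult:
    """Identical CV protocol run twice per fold: Algorithm-1 reliable
    negatives vs. a uniform random unlabeled sample of the same size.
    Everything else (features, seeds, classifier) is shared, so the two
    arms differ only in the negative training set."""
    shape = (cv.repeats, cv.n_folds)
    res = {arm: (np.full(shape, np.nan), np.full(shape, np.nan))
           for arm in ("pu", "random")}
    rn_sizes: list[int] = []
    y_flat = assoc.Y.ravel()
    for rep, f, Y_train, test_rows in _fold_iterator(assoc, cv):
        test_labels = y_flat[test_rows]
        if test_labels.min() == test_labels.max():
            logger.warning("repeat %d fold %d: single-class test set, "
                           "skipping", rep, f)
            continue
        fold_cfg = _fold_pipeline_config(config, cv, rep, f)
        train_assoc = BipartiteAssociations(
            assoc.disease_names, assoc.microbe_names, Y_train)
        dataset, *_ = fit_pair_features(train_assoc, fold_cfg,
                                        functional_d, functional_m)
        pu_result = run_pu(dataset, fold_cfg.stage_config(fold_cfg.pu, "pu"))
        rn = choose_negatives(dataset, pu_result, fold_cfg,
                              exclude=test_rows)
        rn_sizes.append(len(rn))
        unl = np.setdiff1d(np.flatnonzero(dataset.labels == -1), test_rows)
        rng = np.random.default_rng(derive_seed(fold_cfg.seed, "ablation"))
        rand_neg = np.sort(rng.choice(unl, size=len(rn), replace=False))
        for arm, negatives in (("pu", rn), ("random", rand_neg)):
            model, _ = train_classifier(dataset, negatives, fold_cfg)
            scores = predict_scores(model, dataset.X[test_rows])
            res[arm][0][rep, f] = compute_auc(scores, test_labels)
            res[arm][1][rep, f] = compute_aupr(scores, test_labels)
    results = {arm: CVResult(scheme=cv.scheme, aucs=a, auprs=p, config=cv)
               for arm, (a, p) in res.items()}
    return AblationResult(pu=results["pu"], random=results["random"],
                          rn_sizes=rn_sizes)


# ---------------------------------------------------------------------------
# candidate ranking


def rank_candidates(pipeline: MDAPipeline, disease_name: str,
                    top_k: int = 30) -> pd.DataFrame:
    """Top-k microbes for one disease by predicted score.

    Known associations are flagged but kept at their predicted rank.  Ties
    break alphabetically.  An unknown disease raises with the nearest name
    matches listed.
    """
    pipeline._check_fitted()
    assoc = pipeline.assoc
    try:
        di = assoc.disease_index(disease_name)
    except KeyError:
        close = difflib.get_close_matches(disease_name, assoc.disease_names,
                                          n=3, cutoff=0.0)
        raise KeyError(f"unknown disease {disease_name!r}; closest names: "
                       f"{close}") from None
    scores = pipeline.score_matrix_.iloc[di]
    table = pd.DataFrame({
        "microbe": assoc.microbe_names,
        "score": scores.to_numpy(),
        "known": assoc.Y[di].astype(bool),
    })
    table["_key"] = table["microbe"].str.casefold()
    table = table.sort_values(["score", "_key"], ascending=[False, True])
    table = table.drop(columns="_key").head(top_k).reset_index(drop=True)
    table.insert(1, "rank", np.arange(1, len(table) + 1))
    return table
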