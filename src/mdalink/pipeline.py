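"""End-to-end orchestration: similarity -> embedding -> PU -> classifier.

The same fold-level building blocks serve both the fitted
:class:`MDAPipeline` (used for candidate ranking) and the cross-validation
harness in :mod:`mdalink.evaluate`.  All randomness flows from a single
master seed, fanned out per stage by name hashing, so one integer
reproduces a full run bit-for-bit.
"""

from __future__ import annotations

import dataclasses
import logging
import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data_io import BipartiteAssociations
from .dnn import DnnConfig, DnnModel, build_dnn, predict_scores, train_dnn
from .gate import (GateConfig, PairDataset, build_graph, make_pair_features,
                   train_gate)
from .pu import PUConfig, PUResult, run_pu
from .similarity import SimilarityMatrix, fuse_similarity, gapk_similarity

__all__ = [
    "PipelineConfig",
    "MDAPipeline",
    "derive_seed",
    "fit_pair_features",
    "choose_negatives",
    "train_classifier",
]

logger = logging.getLogger(__name__)


def derive_seed(master: int, stage: str) -> int:
    """Deterministic per-stage seed below 2^31 derived from the master seed."""
    return (zlib.crc32(stage.encode()) ^ (int(master) * 0x9E3779B1)) % (2 ** 31)


@dataclass
class PipelineConfig:
    """All stage settings plus the master seed.

    Defaults follow the reference protocol: 64-dimensional embeddings on
    each side (128-wide pair features), spy fraction 0.15, classifier
    128-100-100-50-1 with learning rate 0.001 and dropout 0.2.
    """

    k_neighbors: int = 10
    attributes: str = "profile"  # node attributes: association profile
    gate: GateConfig = field(default_factory=GateConfig)
    pu: PUConfig = field(default_factory=PUConfig)
    dnn: DnnConfig = field(default_factory=DnnConfig)
    seed: int = 0

    def stage_config(self, cfg, stage: str):
        """Copy of a sub-config with its seed derived from the master."""
        return dataclasses.replace(cfg, seed=derive_seed(self.seed, stage))


def _side_embeddings(Y: np.ndarray, side: str, names: list[str],
                     functional: SimilarityMatrix | None,
                     config: PipelineConfig):
    gapk = gapk_similarity(Y, side, names)
    fused = fuse_similarity(functional, gapk)
    X = np.asarray(Y, dtype=float) if side == "disease" \
        else np.asarray(Y, dtype=float).T
    if config.attributes == "similarity":
        X = fused.S
    elif config.attributes != "profile":
        raise ValueError("attributes must be 'profile' or 'similarity'")
    k = min(config.k_neighbors, fused.n - 1)
    graph = build_graph(fused, X, k)
    gate_cfg = config.stage_config(config.gate, f"gate-{side}")
    _, emb, _ = train_gate(graph, gate_cfg)
    return fused, emb


def fit_pair_features(assoc: BipartiteAssociations, config: PipelineConfig,
                      functional_d: SimilarityMatrix | None = None,
                      functional_m: SimilarityMatrix | None = None):
    """Similarities + embeddings + features for every pair.

    Returns ``(dataset, fused_d, fused_m, emb_d, emb_m)``.  Dataset rows are
    in row-major order (row i*m + j is pair (disease i, microbe j)) with
    label 1 for known associations and -1 (unlabeled) otherwise.
    """
    Y = assoc.Y
    fused_d, emb_d = _side_embeddings(Y, "disease", assoc.disease_names,
                                      functional_d, config)
    fused_m, emb_m = _side_embeddings(Y, "microbe", assoc.microbe_names,
                                      functional_m, config)
    n, m = Y.shape
    di, mj = np.divmod(np.arange(n * m), m)
    pairs = np.column_stack([di, mj])
    labels = np.where(Y.ravel() == 1, 1, -1)
    dataset = make_pair_features(emb_m, emb_d, pairs, labels)
    return dataset, fused_d, fused_m, emb_d, emb_m


def choose_negatives(dataset: PairDataset, pu_result: PUResult,
                     config: PipelineConfig,
                     exclude: np.ndarray | None = None) -> np.ndarray:
    """Training negatives: the reliable-negative set, or — if Algorithm-1
    thresholding returned none — a seeded uniform sample of |P| unlabeled
    pairs (logged).

    ``exclude`` removes rows (e.g. held-out test pairs during
    cross-validation) from the candidate pool: training a classifier on the
    very pairs it will be tested on — even with presumed-negative labels —
    lets it memorise the test set instead of generalising to it.
    """
    rn = pu_result.reliable_negatives
    if exclude is not None:
        rn = np.setdiff1d(rn, exclude)
    if len(rn) > 0:
        return rn
    logger.warning("empty reliable-negative set; falling back to a random "
                   "unlabeled sample")
    rng = np.random.default_rng(derive_seed(config.seed, "rn-fallback"))
    unl = np.flatnonzero(dataset.labels == -1)
    if exclude is not None:
        unl = np.setdiff1d(unl, exclude)
    n_pos = int((dataset.labels == 1).sum())
    return np.sort(rng.choice(unl, size=min(n_pos, len(unl)), replace=False))


def train_classifier(dataset: PairDataset, negative_rows: np.ndarray,
                     config: PipelineConfig) -> tuple[DnnModel, np.ndarray]:
    """Fit the DNN on known positives vs. the given negative rows; returns
    (model, loss trace).  The input layer is sized to the feature width."""
    pos = np.flatnonzero(dataset.labels == 1)
    a = dataset.feature_width
    dnn_cfg = config.stage_config(config.dnn, "dnn")
    dnn_cfg = dataclasses.replace(
        dnn_cfg, layer_sizes=(a,) + tuple(dnn_cfg.layer_sizes[1:]))
    model = build_dnn(dnn_cfg)
    idx = np.concatenate([pos, negative_rows])
    y = np.concatenate([np.ones(len(pos)), np.zeros(len(negative_rows))])
    losses = train_dnn(model, dataset.X[idx], y)
    return model, losses


class MDAPipeline:
    """Fitted end-to-end predictor over one association snapshot."""

    def __init__(self, config: PipelineConfig | None = None):
        self.config = config or PipelineConfig()
        self.assoc: BipartiteAssociations | None = None

    def fit(self, assoc: BipartiteAssociations,
            functional_d: SimilarityMatrix | None = None,
            functional_m: SimilarityMatrix | None = None) -> "MDAPipeline":
        self.assoc = assoc
        (self.dataset_, self.fused_d_, self.fused_m_,
         self.emb_d_, self.emb_m_) = fit_pair_features(
            assoc, self.config, functional_d, functional_m)
        pu_cfg = self.config.stage_config(self.config.pu, "pu")
        self.pu_result_ = run_pu(self.dataset_, pu_cfg)
        negatives = choose_negatives(self.dataset_, self.pu_result_,
                                     self.config)
        self.model_, self.losses_ = train_classifier(
            self.dataset_, negatives, self.config)
        scores = predict_scores(self.model_, self.dataset_.X)
        self.score_matrix_ = pd.DataFrame(
            scores.reshape(assoc.Y.shape),
            index=assoc.disease_names, columns=assoc.microbe_names)
        return self

    def _check_fitted(self) -> None:
        if self.assoc is None:
            raise RuntimeError("pipeline is not fitted")

    def predict_pairs(self, rows: np.ndarray) -> np.ndarray:
        """Scores for dataset rows (row-major pair indices)."""
        self._check_fitted()
        return self.score_matrix_.to_numpy().ravel()[np.asarray(rows)]

    def rank_candidates(self, disease_name: str, top_k: int = 30):
        from .evaluate import rank_candidates
        return rank_candidates(self, disease_name, top_k)
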