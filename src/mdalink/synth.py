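"""Synthetic bipartite association data with known latent structure.

Real microbe-disease association matrices are sparse (HMDAD-like data has
~4% density) and far from random: diseases sharing a mechanism recruit
overlapping microbe communities.  The generator emulates this with a
low-rank nonnegative factor model.  Each disease and microbe is assigned a
dominant latent block; the association propensity is the inner product of
the factor rows, and the binary matrix is obtained by thresholding the
propensities at the quantile matching the target density, optionally
followed by random entry flips (label noise).

A second generator plants a ground truth for the PU-learning stage:
pair features drawn from two Gaussians (true positives / true negatives)
separated by a configurable number of standard deviations, with only part
of the positives labeled, so reliable-negative recovery can be scored.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data_io import BipartiteAssociations
from .gate import PairDataset

__all__ = [
    "SyntheticSpec",
    "generate_associations",
    "generate_pu_ground_truth",
    "PUGroundTruth",
]


@dataclass
class SyntheticSpec:
    """Study conditions for the synthetic association matrix.

    Defaults emulate an HMDAD-scale snapshot: tens of diseases, a few
    hundred microbes, ~4% density, rank-4 block structure, no label noise.
    """

    n_diseases: int = 40
    n_microbes: int = 120
    latent_rank: int = 4
    target_density: float = 0.04
    noise_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.latent_rank > min(self.n_diseases, self.n_microbes):
            raise ValueError("latent_rank exceeds matrix dimensions")
        if not 0.0 < self.target_density < 1.0:
            raise ValueError("target_density must be in (0, 1)")
        if not 0.0 <= self.noise_rate < 1.0:
            raise ValueError("noise_rate must be in [0, 1)")
        if self.target_density * self.n_diseases * self.n_microbes < 10:
            raise ValueError("infeasible density: fewer than 10 expected "
                             "associations")


def generate_associations(spec: SyntheticSpec):
    """Draw Y from the low-rank block model.

    Returns ``(BipartiteAssociations, propensity)`` where ``propensity`` is
    the dense n x m latent score matrix the thresholding used — the ground
    truth for signal-recovery checks.  Deterministic per seed.
    """
    rng = np.random.default_rng(spec.seed)
    n, m, r = spec.n_diseases, spec.n_microbes, spec.latent_rank

    # dominant-block membership plus small dense background
    U = rng.gamma(shape=1.0, scale=0.15, size=(n, r))
    V = rng.gamma(shape=1.0, scale=0.15, size=(m, r))
    U[np.arange(n), rng.integers(0, r, n)] += rng.gamma(4.0, 0.5, n)
    V[np.arange(m), rng.integers(0, r, m)] += rng.gamma(4.0, 0.5, m)
    P = U @ V.T
    P = P / P.max()

    cutoff = np.quantile(P, 1.0 - spec.target_density)
    Y = (P > cutoff).astype(np.int8)

    if spec.noise_rate > 0.0:
        n_flip = int(round(spec.noise_rate * n * m))
        flat = rng.choice(n * m, size=n_flip, replace=False)
        Y.flat[flat] = 1 - Y.flat[flat]

    diseases = [f"disease_{i:03d}" for i in range(n)]
    microbes = [f"microbe_{j:04d}" for j in range(m)]
    return BipartiteAssociations(diseases, microbes, Y), P


@dataclass
class PUGroundTruth:
    """Pair features with hidden truth for scoring RN recovery.

    ``dataset.labels`` exposes only what the PU stage may see (1 = labeled
    positive, -1 = unlabeled); ``truth`` records the hidden class of every
    pair (1 = true positive, 0 = true negative).
    """

    dataset: PairDataset
    truth: np.ndarray

    @property
    def unlabeled(self) -> np.ndarray:
        return np.flatnonzero(self.dataset.labels == -1)

    def rn_precision(self, rn: np.ndarray) -> float:
        """Fraction of a reliable-negative set that is truly negative."""
        if len(rn) == 0:
            raise ValueError("empty reliable-negative set")
        return float((self.truth[rn] == 0).mean())

    @property
    def negative_prevalence_in_unlabeled(self) -> float:
        unl = self.unlabeled
        return float((self.truth[unl] == 0).mean())


def generate_pu_ground_truth(n_pairs: int = 300,
                             positive_fraction: float = 0.4,
                             labeled_fraction: float = 0.5,
                             separation: float = 4.0,
                             dim: int = 16,
                             seed: int = 0) -> PUGroundTruth:
    """Two-Gaussian pair features with partially labeled positives.

    The classes differ only in the first coordinate: true positives are
    centred at +separation/2 and true negatives at -separation/2 with unit
    spread, so ``separation`` is the class-mean gap in units of sigma; the
    remaining coordinates are pure noise.  A ``labeled_fraction`` of the
    positives keeps label 1; everything else is unlabeled, which plants
    hidden positives inside U alongside the true negatives.
    """
    if n_pairs < 10:
        raise ValueError("n_pairs too small")
    rng = np.random.default_rng(seed)
    n_pos = int(round(positive_fraction * n_pairs))
    n_neg = n_pairs - n_pos
    X = rng.normal(size=(n_pairs, dim))
    X[:n_pos, 0] += separation / 2.0
    X[n_pos:, 0] -= separation / 2.0
    truth = np.concatenate([np.ones(n_pos, dtype=int),
                            np.zeros(n_neg, dtype=int)])

    labels = np.full(n_pairs, -1, dtype=int)
    n_labeled = max(2, int(round(labeled_fraction * n_pos)))
    labeled = rng.choice(n_pos, size=n_labeled, replace=False)
    labels[labeled] = 1

    perm = rng.permutation(n_pairs)
    X, truth, labels = X[perm], truth[perm], labels[perm]
    pairs = np.column_stack([np.zeros(n_pairs, dtype=int),
                             np.arange(n_pairs)])
    dataset = PairDataset(pairs=pairs, X=X, labels=labels)
    return PUGroundTruth(dataset=dataset, truth=truth)
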