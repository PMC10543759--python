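"""Gaussian association-profile kernel (GAPK) similarity and fusion.

Each disease is represented by its row of the binary association matrix Y
(its association profile), each microbe by its column.  GAPK similarity is a
radial-basis kernel between profiles,

    G_ij = exp(-theta * ||V_i - V_j||^2),

with the bandwidth normalised by the mean squared profile norm,

    theta = n / sum_i ||V_i||^2,

so that the kernel scale adapts to the sparsity of the network.  The fused
similarity averages GAPK with an optional externally supplied functional
similarity wherever the latter is non-zero, and falls back to GAPK alone
elsewhere (structural zeros in functional matrices mean "unknown", not
"dissimilar").
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "SimilarityMatrix",
    "gapk_bandwidth",
    "gapk_similarity",
    "fuse_similarity",
]

_SIDES = ("disease", "microbe")
_KINDS = ("functional", "gapk", "fused")


@dataclass
class SimilarityMatrix:
    """Square symmetric similarity matrix in [0, 1], tagged by side and kind."""

    names: list[str]
    S: np.ndarray
    side: str
    kind: str

    def __post_init__(self) -> None:
        if self.side not in _SIDES:
            raise ValueError(f"side must be one of {_SIDES}")
        if self.kind not in _KINDS:
            raise ValueError(f"kind must be one of {_KINDS}")
        S = np.asarray(self.S, dtype=float)
        if S.ndim != 2 or S.shape[0] != S.shape[1]:
            raise ValueError("similarity matrix must be square")
        if S.shape[0] != len(self.names):
            raise ValueError("names do not match matrix shape")
        if not np.allclose(S, S.T, atol=1e-10):
            raise ValueError("similarity matrix must be symmetric")
        if S.min() < -1e-12 or S.max() > 1 + 1e-12:
            raise ValueError("similarity entries must lie in [0, 1]")
        if self.kind in ("gapk", "fused") and not np.allclose(np.diag(S), 1.0):
            raise ValueError(f"{self.kind} similarity must have unit diagonal")
        self.S = np.clip(S, 0.0, 1.0)

    @property
    def n(self) -> int:
        return self.S.shape[0]


def _profiles(Y: np.ndarray, side: str) -> np.ndarray:
    Y = np.asarray(Y, dtype=float)
    if side == "disease":
        return Y
    if side == "microbe":
        return Y.T
    raise ValueError(f"side must be one of {_SIDES}")


def gapk_bandwidth(Y: np.ndarray, side: str) -> float:
    """Kernel bandwidth theta = n / sum_i ||V_i||^2 over the side's profiles."""
    V = _profiles(Y, side)
    total = float((V ** 2).sum())
    if total == 0.0:
        raise ValueError("bandwidth undefined: all profiles are zero")
    return V.shape[0] / total


def gapk_similarity(Y: np.ndarray, side: str,
                    names: list[str] | None = None) -> SimilarityMatrix:
    """GAPK similarity between all profile pairs of one side."""
    V = _profiles(Y, side)
    theta = gapk_bandwidth(Y, side)
    sq = (V ** 2).sum(axis=1)
    d2 = sq[:, None] + sq[None, :] - 2.0 * (V @ V.T)
    np.maximum(d2, 0.0, out=d2)  # clamp tiny negative rounding
    G = np.exp(-theta * d2)
    G = (G + G.T) / 2.0
    np.fill_diagonal(G, 1.0)
    if names is None:
        prefix = "d" if side == "disease" else "m"
        names = [f"{prefix}{i}" for i in range(V.shape[0])]
    return SimilarityMatrix(list(names), G, side, "gapk")


def fuse_similarity(functional: SimilarityMatrix | None,
                    gapk: SimilarityMatrix) -> SimilarityMatrix:
    """Average functional and GAPK similarity where functional is non-zero,
    GAPK alone elsewhere; with no functional input the fusion is GAPK exactly.
    The diagonal is forced to 1."""
    if gapk.kind != "gapk":
        raise ValueError("second argument must be a gapk SimilarityMatrix")
    if functional is None:
        S = gapk.S.copy()
    else:
        if functional.side != gapk.side:
            raise ValueError("side mismatch between functional and gapk")
        if list(functional.names) != list(gapk.names):
            raise ValueError("name order mismatch between functional and gapk")
        F = functional.S
        # exact-zero test: structural zeros delegate to GAPK
        S = np.where(F != 0.0, (F + gapk.S) / 2.0, gapk.S)
    S = (S + S.T) / 2.0
    np.fill_diagonal(S, 1.0)
    return SimilarityMatrix(list(gapk.names), S, gapk.side, "fused")
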