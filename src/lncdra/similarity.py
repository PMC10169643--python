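"""Gaussian interaction-profile (GIP) kernel similarity.

Each lncRNA's interaction profile is its row of the binary association
matrix A (each drug's, its column).  Similarity between two nodes is
``exp(-alpha * ||profile_i - profile_j||^2)`` where the bandwidth alpha is
one over the mean squared profile norm on that side — the convention used
throughout the GIP-kernel association-prediction literature.  Because
profiles are recomputed from whatever matrix is passed in, cross-validation
recomputes similarity from the training fold's matrix (test positives
zeroed) so no label information leaks through the kernel.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, TextIO

import numpy as np
from scipy.spatial.distance import squareform, pdist

from .data_io import AssociationMatrix
from .errors import ContractError, DegenerateInputError

__all__ = ["SimilarityMatrix", "bandwidth", "gip_similarity", "export_similarity"]

Side = Literal["lncrna", "drug"]


@dataclass(frozen=True)
class SimilarityMatrix:
    """Square symmetric GIP-kernel similarity matrix for one node set."""

    G: np.ndarray
    bandwidth: float
    side: Side
    ids: tuple[str, ...]

    def __post_init__(self):
        G = self.G
        if G.ndim != 2 or G.shape[0] != G.shape[1]:
            raise ContractError("similarity matrix must be square")
        if not np.allclose(G, G.T, atol=1e-12):
            raise ContractError("similarity matrix must be symmetric")

    @property
    def k(self) -> int:
        return self.G.shape[0]


def _profiles(matrix: AssociationMatrix, side: Side) -> np.ndarray:
    if side == "lncrna":
        return matrix.A
    if side == "drug":
        return matrix.A.T
    raise ContractError(f"unknown side {side!r}")


def bandwidth(matrix: AssociationMatrix, side: Side) -> float:
    """GIP bandwidth: 1 / mean squared profile norm on the chosen side.

    Raises :class:`DegenerateInputError` on an all-zero matrix, where the
    mean squared norm vanishes.
    """
    P = _profiles(matrix, side)
    mean_sq = float(np.mean(np.sum(P * P, axis=1)))
    if mean_sq == 0.0:
        raise DegenerateInputError(
            "all-zero association matrix: GIP bandwidth undefined")
    return 1.0 / mean_sq


def gip_similarity(matrix: AssociationMatrix, side: Side) -> SimilarityMatrix:
    """Pairwise GIP-kernel similarity between profiles on one side."""
    alpha = bandwidth(matrix, side)
    P = _profiles(matrix, side)
    if P.shape[0] == 1:
        sq = np.zeros((1, 1))
    else:
        sq = squareform(pdist(P, metric="sqeuclidean"))
    G = np.exp(-alpha * sq)
    # exact symmetry and unit diagonal regardless of fp round-off
    G = (G + G.T) / 2.0
    np.fill_diagonal(G, 1.0)
    ids = matrix.lnc_ids if side == "lncrna" else matrix.drug_ids
    return SimilarityMatrix(G=G, bandwidth=alpha, side=side, ids=tuple(ids))


def export_similarity(sim: SimilarityMatrix, sink: TextIO,
                      delimiter: str = "\t") -> None:
    """Write the similarity matrix with id headers for inspection."""
    sink.write(delimiter.join(["id", *sim.ids]) + "\n")
    for i, name in enumerate(sim.ids):
        row = delimiter.join(f"{v:.10g}" for v in sim.G[i])
        sink.write(f"{name}{delimiter}{row}\n")
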