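"""Planted-block synthetic association matrices.

The real association data (a few thousand lncRNAs by tens of drugs, a few
thousand known pairs) is not redistributable, so tests and examples run on
a planted stochastic block model instead: rows and columns are partitioned
into contiguous blocks of near-equal size, and a pair is associated with
probability ``p_in`` when row and column share a block index and ``p_out``
otherwise.  With ``p_in >> p_out`` the matrix has recoverable low-rank
community structure, so held-out link recovery is measurable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data_io import AssociationMatrix
from .errors import MaskError, ContractError

__all__ = ["SyntheticSpec", "generate_block_association", "mask_edges"]


@dataclass(frozen=True)
class SyntheticSpec:
    m: int = 100
    n: int = 20
    blocks: int = 4
    p_in: float = 0.5
    p_out: float = 0.02
    seed: int = 0

    def __post_init__(self):
        if self.m < 1 or self.n < 1:
            raise ContractError("m and n must be >= 1")
        if not (0 <= self.p_out < self.p_in <= 1):
            raise ContractError("need 0 <= p_out < p_in <= 1")
        if not (1 <= self.blocks <= min(self.m, self.n)):
            raise ContractError("need 1 <= blocks <= min(m, n)")


def block_labels(count: int, blocks: int) -> np.ndarray:
    """Contiguous near-equal blocks; the remainder goes to the last block."""
    base = count // blocks
    labels = np.repeat(np.arange(blocks), base)
    return np.r_[labels, np.full(count - len(labels), blocks - 1)]


def generate_block_association(spec: SyntheticSpec) -> AssociationMatrix:
    """Draw a binary bipartite matrix from the planted block model.

    Redraws (with fresh randomness from the same stream) until at least one
    positive exists, so downstream components never see an all-zero matrix.
    """
    rng = np.random.default_rng(spec.seed)
    row_blk = block_labels(spec.m, spec.blocks)
    col_blk = block_labels(spec.n, spec.blocks)
    same = row_blk[:, None] == col_blk[None, :]
    prob = np.where(same, spec.p_in, spec.p_out)
    while True:
        A = (rng.random((spec.m, spec.n)) < prob).astype(float)
        if A.sum() >= 1:
            break
    lnc_ids = [f"L{i:04d}" for i in range(spec.m)]
    drug_ids = [f"D{j:03d}" for j in range(spec.n)]
    return AssociationMatrix(A, lnc_ids, drug_ids)


def mask_edges(matrix: AssociationMatrix, fraction: float,
               seed: int = 0) -> tuple[AssociationMatrix, set[tuple[int, int]]]:
    """Hold out ceil(fraction * positives) positive entries.

    Returns the training matrix (held-out entries zeroed) and the held-out
    index set.
    """
    if not (0.0 < fraction < 1.0):
        raise MaskError("fraction must lie strictly between 0 and 1")
    positives = matrix.positives()
    n_hold = int(np.ceil(fraction * len(positives)))
    if n_hold < 1 or n_hold >= len(positives):
        raise MaskError(
            f"cannot hold out {n_hold} of {len(positives)} positives")
    rng = np.random.default_rng(seed)
    chosen = rng.choice(len(positives), size=n_hold, replace=False)
    held_out = {positives[i] for i in chosen}
    training = matrix.copy()
    for i, j in held_out:
        training.A[i, j] = 0.0
    return training, held_out
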