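"""The encoder-decoder: normalized-adjacency GCN, multi-head GAT, and the
sigmoid inner-product scorer.

Both node sets get the same pipeline, instantiated separately: the GIP
similarity matrix G defines a dense weighted graph; node features are the
rows of G themselves; a two-layer GCN over the symmetric-normalized
adjacency ``D^{-1/2}(G+I)D^{-1/2}`` extracts initial features; one or more
multi-head graph-attention layers (concat fusion on hidden layers, head
averaging on the last) produce the final embeddings; and candidate
associations are scored as the logistic of the embedding inner product.

Every operation exists in two coupled forms: a tape-based tensor route used
for training, and thin numpy wrappers (the public functions below) that run
the same code and return plain arrays.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Sequence, TextIO

import numpy as np

from .autodiff import Tensor, concat
from .config import TrainConfig
from .data_io import AssociationMatrix
from .errors import CheckpointError, ConfigError, ContractError
from .similarity import SimilarityMatrix, gip_similarity

__all__ = [
    "NormalizedAdjacency", "GCNParams", "GATLayerParams", "AttentionMap",
    "ModelParams", "normalize_adjacency", "neighborhood_mask", "gcn_encode",
    "attention_logits", "attention_normalize", "gat_layer", "init_params",
    "encode", "score", "save_checkpoint", "load_checkpoint",
]


# ---------------------------------------------------------------------------
# parameter containers

@dataclass
class NormalizedAdjacency:
    """Message-passing operator D^{-1/2}(G+I)D^{-1/2} with self-loops."""

    A_hat: np.ndarray
    self_loop_added: bool = True


@dataclass
class GCNParams:
    """Two-layer GCN weights for one side."""

    W0: Tensor
    W1: Tensor
    activation_out: str = "row_softmax"

    @property
    def tensors(self) -> list[Tensor]:
        return [self.W0, self.W1]


@dataclass
class GATLayerParams:
    """One multi-head attention layer: per-head projection and attention vector."""

    W: list[Tensor]          # K matrices, r_in x c
    a: list[Tensor]          # K vectors, length 2c
    fusion: str = "average"  # 'concat' on hidden layers, 'average' on the last
    leaky_slope: float = 0.2

    @property
    def K(self) -> int:
        return len(self.W)

    @property
    def c(self) -> int:
        return self.W[0].shape[1]

    @property
    def tensors(self) -> list[Tensor]:
        return [*self.W, *self.a]


@dataclass
class AttentionMap:
    """Normalized attention coefficients for one head, with its mask."""

    alpha: np.ndarray
    neighborhood: np.ndarray


@dataclass
class SideParams:
    """All parameters of one side's (lncRNA or drug) encoder."""

    gcn: GCNParams | None
    projection: Tensor | None  # gcn_only: linear map r -> c
    gat_layers: list[GATLayerParams] = field(default_factory=list)

    @property
    def tensors(self) -> list[Tensor]:
        out: list[Tensor] = []
        if self.gcn is not None:
            out.extend(self.gcn.tensors)
        if self.projection is not None:
            out.append(self.projection)
        for layer in self.gat_layers:
            out.extend(layer.tensors)
        return out


@dataclass
class ModelParams:
    lnc: SideParams
    drug: SideParams
    m: int
    n: int

    @property
    def tensors(self) -> list[Tensor]:
        return self.lnc.tensors + self.drug.tensors


# ---------------------------------------------------------------------------
# graph operators

def normalize_adjacency(G: SimilarityMatrix | np.ndarray) -> NormalizedAdjacency:
    """Symmetric normalization with self-loops: D^{-1/2}(G+I)D^{-1/2}."""
    Gm = G.G if isinstance(G, SimilarityMatrix) else np.asarray(G, dtype=float)
    if Gm.ndim != 2 or Gm.shape[0] != Gm.shape[1]:
        raise ContractError("similarity matrix must be square")
    if not np.allclose(Gm, Gm.T, atol=1e-10):
        raise ContractError("similarity matrix must be symmetric")
    if (Gm < 0).any():
        raise ContractError("similarity matrix must be nonnegative")
    A_tilde = Gm + np.eye(Gm.shape[0])
    d = A_tilde.sum(axis=1)
    inv_sqrt = 1.0 / np.sqrt(d)
    A_hat = A_tilde * inv_sqrt[:, None] * inv_sqrt[None, :]
    return NormalizedAdjacency(A_hat=A_hat, self_loop_added=True)


def neighborhood_mask(G: SimilarityMatrix | np.ndarray,
                      knn: int | None = None) -> np.ndarray:
    """Boolean attention neighborhoods from the similarity graph.

    Default is the full graph (every node attends to every node, self
    included).  With ``knn``, each node keeps its ``knn`` most-similar
    neighbors (ties broken by smaller index) plus itself.
    """
    Gm = G.G if isinstance(G, SimilarityMatrix) else np.asarray(G, dtype=float)
    k = Gm.shape[0]
    if knn is None:
        return np.ones((k, k), dtype=bool)
    mask = np.zeros((k, k), dtype=bool)
    for i in range(k):
        order = np.lexsort((np.arange(k), -Gm[i]))
        mask[i, order[: min(knn, k)]] = True
        mask[i, i] = True
    return mask


def _gcn_encode_t(X: Tensor, A_hat: np.ndarray, params: GCNParams) -> Tensor:
    A = Tensor(A_hat)
    H = (A @ X @ params.W0).relu()
    Z = A @ H @ params.W1
    if params.activation_out == "row_softmax":
        return Z.row_softmax()
    if params.activation_out == "relu":
        return Z.relu()
    if params.activation_out == "identity":
        return Z
    raise ConfigError(f"unknown activation_out {params.activation_out!r}")


def gcn_encode(X: np.ndarray, A_hat: NormalizedAdjacency,
               params: GCNParams) -> np.ndarray:
    """Two-layer GCN: activation_out(A_hat . ReLU(A_hat . X . W0) . W1)."""
    X = np.asarray(X, dtype=float)
    if X.shape[1] != params.W0.shape[0]:
        raise ContractError(
            f"feature width {X.shape[1]} != W0 input dim {params.W0.shape[0]}")
    out = _gcn_encode_t(Tensor(X), A_hat.A_hat, params)
    if not np.isfinite(out.data).all():
        raise ContractError("non-finite values in GCN output")
    return out.data


def _head_logits_t(X: Tensor, W: Tensor, a: Tensor, slope: float) -> Tensor:
    """e_ij = LeakyReLU(a^T [W x_i || W x_j]) for all pairs, via the split
    a = [a_src; a_dst]: e_ij = LeakyReLU(s_i + t_j)."""
    H = X @ W
    c = W.shape[1]
    s = (H @ a[:c].reshape((c, 1)))        # k x 1
    t = (H @ a[c:].reshape((c, 1)))        # k x 1
    return (s + t.T).leaky_relu(slope)


def attention_logits(X: np.ndarray, params: GATLayerParams,
                     head: int = 0) -> np.ndarray:
    """Raw pre-softmax attention logits of one head."""
    if not (0 <= head < params.K):
        raise ContractError(f"head {head} out of range for K={params.K}")
    X = np.asarray(X, dtype=float)
    if X.shape[1] != params.W[head].shape[0]:
        raise ContractError("feature width does not match head projection")
    return _head_logits_t(Tensor(X), params.W[head], params.a[head],
                          params.leaky_slope).data


def attention_normalize(logits: np.ndarray,
                        neighborhood: np.ndarray) -> AttentionMap:
    """Masked, max-stabilized softmax of logits over each neighborhood."""
    logits = np.asarray(logits, dtype=float)
    neighborhood = np.asarray(neighborhood, dtype=bool)
    if logits.shape != neighborhood.shape:
        raise ContractError("logits and neighborhood shapes differ")
    if not neighborhood.any(axis=1).all():
        raise ContractError("a node has an empty attention neighborhood")
    alpha = Tensor(logits).row_softmax(neighborhood).data
    return AttentionMap(alpha=alpha, neighborhood=neighborhood)


def _gat_layer_t(X: Tensor, params: GATLayerParams, mask: np.ndarray,
                 attention_sink: list | None = None) -> Tensor:
    per_head = []
    for W, a in zip(params.W, params.a):
        H = X @ W
        e = _head_logits_t(X, W, a, params.leaky_slope)
        alpha = e.row_softmax(mask)
        if attention_sink is not None:
            attention_sink.append(alpha.data)
        per_head.append(alpha @ H)
    if params.fusion == "concat":
        return concat([h.elu() for h in per_head], axis=1)
    if params.fusion == "average":
        total = per_head[0]
        for h in per_head[1:]:
            total = total + h
        return (total / params.K).elu()
    raise ConfigError(f"unknown fusion {params.fusion!r}")


def gat_layer(X: np.ndarray, G: SimilarityMatrix | np.ndarray,
              params: GATLayerParams, knn: int | None = None) -> np.ndarray:
    """One multi-head attention layer over the similarity graph.

    Concat fusion applies the node activation per head and concatenates
    (output width K*c); average fusion averages head aggregates before the
    activation (output width c).
    """
    mask = neighborhood_mask(G, knn)
    return _gat_layer_t(Tensor(np.asarray(X, dtype=float)), params, mask).data


# ---------------------------------------------------------------------------
# parameter initialization

def _glorot(rng: np.random.Generator, shape: tuple[int, ...]) -> Tensor:
    fan_in, fan_out = (shape if len(shape) == 2 else (shape[0], 1))
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return Tensor(rng.uniform(-limit, limit, size=shape), requires_grad=True)


def _gat_stack_widths(config: TrainConfig, input_dim: int) -> list[tuple[int, int, str]]:
    """(input_dim, per-head width c, fusion) for each GAT layer."""
    n_layers = config.n_gat_layers
    widths = []
    cur = input_dim
    for li in range(n_layers):
        last = li == n_layers - 1
        if last:
            widths.append((cur, config.embedding_size, "average"))
            cur = config.embedding_size
        else:
            c = config.embedding_size // config.heads
            widths.append((cur, c, "concat"))
            cur = c * config.heads
    return widths


def _init_side(rng: np.random.Generator, k: int,
               config: TrainConfig) -> SideParams:
    r = config.gcn_hidden
    gcn = None
    projection = None
    gat_layers: list[GATLayerParams] = []

    if config.variant in ("full", "gcn_only"):
        gcn = GCNParams(W0=_glorot(rng, (k, r)), W1=_glorot(rng, (r, r)),
                        activation_out=config.activation_out)
    if config.variant == "gcn_only" or (config.variant == "full"
                                        and config.n_gat_layers == 0):
        projection = _glorot(rng, (r, config.embedding_size))
    if config.variant in ("full", "gat_only") and config.n_gat_layers > 0:
        gat_input = r if config.variant == "full" else k
        for d_in, c, fusion in _gat_stack_widths(config, gat_input):
            W = [_glorot(rng, (d_in, c)) for _ in range(config.heads)]
            a = [_glorot(rng, (2 * c,)) for _ in range(config.heads)]
            gat_layers.append(GATLayerParams(W=W, a=a, fusion=fusion,
                                             leaky_slope=config.leaky_slope))
    return SideParams(gcn=gcn, projection=projection, gat_layers=gat_layers)


def init_params(m: int, n: int, config: TrainConfig,
                rng: np.random.Generator | None = None) -> ModelParams:
    """Glorot-uniform initialization of all encoder parameters from the seed."""
    if config.variant == "gat_only" and config.n_gat_layers < 1:
        raise ConfigError("variant=gat_only requires layers >= 3")
    if rng is None:
        rng = np.random.default_rng(config.seed)
    return ModelParams(lnc=_init_side(rng, m, config),
                       drug=_init_side(rng, n, config), m=m, n=n)


# ---------------------------------------------------------------------------
# full encoder and decoder

def _dropout_t(X: Tensor, p: float, rng: np.random.Generator | None) -> Tensor:
    if p <= 0.0 or rng is None:
        return X
    keep = (rng.random(X.shape) >= p) / (1.0 - p)
    return X * Tensor(keep)


def _encode_side_t(G: SimilarityMatrix, side_params: SideParams,
                   config: TrainConfig, rng: np.random.Generator | None = None,
                   attention_sink: list | None = None) -> Tensor:
    X = Tensor(G.G)
    mask = neighborhood_mask(G, config.knn)
    H = X
    if side_params.gcn is not None:
        A_hat = normalize_adjacency(G).A_hat
        H = _gcn_encode_t(H, A_hat, side_params.gcn)
        H = _dropout_t(H, config.dropout, rng)
    if side_params.projection is not None:
        return H @ side_params.projection
    for li, layer in enumerate(side_params.gat_layers):
        if li > 0:
            H = _dropout_t(H, config.dropout, rng)
        H = _gat_layer_t(H, layer, mask, attention_sink)
    return H


def _encode_t(matrix: AssociationMatrix, config: TrainConfig,
              params: ModelParams, rng: np.random.Generator | None = None,
              attention_sink: list | None = None) -> tuple[Tensor, Tensor]:
    if (params.m, params.n) != (matrix.m, matrix.n):
        raise ContractError(
            f"parameters built for {params.m}x{params.n}, "
            f"matrix is {matrix.m}x{matrix.n}")
    Gl = gip_similarity(matrix, "lncrna")
    Gd = gip_similarity(matrix, "drug")
    Xl = _encode_side_t(Gl, params.lnc, config, rng, attention_sink)
    Xd = _encode_side_t(Gd, params.drug, config, rng, attention_sink)
    return Xl, Xd


def encode(matrix: AssociationMatrix, config: TrainConfig,
           params: ModelParams) -> tuple[np.ndarray, np.ndarray]:
    """Embed both node sets; returns (m x c lncRNA, n x c drug) arrays."""
    Xl, Xd = _encode_t(matrix, config, params)
    return Xl.data, Xd.data


def _score_t(Xl: Tensor, Xd: Tensor) -> Tensor:
    return (Xl @ Xd.T).sigmoid()


def score(lnc_emb: np.ndarray, drug_emb: np.ndarray) -> np.ndarray:
    """Sigmoid inner-product decoder: A'_ij = logistic(x_i . y_j)."""
    lnc_emb = np.asarray(lnc_emb, dtype=float)
    drug_emb = np.asarray(drug_emb, dtype=float)
    if lnc_emb.shape[1] != drug_emb.shape[1]:
        raise ContractError(
            f"embedding widths differ: {lnc_emb.shape[1]} vs {drug_emb.shape[1]}")
    return _score_t(Tensor(lnc_emb), Tensor(drug_emb)).data


# ---------------------------------------------------------------------------
# checkpointing

def _side_to_jsonable(side: SideParams) -> dict:
    out: dict = {"gat_layers": []}
    if side.gcn is not None:
        out["gcn"] = {"W0": side.gcn.W0.data.tolist(),
                      "W1": side.gcn.W1.data.tolist(),
                      "activation_out": side.gcn.activation_out}
    if side.projection is not None:
        out["projection"] = side.projection.data.tolist()
    for layer in side.gat_layers:
        out["gat_layers"].append({
            "W": [w.data.tolist() for w in layer.W],
            "a": [a.data.tolist() for a in layer.a],
            "fusion": layer.fusion,
            "leaky_slope": layer.leaky_slope,
        })
    return out


def _side_from_jsonable(obj: dict) -> SideParams:
    gcn = None
    if "gcn" in obj:
        gcn = GCNParams(W0=Tensor(np.array(obj["gcn"]["W0"]), requires_grad=True),
                        W1=Tensor(np.array(obj["gcn"]["W1"]), requires_grad=True),
                        activation_out=obj["gcn"]["activation_out"])
    projection = None
    if "projection" in obj:
        projection = Tensor(np.array(obj["projection"]), requires_grad=True)
    gat_layers = [
        GATLayerParams(
            W=[Tensor(np.array(w), requires_grad=True) for w in lay["W"]],
            a=[Tensor(np.array(a), requires_grad=True) for a in lay["a"]],
            fusion=lay["fusion"], leaky_slope=lay["leaky_slope"])
        for lay in obj["gat_layers"]
    ]
    return SideParams(gcn=gcn, projection=projection, gat_layers=gat_layers)


def save_checkpoint(path: str, params: ModelParams, config: TrainConfig,
                    matrix: AssociationMatrix) -> None:
    """Serialize all parameter tensors plus the config and id maps (JSON)."""
    payload = {
        "format": "lncdra-checkpoint-v1",
        "config": config.to_dict(),
        "m": params.m, "n": params.n,
        "lnc_ids": matrix.lnc_ids, "drug_ids": matrix.drug_ids,
        "lnc": _side_to_jsonable(params.lnc),
        "drug": _side_to_jsonable(params.drug),
    }
    with open(path, "w") as fh:
        json.dump(payload, fh)


def load_checkpoint(path: str) -> tuple[ModelParams, TrainConfig, list[str], list[str]]:
    """Load a checkpoint, validating format and shape consistency."""
    with open(path) as fh:
        payload = json.load(fh)
    if payload.get("format") != "lncdra-checkpoint-v1":
        raise CheckpointError(f"{path} is not a recognized checkpoint")
    config = TrainConfig(**payload["config"])
    params = ModelParams(lnc=_side_from_jsonable(payload["lnc"]),
                         drug=_side_from_jsonable(payload["drug"]),
                         m=payload["m"], n=payload["n"])
    ref = init_params(params.m, params.n, config)
    got = [p.data.shape for p in params.tensors]
    want = [p.data.shape for p in ref.tensors]
    if got != want:
        raise CheckpointError("checkpoint parameter shapes do not match config")
    return params, config, payload["lnc_ids"], payload["drug_ids"]
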