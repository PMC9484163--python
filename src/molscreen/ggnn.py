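"""Gated graph propagation, attention readout and substructure fusion.

The topological branch of the model. Node states start at the atom feature
vectors and are updated for ``interaction_steps`` rounds of GRU-gated
message passing, where the message into each atom is the bond-order-weighted
sum of its neighbors' states followed by a linear map:

    o_t = (A h_{t-1}) W_o + b_o
    z_t = sigmoid(o_t W_z + h_{t-1} U_z + b_z)        (update gate)
    r_t = sigmoid(o_t W_r + h_{t-1} U_r + b_r)        (reset gate)
    c_t = tanh(o_t W_h + (r_t * h_{t-1}) U_h + b_h)   (candidate)
    h_t = c_t * z_t + h_{t-1} * (1 - z_t)

Bond orders {1, 1.5, 2, 3} act as scalar edge weights in the aggregation;
there are no per-bond-type weight matrices. The readout gates each node
vector through two small perceptrons, then combines a shrunken mean
(divisor |V|+1) with an elementwise max-pool. Substructure vectors are
fused with the parent-graph vector by softmax attention.

All functions run on :class:`~molscreen.autodiff.Tensor` so the whole
branch is trainable; numpy-in/numpy-out wrappers cover single graphs.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field

import numpy as np

from .autodiff import Tensor, concat, parameter
from .molgraph import MolecularGraph

_NEG_INF = 1e9  # additive mask surrogate for -infinity in softmax logits


@dataclass
class GgnnParameters:
    """All trainable weights of the topological branch.

    Shapes are consistent with ``hidden_dim`` d: the propagation and gate
    matrices are (d, d), the readout perceptrons have one hidden layer of
    width d, and the fusion attention uses a d-dimensional context vector.
    """

    hidden_dim: int = 39
    interaction_steps: int = 2
    pooling: str = "fusion"  # "fusion" | "mean" | "max"
    weights: dict[str, Tensor] = field(default_factory=dict)
    input_projection: bool = False

    @classmethod
    def init(
        cls,
        rng: np.random.Generator,
        hidden_dim: int = 39,
        interaction_steps: int = 2,
        pooling: str = "fusion",
        feature_dim: int | None = None,
    ) -> "GgnnParameters":
        d = hidden_dim
        if pooling not in ("fusion", "mean", "max"):
            raise ValueError(f"unknown pooling {pooling!r}")
        names_dd = [
            "W_o", "W_z", "U_z", "W_r", "U_r", "W_h", "U_h",
            "f1_W1", "f1_W2", "f2_W1", "f2_W2", "att_W",
        ]
        weights = {name: parameter(np.zeros((d, d)), rng=rng) for name in names_dd}
        for name in ["b_o", "b_z", "b_r", "b_h", "f1_b1", "f1_b2", "f2_b1", "f2_b2", "att_b"]:
            weights[name] = parameter(np.zeros(d))
        weights["att_c"] = parameter(np.zeros((d, 1)), rng=rng)
        params = cls(
            hidden_dim=d,
            interaction_steps=interaction_steps,
            pooling=pooling,
            weights=weights,
        )
        if feature_dim is not None and feature_dim != d:
            params.input_projection = True
            weights["W_in"] = parameter(np.zeros((feature_dim, d)), rng=rng)
            weights["b_in"] = parameter(np.zeros(d))
        return params

    def parameters(self) -> list[Tensor]:
        return [self.weights[k] for k in sorted(self.weights)]

    # -- checkpointing ---------------------------------------------------

    def config_hash(self) -> str:
        payload = json.dumps(
            {
                "hidden_dim": self.hidden_dim,
                "interaction_steps": self.interaction_steps,
                "pooling": self.pooling,
                "shapes": {k: list(v.shape) for k, v in sorted(self.weights.items())},
            },
            sort_keys=True,
        )
        return hashlib.sha256(payload.encode()).hexdigest()

    def save(self, path: str) -> None:
        arrays = {k: v.value for k, v in self.weights.items()}
        arrays["__meta__"] = np.array(
            [self.hidden_dim, self.interaction_steps,
             ("fusion", "mean", "max").index(self.pooling)], dtype=np.int64
        )
        arrays["__hash__"] = np.frombuffer(
            bytes.fromhex(self.config_hash()), dtype=np.uint8
        )
        np.savez_compressed(path, **arrays)

    @classmethod
    def load(cls, path: str) -> "GgnnParameters":
        data = np.load(path)
        meta = data["__meta__"]
        params = cls(
            hidden_dim=int(meta[0]),
            interaction_steps=int(meta[1]),
            pooling=("fusion", "mean", "max")[int(meta[2])],
            weights={
                k: Tensor(data[k], requires_grad=True)
                for k in data.files
                if not k.startswith("__")
            },
        )
        params.input_projection = "W_in" in params.weights
        stored = bytes(data["__hash__"]).hex()
        if stored != params.config_hash():
            raise ValueError(f"checkpoint config hash mismatch in {path}")
        return params


def _check_dims(params: GgnnParameters, feature_dim: int) -> None:
    if params.input_projection:
        expected = params.weights["W_in"].shape[0]
    else:
        expected = params.hidden_dim
    if feature_dim != expected:
        raise ValueError(
            f"atom feature dimension {feature_dim} does not match hidden_dim "
            f"{params.hidden_dim}; configure an input projection"
        )


def propagate_batch(
    adjacency: np.ndarray, features: np.ndarray, params: GgnnParameters
) -> Tensor:
    """T rounds of gated propagation over a padded batch.

    ``adjacency`` is (B, n, n), ``features`` (B, n, f). Padded atoms have
    all-zero adjacency rows/columns so they never influence real atoms.
    """
    _check_dims(params, features.shape[-1])
    w = params.weights
    h = Tensor(features)
    if params.input_projection:
        h = h @ w["W_in"] + w["b_in"]
    A = Tensor(adjacency)
    for _ in range(params.interaction_steps):
        o = (A @ h) @ w["W_o"] + w["b_o"]
        z = (o @ w["W_z"] + h @ w["U_z"] + w["b_z"]).sigmoid()
        r = (o @ w["W_r"] + h @ w["U_r"] + w["b_r"]).sigmoid()
        cand = (o @ w["W_h"] + (r * h) @ w["U_h"] + w["b_h"]).tanh()
        h = cand * z + h * (1.0 - z)
    return h


def readout_batch(
    node_states: Tensor,
    mask: np.ndarray,
    params: GgnnParameters,
) -> Tensor:
    """Gated-attention readout of a padded batch to (B, d) graph vectors.

    Per node: g = sigmoid(f1(h)) * tanh(f2(h)); per graph the result is the
    shrunken mean of g (divisor |V|+1) plus the elementwise max over g,
    restricted to real atoms by ``mask`` (B, n, 1).
    """
    w = params.weights
    n_atoms = mask.sum(axis=(1, 2))
    if np.any(n_atoms < 1):
        raise ValueError("readout of an empty graph")
    f1 = (node_states @ w["f1_W1"] + w["f1_b1"]).tanh() @ w["f1_W2"] + w["f1_b2"]
    f2 = (node_states @ w["f2_W1"] + w["f2_b1"]).tanh() @ w["f2_W2"] + w["f2_b2"]
    gated = f1.sigmoid() * f2.tanh()
    mean_part = (gated * mask).sum(axis=1) / (n_atoms + 1.0)[:, None]
    max_part = (gated * mask + (mask - 1.0) * _NEG_INF).max(axis=1)
    if params.pooling == "mean":
        return mean_part
    if params.pooling == "max":
        return max_part
    return mean_part + max_part


def fuse_batch(
    h_graph: Tensor, sub_vectors: Tensor, sub_mask: np.ndarray, params: GgnnParameters
) -> Tensor:
    """Softmax-attention fusion of parent vectors with substructure vectors.

    ``h_graph`` is (B, d), ``sub_vectors`` (B, S, d) with ``sub_mask``
    (B, S) marking real substructures; the parent is always a candidate, so
    a molecule with no substructure keeps its parent vector exactly.
    """
    w = params.weights
    B, d = h_graph.shape
    S = sub_vectors.shape[1]
    cand = concat([h_graph.reshape(B, 1, d), sub_vectors], axis=1)
    e = ((cand @ w["att_W"] + w["att_b"]).tanh() @ w["att_c"]).reshape(B, S + 1)
    pad = np.concatenate([np.zeros((B, 1)), (sub_mask - 1.0) * _NEG_INF], axis=1)
    weights = (e + Tensor(pad)).softmax(axis=1)
    return (weights.reshape(B, S + 1, 1) * cand).sum(axis=1)


# -- single-graph numpy wrappers (the library-level operations) ----------


def _as_batch(graph: MolecularGraph) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    n = graph.atom_count
    return (
        graph.adjacency[None, :, :],
        graph.atom_features[None, :, :],
        np.ones((1, n, 1)),
    )


def propagate(graph: MolecularGraph, params: GgnnParameters) -> np.ndarray:
    """Node-state matrix (n, d) after T interaction steps."""
    A, H0, _ = _as_batch(graph)
    return propagate_batch(A, H0, params).value[0]


def readout(node_states: np.ndarray, params: GgnnParameters) -> np.ndarray:
    """Graph-level vector of length d from an (n, d) node-state matrix."""
    states = np.asarray(node_states, dtype=float)
    if states.ndim != 2 or states.shape[0] < 1:
        raise ValueError("readout needs a non-empty (n, d) node-state matrix")
    mask = np.ones((1, states.shape[0], 1))
    return readout_batch(Tensor(states[None]), mask, params).value[0]


def fuse_subgraphs(
    h_graph: np.ndarray, subgraph_vectors: list[np.ndarray], params: GgnnParameters
) -> np.ndarray:
    """Attention-weighted combination of a parent vector and its subgraph vectors."""
    h = Tensor(np.asarray(h_graph, dtype=float)[None])
    S = len(subgraph_vectors)
    if S == 0:
        subs = Tensor(np.zeros((1, 0, h.shape[1])))
        mask = np.zeros((1, 0))
    else:
        subs = Tensor(np.stack(subgraph_vectors)[None])
        mask = np.ones((1, S))
    return fuse_batch(h, subs, mask, params).value[0]


def attention_weights(
    h_graph: np.ndarray, subgraph_vectors: list[np.ndarray], params: GgnnParameters
) -> np.ndarray:
    """The softmax weights over {parent} + subgraphs (sums to 1)."""
    w = params.weights
    cand = np.concatenate([h_graph[None], np.stack(subgraph_vectors)] if subgraph_vectors else [h_graph[None]])
    e = (np.tanh(cand @ w["att_W"].value + w["att_b"].value) @ w["att_c"].value).ravel()
    e = e - e.max()
    p = np.exp(e)
    return p / p.sum()
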