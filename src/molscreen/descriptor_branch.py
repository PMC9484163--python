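"""Discrete-descriptor branch: boosted-tree descriptor ranking and readout.

The compound table carries hundreds of precomputed molecular descriptors
(default 729). A gradient-boosted tree ensemble under the second-order
objective ranks them by total split gain; the top k (default 50) are
z-score standardized, reweighted per position by softmax attention over
e_j = c^T tanh(w m_j + b), and projected by a fully connected layer to a
39-dimensional readout h_m that matches the topological branch's size.

The closed forms of the boosting objective are exposed directly:
``leaf_weight`` returns the optimal leaf value -G/(H+lambda) and
``structure_score`` the objective -1/2 sum_j G_j^2/(H_j+lambda) + gamma*T
for a fixed tree structure. The ensemble trainer itself is xgboost.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import xgboost as xgb

from .autodiff import Tensor, parameter


class NumericDomainError(ValueError):
    pass


def leaf_weight(G: float, H: float, lambda_reg: float) -> float:
    """Optimal leaf value -G/(H + lambda) for leaf gradient/hessian sums."""
    if lambda_reg < 0:
        raise NumericDomainError("lambda_reg must be >= 0")
    denom = H + lambda_reg
    if denom <= 0:
        raise NumericDomainError(f"H + lambda must be > 0, got {denom}")
    return -G / denom


def structure_score(
    leaf_stats: list[tuple[float, float]], lambda_reg: float, gamma: float
) -> float:
    """Objective of a fixed tree structure: -1/2 sum G_j^2/(H_j+lam) + gamma*T."""
    total = 0.0
    for G, H in leaf_stats:
        denom = H + lambda_reg
        if denom <= 0:
            raise NumericDomainError(f"H + lambda must be > 0, got {denom}")
        total += G**2 / denom
    return -0.5 * total + gamma * len(leaf_stats)


def split_gain(
    left: tuple[float, float],
    right: tuple[float, float],
    lambda_reg: float,
    gamma: float,
) -> float:
    """Gain of splitting one leaf into (left, right); negative means rejected."""
    parent = (left[0] + right[0], left[1] + right[1])
    return structure_score([parent], lambda_reg, gamma) - structure_score(
        [left, right], lambda_reg, gamma
    )


@dataclass
class DescriptorTable:
    """Aligned compound ids, descriptor names and an (n, p) value matrix."""

    compound_ids: list[str]
    names: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        if len(set(self.names)) != len(self.names):
            raise ValueError("descriptor names must be unique")
        if self.values.shape != (len(self.compound_ids), len(self.names)):
            raise ValueError("values shape does not match ids x names")

    def impute_median(self, train_index: np.ndarray | None = None) -> "DescriptorTable":
        """Replace missing values by the train-split column median."""
        values = self.values.copy()
        ref = values if train_index is None else values[train_index]
        n_missing = int(np.isnan(values).sum())
        if n_missing:
            medians = np.nanmedian(ref, axis=0)
            medians = np.where(np.isnan(medians), 0.0, medians)
            idx = np.where(np.isnan(values))
            values[idx] = medians[idx[1]]
            warnings.warn(f"imputed {n_missing} missing descriptor values by train median")
        return DescriptorTable(self.compound_ids, self.names, values)


@dataclass
class DescriptorRanking:
    """Descriptor names ordered by nonincreasing total-gain importance."""

    ranked_names: list[str]
    scores: np.ndarray
    k: int = 50
    degenerate: bool = False  # True when the variance fallback was used

    def top_k(self) -> list[str]:
        return self.ranked_names[: self.k]

    def to_tsv(self, path: str) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            for name, score in zip(self.ranked_names, self.scores):
                fh.write(f"{name}\t{score:.10g}\n")

    @classmethod
    def from_tsv(cls, path: str, k: int = 50) -> "DescriptorRanking":
        names, scores = [], []
        with open(path, encoding="utf-8") as fh:
            for line in fh:
                name, score = line.rstrip("\n").split("\t")
                names.append(name)
                scores.append(float(score))
        return cls(ranked_names=names, scores=np.array(scores), k=k)


DEFAULT_BOOSTING = {
    "n_rounds": 200,
    "max_depth": 4,
    "learning_rate": 0.1,
    "lambda_reg": 1.0,
    "gamma": 0.0,
}


def rank_descriptors(
    table: DescriptorTable,
    target: np.ndarray,
    k: int = 50,
    boosting_config: dict | None = None,
    objective: str = "regression",
    seed: int = 0,
) -> DescriptorRanking:
    """Rank descriptors by total gain of a gradient-boosted tree ensemble.

    Ties break by descriptor name; descriptors never used in a split score
    zero. A constant target cannot be boosted on and falls back to a
    variance ranking with ``degenerate=True`` and a warning.
    """
    target = np.asarray(target, dtype=float)
    if len(target) != len(table.compound_ids):
        raise ValueError("target length does not match table")
    if k > len(table.names):
        raise ValueError("k exceeds the number of descriptors")
    cfg = dict(DEFAULT_BOOSTING, **(boosting_config or {}))
    if np.ptp(target) == 0:
        warnings.warn("constant target: descriptor ranking falls back to variance")
        scores = table.values.var(axis=0)
        order = sorted(range(len(table.names)), key=lambda j: (-scores[j], table.names[j]))
        return DescriptorRanking(
            ranked_names=[table.names[j] for j in order],
            scores=scores[order], k=k, degenerate=True,
        )
    dtrain = xgb.DMatrix(table.values, label=target, feature_names=list(table.names))
    params = {
        "max_depth": cfg["max_depth"],
        "eta": cfg["learning_rate"],
        "lambda": cfg["lambda_reg"],
        "gamma": cfg["gamma"],
        "objective": "reg:squarederror" if objective == "regression" else "binary:logistic",
        "tree_method": "hist",
        "seed": seed,
        "nthread": 1,
    }
    booster = xgb.train(params, dtrain, num_boost_round=cfg["n_rounds"])
    gains = booster.get_score(importance_type="total_gain")
    scores = np.array([gains.get(name, 0.0) for name in table.names])
    order = sorted(range(len(table.names)), key=lambda j: (-scores[j], table.names[j]))
    return DescriptorRanking(
        ranked_names=[table.names[j] for j in order], scores=scores[order], k=k
    )


def merged_ranking(rankings: list[DescriptorRanking], k: int = 50) -> DescriptorRanking:
    """Merge per-task rankings by mean normalized gain."""
    names = sorted(rankings[0].ranked_names)
    merged = np.zeros(len(names))
    for r in rankings:
        total = r.scores.sum() or 1.0
        lookup = dict(zip(r.ranked_names, r.scores / total))
        merged += np.array([lookup[n] for n in names])
    merged /= len(rankings)
    order = sorted(range(len(names)), key=lambda j: (-merged[j], names[j]))
    return DescriptorRanking(
        ranked_names=[names[j] for j in order], scores=merged[order], k=k
    )


@dataclass
class Standardizer:
    """Train-split z-scoring of the selected descriptor columns."""

    mean: np.ndarray
    std: np.ndarray

    @classmethod
    def fit(cls, values: np.ndarray) -> "Standardizer":
        std = values.std(axis=0)
        return cls(mean=values.mean(axis=0), std=np.where(std == 0, 1.0, std))

    def transform(self, values: np.ndarray) -> np.ndarray:
        return (values - self.mean) / self.std


@dataclass
class ReadoutParameters:
    """Attention + projection weights of the descriptor readout."""

    k: int = 50
    out_dim: int = 39
    att_dim: int = 16
    weights: dict[str, Tensor] = field(default_factory=dict)

    @classmethod
    def init(cls, rng: np.random.Generator, k: int = 50, out_dim: int = 39,
             att_dim: int = 16) -> "ReadoutParameters":
        # the softmax attention shrinks each position to ~m_j/k, so the
        # projection init is scaled by k to keep h_m at unit variance
        weights = {
            "att_w": parameter(np.zeros(att_dim), rng=rng),
            "att_b": parameter(np.zeros(att_dim)),
            "att_c": parameter(np.zeros((att_dim, 1)), rng=rng),
            "proj_W": parameter(
                np.zeros((k, out_dim)), rng=rng,
                scale=k * np.sqrt(2.0 / (k + out_dim)),
            ),
            "proj_b": parameter(np.zeros(out_dim)),
        }
        return cls(k=k, out_dim=out_dim, att_dim=att_dim, weights=weights)

    def parameters(self) -> list[Tensor]:
        return [self.weights[k] for k in sorted(self.weights)]


def readout_batch(m: Tensor, params: ReadoutParameters) -> Tensor:
    """Attention-reweight an (B, k) descriptor batch and project to (B, 39).

    Each scalar position m_j gets a logit e_j = c^T tanh(w * m_j + b); the
    softmax over positions rescales the vector before the affine projection.
    """
    w = params.weights
    B, k = m.shape
    hidden = (m.reshape(B, k, 1) * w["att_w"] + w["att_b"]).tanh()
    e = (hidden @ w["att_c"]).reshape(B, k)
    att = e.softmax(axis=1)
    weighted = att * m
    return weighted @ w["proj_W"] + w["proj_b"]


def descriptor_readout(m: np.ndarray, params: ReadoutParameters) -> np.ndarray:
    """h_m (length 39) for one standardized selected-descriptor vector."""
    m = np.asarray(m, dtype=float)
    if not np.all(np.isfinite(m)):
        raise ValueError("descriptor vector must be finite")
    return readout_batch(Tensor(m[None]), params).value[0]


def descriptor_attention_weights(m: np.ndarray, params: ReadoutParameters) -> np.ndarray:
    """Softmax position weights (length k, sums to 1) for one vector."""
    w = params.weights
    hidden = np.tanh(np.outer(m, np.ones_like(w["att_w"].value)) * w["att_w"].value + w["att_b"].value)
    e = (hidden @ w["att_c"].value).ravel()
    e = e - e.max()
    p = np.exp(e)
    return p / p.sum()
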