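"""Branch fusion, task heads, training loop and evaluation metrics.

The two branch readouts — the topological vector h and the descriptor
vector h_m, both length 39 — are combined by a convex combination
h_final = lambda * h + (1 - lambda) * h_m (default lambda 0.6). A linear
head on h_final predicts the continuous ERalpha activity (pIC50, trained
with mean squared error); a two-way softmax head predicts each binary
ADMET endpoint (trained with cross-entropy). One model is trained per
task. Training uses Adam (learning rate 0.01), dropout 0.5 on h_final,
and early stopping on validation loss; everything is seeded.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import (
    average_precision_score,
    f1_score,
    mean_squared_error,
    precision_score,
    r2_score,
    recall_score,
    roc_auc_score,
)
from sklearn.model_selection import train_test_split

from . import descriptor_branch as desc
from . import ggnn as ggnn_mod
from .autodiff import Adam, Tensor, gather_rows, parameter
from .molgraph import MolecularGraph, mol_from_smiles
from .subgraph import SpeVocabulary, extract_substructures, induced_subgraph

REGRESSION_TASK = "eralpha"
CLASSIFICATION_TASKS = ("caco2", "cyp3a4", "herg", "hob", "mn")
ALL_TASKS = (REGRESSION_TASK,) + CLASSIFICATION_TASKS


class ConfigurationError(ValueError):
    pass


def fuse(h: np.ndarray, h_m: np.ndarray, lambda_fuse: float = 0.6) -> np.ndarray:
    """Elementwise convex combination lambda*h + (1-lambda)*h_m."""
    if not 0.0 <= lambda_fuse <= 1.0:
        raise ConfigurationError(f"lambda_fuse must be in [0, 1], got {lambda_fuse}")
    return lambda_fuse * np.asarray(h, float) + (1.0 - lambda_fuse) * np.asarray(h_m, float)


def loss_regression(pred: np.ndarray, truth: np.ndarray) -> float:
    """Batch mean squared error."""
    pred, truth = np.asarray(pred, float), np.asarray(truth, float)
    return float(np.mean((truth - pred) ** 2))


def loss_classification(probs: np.ndarray, onehot: np.ndarray) -> float:
    """Cross-entropy of class probabilities against one-hot labels."""
    probs, onehot = np.atleast_2d(probs), np.atleast_2d(onehot)
    return float(-np.sum(onehot * np.log(np.clip(probs, 1e-12, None))) / probs.shape[0])


# -- dataset preparation -------------------------------------------------


def _pad_graphs(graphs: list[MolecularGraph], feature_dim: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    n_max = max((g.atom_count for g in graphs), default=1)
    N = len(graphs)
    adjacency = np.zeros((N, n_max, n_max))
    features = np.zeros((N, n_max, feature_dim))
    mask = np.zeros((N, n_max, 1))
    for idx, g in enumerate(graphs):
        n = g.atom_count
        adjacency[idx, :n, :n] = g.adjacency
        features[idx, :n] = g.atom_features
        mask[idx, :n, 0] = 1.0
    return adjacency, features, mask


@dataclass
class PreparedGraphs:
    """Padded graph tensors for a list of compounds plus their substructures.

    Parent molecules and their (much smaller) induced substructure
    subgraphs are padded separately; ``sub_index`` addresses each
    compound's subgraph rows with ``sub_mask`` marking real slots.
    """

    adjacency: np.ndarray  # parents (B, n, n)
    features: np.ndarray  # (B, n, f)
    mask: np.ndarray  # (B, n, 1)
    sub_adjacency: np.ndarray  # subgraphs (M, ns, ns)
    sub_features: np.ndarray  # (M, ns, f)
    sub_node_mask: np.ndarray  # (M, ns, 1)
    sub_index: np.ndarray  # (B, S) rows into the subgraph arrays
    sub_mask: np.ndarray  # (B, S)

    @property
    def n_compounds(self) -> int:
        return self.adjacency.shape[0]

    @property
    def n_substructure_slots(self) -> int:
        return self.sub_mask.shape[1]

    def subset(self, rows: np.ndarray) -> "PreparedGraphs":
        """Restrict to a compound subset (graph rows are re-gathered)."""
        rows = np.asarray(rows, dtype=int)
        real = self.sub_mask[rows].astype(bool)
        keep = self.sub_index[rows][real]
        sub_index = np.zeros((len(rows), self.n_substructure_slots), dtype=int)
        sub_index[real] = np.arange(len(keep))
        return PreparedGraphs(
            adjacency=self.adjacency[rows],
            features=self.features[rows],
            mask=self.mask[rows],
            sub_adjacency=self.sub_adjacency[keep],
            sub_features=self.sub_features[keep],
            sub_node_mask=self.sub_node_mask[keep],
            sub_index=sub_index,
            sub_mask=self.sub_mask[rows],
        )


def prepare_graphs(
    smiles_list: list[str],
    vocab: SpeVocabulary | None,
    n_max_substructures: int = 8,
) -> PreparedGraphs:
    """Featurize, extract substructures and pad both graph sets."""
    parents = [mol_from_smiles(s) for s in smiles_list]
    B = len(parents)
    S = n_max_substructures if vocab is not None else 0
    subgraphs: list[MolecularGraph] = []
    sub_index = np.zeros((B, S), dtype=int)
    sub_mask = np.zeros((B, S))
    for i, g in enumerate(parents):
        if vocab is None or S == 0:
            continue
        subs = extract_substructures(g, vocab, n_max=S)
        for j, (_, atoms) in enumerate(subs.members):
            sub_index[i, j] = len(subgraphs)
            sub_mask[i, j] = 1.0
            subgraphs.append(induced_subgraph(g, atoms))
    f = parents[0].atom_features.shape[1]
    adjacency, features, mask = _pad_graphs(parents, f)
    sub_adjacency, sub_features, sub_node_mask = _pad_graphs(subgraphs, f)
    return PreparedGraphs(
        adjacency=adjacency,
        features=features,
        mask=mask,
        sub_adjacency=sub_adjacency,
        sub_features=sub_features,
        sub_node_mask=sub_node_mask,
        sub_index=sub_index,
        sub_mask=sub_mask,
    )


def split_indices(
    n: int,
    labels: np.ndarray | None,
    seed: int,
    fractions: tuple[float, float, float] = (0.8, 0.1, 0.1),
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Seeded 8:1:1 train/validation/test split, stratified for binary labels."""
    idx = np.arange(n)
    strat = labels if labels is not None and len(np.unique(labels)) == 2 else None
    try:
        train, rest = train_test_split(
            idx, train_size=fractions[0], random_state=seed,
            stratify=strat,
        )
        rel = fractions[1] / (fractions[1] + fractions[2])
        val, test = train_test_split(
            rest, train_size=rel, random_state=seed,
            stratify=None if strat is None else strat[rest],
        )
    except ValueError as exc:
        raise ConfigurationError(f"cannot form an 8:1:1 split of {n} samples: {exc}")
    if min(len(train), len(val), len(test)) == 0:
        raise ConfigurationError("a split is empty; dataset too small for 8:1:1")
    return train, val, test


# -- the model -----------------------------------------------------------


@dataclass
class TrainConfig:
    learning_rate: float = 0.01
    dropout: float = 0.5
    weight_decay: float = 0.0
    epochs: int = 200
    batch_size: int = 64
    patience: int = 20
    lambda_fuse: float = 0.6
    interaction_steps: int = 2
    pooling: str = "fusion"
    hidden_dim: int = 39
    top_k: int = 50
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.lambda_fuse <= 1.0:
            raise ConfigurationError("lambda_fuse must be in [0, 1]")


class Model:
    """One dual-branch predictor for a single task."""

    def __init__(self, task: str, config: TrainConfig, feature_dim: int = 39):
        if task not in ALL_TASKS:
            raise ConfigurationError(f"unknown task {task!r}; expected one of {ALL_TASKS}")
        self.task = task
        self.config = config
        self.is_regression = task == REGRESSION_TASK
        rng = np.random.default_rng(config.seed)
        self.ggnn = ggnn_mod.GgnnParameters.init(
            rng,
            hidden_dim=config.hidden_dim,
            interaction_steps=config.interaction_steps,
            pooling=config.pooling,
            feature_dim=feature_dim,
        )
        self.readout = desc.ReadoutParameters.init(
            rng, k=config.top_k, out_dim=config.hidden_dim
        )
        out = 1 if self.is_regression else 2
        self.head_W = parameter(np.zeros((config.hidden_dim, out)), rng=rng)
        self.head_b = parameter(np.zeros(out))
        self.standardizer: desc.Standardizer | None = None
        self.selected_names: list[str] | None = None

    def parameters(self) -> list[Tensor]:
        params: list[Tensor] = [self.head_W, self.head_b]
        lam = self.config.lambda_fuse
        if lam > 0.0:
            params += self.ggnn.parameters()
        if lam < 1.0:
            params += self.readout.parameters()
        return params

    # forward ------------------------------------------------------------

    def _h_final(
        self,
        graphs: PreparedGraphs,
        descriptors: np.ndarray,
        rows: np.ndarray,
        dropout_rng: np.random.Generator | None,
    ) -> Tensor:
        lam = self.config.lambda_fuse
        parts: list[tuple[float, Tensor]] = []
        if lam > 0.0:
            sub = graphs.subset(rows)
            states = ggnn_mod.propagate_batch(sub.adjacency, sub.features, self.ggnn)
            h_parent = ggnn_mod.readout_batch(states, sub.mask, self.ggnn)
            B, S = sub.sub_mask.shape
            if S and sub.sub_mask.any():
                sub_states = ggnn_mod.propagate_batch(
                    sub.sub_adjacency, sub.sub_features, self.ggnn
                )
                sub_all = ggnn_mod.readout_batch(sub_states, sub.sub_node_mask, self.ggnn)
                subvecs = gather_rows(sub_all, sub.sub_index.reshape(-1)).reshape(
                    B, S, self.config.hidden_dim
                )
            else:
                subvecs = Tensor(np.zeros((B, 0, self.config.hidden_dim)))
                sub.sub_mask = np.zeros((B, 0))
            h = ggnn_mod.fuse_batch(h_parent, subvecs, sub.sub_mask, self.ggnn)
            parts.append((lam, h))
        if lam < 1.0:
            h_m = desc.readout_batch(Tensor(descriptors[rows]), self.readout)
            parts.append((1.0 - lam, h_m))
        h_final = parts[0][0] * parts[0][1]
        for weight, tensor in parts[1:]:
            h_final = h_final + weight * tensor
        if dropout_rng is not None and self.config.dropout > 0.0:
            keep = 1.0 - self.config.dropout
            mask = dropout_rng.binomial(1, keep, size=h_final.shape) / keep
            h_final = h_final * Tensor(mask)
        return h_final

    def _loss(self, h_final: Tensor, labels: np.ndarray) -> Tensor:
        out = h_final @ self.head_W + self.head_b
        B = h_final.shape[0]
        if self.is_regression:
            pred = out.reshape(B)
            diff = pred - Tensor(labels)
            return (diff * diff).mean()
        probs = out.softmax(axis=1)
        onehot = np.eye(2)[labels.astype(int)]
        eps = 1e-12
        return -((probs + eps).log() * Tensor(onehot)).sum() / float(B)

    def predict(
        self, graphs: PreparedGraphs, descriptors: np.ndarray,
        rows: np.ndarray | None = None,
    ) -> np.ndarray:
        """Regression value per compound, or positive-class probability."""
        if rows is None:
            rows = np.arange(graphs.n_compounds)
        h_final = self._h_final(graphs, descriptors, rows, dropout_rng=None)
        out = (h_final @ self.head_W + self.head_b).value
        if self.is_regression:
            return out.ravel()
        shifted = out - out.max(axis=1, keepdims=True)
        e = np.exp(shifted)
        return (e / e.sum(axis=1, keepdims=True))[:, 1]


    # checkpointing --------------------------------------------------------

    def save(self, path: str) -> None:
        """Write all weights plus task/config metadata to one archive."""
        import json

        arrays: dict[str, np.ndarray] = {}
        for name, t in self.ggnn.weights.items():
            arrays[f"ggnn.{name}"] = t.value
        for name, t in self.readout.weights.items():
            arrays[f"readout.{name}"] = t.value
        arrays["head.W"] = self.head_W.value
        arrays["head.b"] = self.head_b.value
        if self.standardizer is not None:
            arrays["std.mean"] = self.standardizer.mean
            arrays["std.std"] = self.standardizer.std
        meta = {
            "task": self.task,
            "config": self.config.__dict__,
            "selected_names": self.selected_names,
        }
        arrays["__meta__"] = np.frombuffer(
            json.dumps(meta).encode("utf-8"), dtype=np.uint8
        ).copy()
        np.savez_compressed(path, **arrays)

    @classmethod
    def load(cls, path: str) -> "Model":
        import json

        data = np.load(path)
        meta = json.loads(bytes(data["__meta__"]).decode("utf-8"))
        config = TrainConfig(**meta["config"])
        feature_dim = (
            data["ggnn.W_in"].shape[0] if "ggnn.W_in" in data.files
            else config.hidden_dim
        )
        model = cls(meta["task"], config, feature_dim=feature_dim)
        for name in model.ggnn.weights:
            model.ggnn.weights[name].value = data[f"ggnn.{name}"]
        for name in model.readout.weights:
            model.readout.weights[name].value = data[f"readout.{name}"]
        model.head_W.value = data["head.W"]
        model.head_b.value = data["head.b"]
        if "std.mean" in data.files:
            model.standardizer = desc.Standardizer(
                mean=data["std.mean"], std=data["std.std"]
            )
        model.selected_names = meta["selected_names"]
        return model


@dataclass
class TrainResult:
    model: Model
    history: list[dict[str, float]] = field(default_factory=list)
    metrics: dict[str, float] = field(default_factory=dict)
    best_epoch: int = -1


def train(
    graphs: PreparedGraphs,
    descriptors: np.ndarray,
    labels: np.ndarray,
    task: str,
    config: TrainConfig,
    splits: tuple[np.ndarray, np.ndarray, np.ndarray] | None = None,
    early_stopping: bool = True,
    log: bool = False,
) -> TrainResult:
    """Train one task model; returns the model, loss history and test metrics.

    ``descriptors`` must already be restricted to the selected top-k columns
    (raw scale; standardization statistics are fit on the training split
    here). Fully deterministic for a fixed config seed on one thread.
    """
    labels = np.asarray(labels, dtype=float)
    if splits is None:
        strat = None if task == REGRESSION_TASK else labels
        splits = split_indices(graphs.n_compounds, strat, seed=config.seed)
    train_idx, val_idx, test_idx = splits
    if len(train_idx) == 0:
        raise ConfigurationError("empty training split")
    std = desc.Standardizer.fit(descriptors[train_idx])
    descriptors = std.transform(descriptors)
    model = Model(task, config, feature_dim=graphs.features.shape[-1])
    model.standardizer = std
    optimizer = Adam(
        model.parameters(), lr=config.learning_rate,
        weight_decay=config.weight_decay,
    )
    rng = np.random.default_rng(config.seed + 1)
    best_val = np.inf
    best_weights: list[np.ndarray] | None = None
    best_epoch = -1
    history: list[dict[str, float]] = []
    since_best = 0
    for epoch in range(config.epochs):
        order = rng.permutation(train_idx)
        epoch_loss = 0.0
        for start in range(0, len(order), config.batch_size):
            batch = order[start : start + config.batch_size]
            optimizer.zero_grad()
            h_final = model._h_final(graphs, descriptors, batch, dropout_rng=rng)
            loss = model._loss(h_final, labels[batch])
            loss.backward()
            optimizer.step()
            epoch_loss += float(loss.value) * len(batch)
        epoch_loss /= len(train_idx)
        if len(val_idx):
            h_val = model._h_final(graphs, descriptors, val_idx, dropout_rng=None)
            val_loss = float(model._loss(h_val, labels[val_idx]).value)
        else:
            val_loss = epoch_loss
        history.append({"epoch": epoch, "train_loss": epoch_loss, "val_loss": val_loss})
        if log:
            if len(val_idx):
                val_preds = model.predict(graphs, descriptors, val_idx)
                val_metrics = evaluate(val_preds, labels[val_idx], task)
                metric_name = "mse" if model.is_regression else "f1"
                metric_str = f" val_{metric_name}={val_metrics[metric_name]:.4f}"
            else:
                metric_str = ""
            print(
                f"epoch={epoch} train_loss={epoch_loss:.5f} "
                f"val_loss={val_loss:.5f}{metric_str}"
            )
        if val_loss < best_val - 1e-9:
            best_val = val_loss
            best_epoch = epoch
            best_weights = [p.value.copy() for p in model.parameters()]
            since_best = 0
        else:
            since_best += 1
            if early_stopping and since_best >= config.patience:
                break
    if early_stopping and best_weights is not None:
        for p, w in zip(model.parameters(), best_weights):
            p.value = w
    result = TrainResult(model=model, history=history, best_epoch=best_epoch)
    if len(test_idx):
        preds = model.predict(graphs, descriptors, test_idx)
        result.metrics = evaluate(preds, labels[test_idx], task)
    return result


def evaluate(predictions: np.ndarray, labels: np.ndarray, task: str) -> dict[str, float]:
    """Regression: MSE and R2. Classification: precision, recall, F1, AUC, AUPR.

    Classification predictions are positive-class probabilities; the binary
    call uses threshold 0.5, while AUC/AUPR use the probabilities directly.
    """
    predictions = np.asarray(predictions, float)
    labels = np.asarray(labels, float)
    if task == REGRESSION_TASK:
        return {
            "mse": float(mean_squared_error(labels, predictions)),
            "r2": float(r2_score(labels, predictions)),
        }
    calls = (predictions >= 0.5).astype(int)
    y = labels.astype(int)
    out = {
        "precision": float(precision_score(y, calls, zero_division=0)),
        "recall": float(recall_score(y, calls, zero_division=0)),
        "f1": float(f1_score(y, calls, zero_division=0)),
    }
    if len(np.unique(y)) == 2:
        out["auc"] = float(roc_auc_score(y, predictions))
        out["aupr"] = float(average_precision_score(y, predictions))
    else:
        warnings.warn("single-class labels: AUC/AUPR undefined, reported as nan")
        out["auc"] = out["aupr"] = float("nan")
    return out


def repeated_evaluation(
    graphs: PreparedGraphs,
    descriptors: np.ndarray,
    labels: np.ndarray,
    task: str,
    config: TrainConfig,
    n_repeats: int = 10,
) -> dict[str, float]:
    """Mean test metrics over repeated stratified 8:1:1 resamples."""
    metric_lists: dict[str, list[float]] = {}
    for rep in range(n_repeats):
        cfg = TrainConfig(**{**config.__dict__, "seed": config.seed + rep})
        result = train(graphs, descriptors, labels, task, cfg)
        for key, value in result.metrics.items():
            metric_lists.setdefault(key, []).append(value)
    return {k: float(np.mean(v)) for k, v in metric_lists.items()}
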