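"""End-to-end glue: descriptor selection, per-task training, prediction
and candidate ranking over a compound table.

The substructure vocabulary is learned on the training split only (the
split drawn from the pipeline seed), never on validation or test SMILES.
The same learned vocabulary and featurized graph batch are shared by all
six task models; each task trains its own model and split.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import descriptor_branch as desc
from . import predictor, ranker, subgraph
from .io_config import PipelineConfig
from .predictor import ALL_TASKS, CLASSIFICATION_TASKS, REGRESSION_TASK


def select_descriptors(
    table: desc.DescriptorTable,
    labels: dict[str, np.ndarray],
    config: PipelineConfig,
    train_index: np.ndarray | None = None,
) -> desc.DescriptorRanking:
    """Rank descriptors on the configured selection target label."""
    target_task = config.selection_target
    if target_task == "merged":
        rankings = [
            select_descriptors(
                table, labels, _with(config, selection_target=t), train_index
            )
            for t in labels
        ]
        return desc.merged_ranking(rankings, k=config.top_k)
    if target_task not in labels:
        raise KeyError(f"selection target {target_task!r} has no label column")
    sub_table = table
    target = labels[target_task]
    if train_index is not None:
        sub_table = desc.DescriptorTable(
            [table.compound_ids[i] for i in train_index],
            table.names,
            table.values[train_index],
        )
        target = target[train_index]
    return desc.rank_descriptors(
        sub_table.impute_median(),
        target,
        k=config.top_k,
        boosting_config={
            "n_rounds": config.boosting_rounds,
            "max_depth": config.boosting_depth,
            "learning_rate": config.boosting_learning_rate,
            "lambda_reg": config.boosting_lambda,
            "gamma": config.boosting_gamma,
        },
        objective="regression" if target_task == REGRESSION_TASK else "classification",
        seed=config.stage_seed("descriptor-ranking"),
    )


def _with(config: PipelineConfig, **overrides) -> PipelineConfig:
    return PipelineConfig(**{**config.to_dict(), **overrides})


def train_config(config: PipelineConfig) -> predictor.TrainConfig:
    return predictor.TrainConfig(
        learning_rate=config.learning_rate,
        dropout=config.dropout,
        weight_decay=config.weight_decay,
        epochs=config.epochs,
        batch_size=config.batch_size,
        patience=config.patience,
        lambda_fuse=config.lambda_fuse,
        interaction_steps=config.interaction_steps,
        pooling=config.pooling,
        hidden_dim=config.hidden_dim,
        top_k=config.top_k,
        seed=config.stage_seed("training"),
    )


def learn_vocabulary(
    smiles: list[str], config: PipelineConfig, train_index: np.ndarray | None = None
) -> subgraph.SpeVocabulary:
    corpus = smiles if train_index is None else [smiles[i] for i in train_index]
    return subgraph.learn_vocab(
        corpus, max_vocab=config.vocab_max, min_frequency=config.vocab_min_frequency
    )


def run_pipeline(
    smiles: list[str],
    table: desc.DescriptorTable,
    labels: dict[str, np.ndarray],
    config: PipelineConfig,
    tasks: tuple[str, ...] = ALL_TASKS,
) -> tuple[pd.DataFrame, ranker.RankedList, dict[str, predictor.TrainResult]]:
    """Select descriptors, train every task model, predict, and rank.

    Returns the prediction table (one row per compound), the ranked list,
    and the per-task training results.
    """
    n = len(smiles)
    split = predictor.split_indices(n, None, seed=config.stage_seed("split"))
    vocab = learn_vocabulary(smiles, config, train_index=split[0])
    graphs = predictor.prepare_graphs(smiles, vocab, config.n_max_substructures)
    ranking = select_descriptors(table, labels, config, train_index=split[0])
    selected = [table.names.index(name) for name in ranking.top_k()]
    matrix = table.impute_median().values[:, selected]

    cfg = train_config(config)
    results: dict[str, predictor.TrainResult] = {}
    predictions = pd.DataFrame({"compound_id": table.compound_ids})
    for task in tasks:
        if task not in labels:
            continue
        result = predictor.train(graphs, matrix, labels[task], task, cfg)
        result.model.selected_names = ranking.top_k()
        results[task] = result
        std_matrix = result.model.standardizer.transform(matrix)
        preds = result.model.predict(graphs, std_matrix)
        if task == REGRESSION_TASK:
            predictions["pIC50_pred"] = preds
        else:
            predictions[f"{task}_prob"] = preds
            predictions[f"{task}_call"] = (preds >= 0.5).astype(int)

    ranked = None
    if "pIC50_pred" in predictions.columns and all(
        f"{t}_call" in predictions.columns for t in CLASSIFICATION_TASKS
    ):
        card = ranker.build_scorecard(
            predictions,
            significance=config.significance,
            factor=config.score_factor,
            offset=config.score_offset,
            activity_quantile=config.activity_quantile,
            min_favorable=config.min_favorable,
        )
        ranked = ranker.rank_candidates(card, predictions)
    return predictions, ranked, results
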