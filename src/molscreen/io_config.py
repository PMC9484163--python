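"""Compound-table IO, pipeline configuration and seed fan-out.

The CSV dialect is comma-separated UTF-8 with a header row: a compound id
column, a SMILES column, label columns (continuous pIC50, binary ADMET)
and descriptor columns — by default everything that is not id/SMILES/label
is a descriptor. Reading validates SMILES parseability, descriptor
numeric-ness and label domains, reporting row numbers; schema, numeric and
config problems raise distinct exceptions mapped to distinct CLI exit
codes (2, 3, 4).
"""

from __future__ import annotations

import dataclasses
import hashlib
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from .descriptor_branch import DescriptorTable
from .molgraph import SmilesParseError, mol_from_smiles
from .predictor import ALL_TASKS, CLASSIFICATION_TASKS
from .synthetic_data import LABEL_COLUMNS

logger = logging.getLogger("molscreen")


class SchemaError(ValueError):
    exit_code = 2


class NumericError(ValueError):
    exit_code = 3


class ConfigError(ValueError):
    exit_code = 4


@dataclass
class PipelineConfig:
    """Every tunable of the pipeline with its default.

    Unknown keys in an overrides file are rejected; the resolved config can
    be dumped (and hashed) alongside any output so results are traceable.
    """

    # fusion / model
    lambda_fuse: float = 0.6
    interaction_steps: int = 2
    hidden_dim: int = 39
    pooling: str = "fusion"
    learning_rate: float = 0.01
    dropout: float = 0.5
    weight_decay: float = 0.0
    epochs: int = 200
    batch_size: int = 64
    patience: int = 20
    # descriptor branch
    top_k: int = 50
    selection_target: str = "eralpha"
    boosting_rounds: int = 200
    boosting_depth: int = 4
    boosting_learning_rate: float = 0.1
    boosting_lambda: float = 1.0
    boosting_gamma: float = 0.0
    # substructures
    vocab_max: int = 300
    vocab_min_frequency: int = 5
    n_max_substructures: int = 8
    # featurization
    mass_norm: float = 200.0
    # ranking
    significance: float = 0.05
    score_factor: float = 20.0 / float(np.log(2.0))
    score_offset: float = 600.0
    activity_quantile: float = 0.7
    min_favorable: int = 4
    # io
    smiles_column: str = "SMILES"
    id_column: str = "compound_id"
    # seeding
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str) -> "PipelineConfig":
        with open(path, encoding="utf-8") as fh:
            overrides = yaml.safe_load(fh) or {}
        return cls.from_dict(overrides)

    @classmethod
    def from_dict(cls, overrides: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(overrides) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**overrides)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def dump(self, path: str) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    def config_hash(self) -> str:
        payload = yaml.safe_dump(self.to_dict(), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]

    def stage_seed(self, stage: str) -> int:
        """Deterministic per-stage seed fanned out from the global seed."""
        digest = hashlib.sha256(f"{self.seed}:{stage}".encode()).digest()
        return int.from_bytes(digest[:4], "little") % (2**31)


def read_compound_table(
    path: str, config: PipelineConfig | None = None
) -> tuple[list[str], DescriptorTable, dict[str, np.ndarray]]:
    """Read and validate a compound CSV.

    Returns the SMILES list, the descriptor table and a mapping from task
    name to label vector (absent label columns are simply omitted).
    """
    config = config or PipelineConfig()
    frame = pd.read_csv(path)
    for col in (config.id_column, config.smiles_column):
        if col not in frame.columns:
            raise SchemaError(f"missing required column {col!r} in {path}")
    label_cols = {t: LABEL_COLUMNS[t] for t in ALL_TASKS if LABEL_COLUMNS[t] in frame.columns}
    reserved = {config.id_column, config.smiles_column, *label_cols.values()}
    descriptor_names = [c for c in frame.columns if c not in reserved]

    smiles = list(frame[config.smiles_column].astype(str))
    bad_rows = []
    for i, s in enumerate(smiles):
        try:
            mol_from_smiles(s)
        except SmilesParseError:
            bad_rows.append(i + 2)  # header is line 1
    if bad_rows:
        if len(bad_rows) > 0.05 * len(smiles):
            raise NumericError(
                f"{len(bad_rows)} of {len(smiles)} SMILES unparsable "
                f"(first bad lines: {bad_rows[:5]})"
            )
        logger.warning("unparsable SMILES on lines %s", bad_rows)

    values = np.empty((len(frame), len(descriptor_names)))
    for j, name in enumerate(descriptor_names):
        col = pd.to_numeric(frame[name], errors="coerce")
        if col.isna().any() and not frame[name].isna().any():
            row = int(col.index[col.isna()][0]) + 2
            raise NumericError(f"non-numeric descriptor {name!r} at line {row}")
        values[:, j] = col.to_numpy(dtype=float)

    labels: dict[str, np.ndarray] = {}
    for task, col_name in label_cols.items():
        col = frame[col_name]
        if task in CLASSIFICATION_TASKS:
            vals = col.to_numpy()
            bad = ~np.isin(vals, (0, 1))
            if bad.any():
                row = int(np.where(bad)[0][0]) + 2
                raise NumericError(
                    f"label {col_name!r} must be 0/1; got {vals[bad][0]!r} at line {row}"
                )
            labels[task] = vals.astype(int)
        else:
            vals = pd.to_numeric(col, errors="coerce")
            if vals.isna().any():
                row = int(vals.index[vals.isna()][0]) + 2
                raise NumericError(f"label {col_name!r} not numeric at line {row}")
            labels[task] = vals.to_numpy(dtype=float)

    table = DescriptorTable(
        compound_ids=list(frame[config.id_column].astype(str)),
        names=descriptor_names,
        values=values,
    )
    logger.info(
        "read %d compounds, %d descriptors, labels %s (config %s)",
        len(smiles), len(descriptor_names), sorted(labels), config.config_hash(),
    )
    return smiles, table, labels
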