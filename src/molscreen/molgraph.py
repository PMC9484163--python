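"""Atom-level molecular graphs from SMILES.

Each heavy atom becomes a node carrying a fixed 39-dimensional feature
vector (seven one-hot blocks plus a normalized atomic mass); bonds become
entries of a symmetric adjacency matrix whose values encode bond order
numerically (single 1, aromatic 1.5, double 2, triple 3). Hydrogens are
not nodes: they are folded into the per-atom hydrogen-count block.

The block layout is frozen so feature positions are stable across runs:

    atom type        12   (ATOM_VOCAB order; out-of-vocabulary -> all zero)
    number of bonds   6   (heavy-atom degree 0..5, saturating)
    formal charge     5   (-2, -1, 0, +1, +2, clamping)
    chirality         4   (CW, CCW, unspecified, other)
    hydrogen count    5   (0..4 bound hydrogens, saturating)
    hybridization     5   (sp, sp2, sp3, sp3d, sp3d2; other -> all zero)
    aromaticity       1
    atom mass         1   (mass / MASS_NORM, clipped to [0, 1])
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from rdkit import Chem
from rdkit import RDLogger

RDLogger.DisableLog("rdApp.*")  # rdkit parse chatter; we raise our own errors

ATOM_VOCAB: tuple[str, ...] = (
    "C", "N", "O", "S", "F", "Cl", "Br", "I", "P", "B", "Si", "Se",
)
DEGREES: tuple[int, ...] = (0, 1, 2, 3, 4, 5)
FORMAL_CHARGES: tuple[int, ...] = (-2, -1, 0, 1, 2)
CHIRALITY: tuple[str, ...] = ("CW", "CCW", "unspecified", "other")
HYDROGEN_COUNTS: tuple[int, ...] = (0, 1, 2, 3, 4)
HYBRIDIZATIONS: tuple[str, ...] = ("sp", "sp2", "sp3", "sp3d", "sp3d2")
MASS_NORM: float = 200.0

#: feature-vector length: 12 + 6 + 5 + 4 + 5 + 5 + 1 + 1
FEATURE_DIM: int = (
    len(ATOM_VOCAB) + len(DEGREES) + len(FORMAL_CHARGES) + len(CHIRALITY)
    + len(HYDROGEN_COUNTS) + len(HYBRIDIZATIONS) + 1 + 1
)

_CHIRAL_TAGS = {
    Chem.ChiralType.CHI_TETRAHEDRAL_CW: "CW",
    Chem.ChiralType.CHI_TETRAHEDRAL_CCW: "CCW",
    Chem.ChiralType.CHI_UNSPECIFIED: "unspecified",
}
_HYBRID_NAMES = {
    Chem.HybridizationType.SP: "sp",
    Chem.HybridizationType.SP2: "sp2",
    Chem.HybridizationType.SP3: "sp3",
    Chem.HybridizationType.SP3D: "sp3d",
    Chem.HybridizationType.SP3D2: "sp3d2",
}


class SmilesParseError(ValueError):
    """Raised when a SMILES string cannot be parsed."""


class FeatureEncodingError(ValueError):
    """Raised when an atomic descriptor is outside its declared domain."""


@dataclass
class MolecularGraph:
    """One compound as a featurized heavy-atom graph.

    ``atom_features`` is ``(atom_count, FEATURE_DIM)``; ``adjacency`` is the
    symmetric bond-order matrix with entries in {0, 1, 1.5, 2, 3}. Atom order
    is the parser's atom indexing and is used consistently downstream.
    """

    smiles: str
    atom_count: int
    atom_features: np.ndarray
    adjacency: np.ndarray
    atom_order: list[int] = field(default_factory=list)

    def validate(self) -> None:
        n = self.atom_count
        if self.atom_features.shape != (n, FEATURE_DIM):
            raise ValueError(
                f"atom_features shape {self.atom_features.shape} != ({n}, {FEATURE_DIM})"
            )
        if self.adjacency.shape != (n, n):
            raise ValueError("adjacency shape mismatch")
        if not np.allclose(self.adjacency, self.adjacency.T):
            raise ValueError("adjacency not symmetric")
        if np.any(np.diag(self.adjacency) != 0):
            raise ValueError("adjacency diagonal not zero")
        allowed = {0.0, 1.0, 1.5, 2.0, 3.0}
        if not set(np.unique(self.adjacency)).issubset(allowed):
            raise ValueError("adjacency entries outside {0, 1, 1.5, 2, 3}")


def _one_hot(size: int, index: int | None) -> np.ndarray:
    v = np.zeros(size)
    if index is not None:
        v[index] = 1.0
    return v


def featurize_atom(
    symbol: str,
    degree: int,
    formal_charge: int,
    chirality: str,
    n_hydrogens: int,
    hybridization: str | None,
    aromatic: bool,
    mass: float,
    *,
    atom_vocab: tuple[str, ...] = ATOM_VOCAB,
    mass_norm: float = MASS_NORM,
    atom_index: int | None = None,
) -> np.ndarray:
    """Encode one atom's eight descriptors into the 39-length vector.

    Out-of-vocabulary elements encode as an all-zero atom-type block with a
    warning; degree, charge and hydrogen count saturate/clamp at the block
    boundary with a warning. Descriptors with no sensible clamp (chirality,
    a negative hydrogen count, ...) raise :class:`FeatureEncodingError`.
    """
    where = f" (atom {atom_index})" if atom_index is not None else ""

    if symbol in atom_vocab:
        type_block = _one_hot(len(atom_vocab), atom_vocab.index(symbol))
    else:
        warnings.warn(f"element {symbol!r}{where} not in atom vocabulary; atom-type block is all-zero")
        type_block = _one_hot(len(atom_vocab), None)

    if degree < 0:
        raise FeatureEncodingError(f"negative degree {degree}{where} in block 'number of bonds'")
    if degree > DEGREES[-1]:
        warnings.warn(f"degree {degree}{where} saturates the bond-count block")
        degree = DEGREES[-1]
    degree_block = _one_hot(len(DEGREES), degree)

    if formal_charge < FORMAL_CHARGES[0] or formal_charge > FORMAL_CHARGES[-1]:
        warnings.warn(f"formal charge {formal_charge}{where} clamped to [-2, 2]")
        formal_charge = int(np.clip(formal_charge, FORMAL_CHARGES[0], FORMAL_CHARGES[-1]))
    charge_block = _one_hot(len(FORMAL_CHARGES), FORMAL_CHARGES.index(formal_charge))

    if chirality not in CHIRALITY:
        raise FeatureEncodingError(f"chirality {chirality!r}{where} not one of {CHIRALITY}")
    chirality_block = _one_hot(len(CHIRALITY), CHIRALITY.index(chirality))

    if n_hydrogens < 0:
        raise FeatureEncodingError(f"negative hydrogen count{where}")
    if n_hydrogens > HYDROGEN_COUNTS[-1]:
        warnings.warn(f"hydrogen count {n_hydrogens}{where} saturates its block")
        n_hydrogens = HYDROGEN_COUNTS[-1]
    hydrogen_block = _one_hot(len(HYDROGEN_COUNTS), n_hydrogens)

    if hybridization in HYBRIDIZATIONS:
        hybrid_block = _one_hot(len(HYBRIDIZATIONS), HYBRIDIZATIONS.index(hybridization))
    else:
        hybrid_block = _one_hot(len(HYBRIDIZATIONS), None)

    aromatic_block = np.array([1.0 if aromatic else 0.0])
    mass_block = np.array([float(np.clip(mass / mass_norm, 0.0, 1.0))])

    return np.concatenate(
        [type_block, degree_block, charge_block, chirality_block,
         hydrogen_block, hybrid_block, aromatic_block, mass_block]
    )


_BOND_ORDER = {
    Chem.BondType.SINGLE: 1.0,
    Chem.BondType.DOUBLE: 2.0,
    Chem.BondType.TRIPLE: 3.0,
    Chem.BondType.AROMATIC: 1.5,
}


def mol_from_smiles(
    smiles: str,
    *,
    atom_vocab: tuple[str, ...] = ATOM_VOCAB,
    mass_norm: float = MASS_NORM,
) -> MolecularGraph:
    """Parse a SMILES string into a featurized :class:`MolecularGraph`.

    Deterministic for identical input: atom order follows the parser's
    indexing of the input string. Raises :class:`SmilesParseError` naming
    the offending string when parsing fails.
    """
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise SmilesParseError(f"invalid SMILES: {smiles!r}")
    n = mol.GetNumAtoms()
    features = np.zeros((n, FEATURE_DIM))
    for atom in mol.GetAtoms():
        i = atom.GetIdx()
        features[i] = featurize_atom(
            atom.GetSymbol(),
            atom.GetDegree(),
            atom.GetFormalCharge(),
            _CHIRAL_TAGS.get(atom.GetChiralTag(), "other"),
            atom.GetTotalNumHs(),
            _HYBRID_NAMES.get(atom.GetHybridization()),
            atom.GetIsAromatic(),
            atom.GetMass(),
            atom_vocab=atom_vocab,
            mass_norm=mass_norm,
            atom_index=i,
        )
    adjacency = np.zeros((n, n))
    for bond in mol.GetBonds():
        order = _BOND_ORDER.get(bond.GetBondType())
        if order is None:
            raise FeatureEncodingError(
                f"unsupported bond type {bond.GetBondType()} in {smiles!r}"
            )
        i, j = bond.GetBeginAtomIdx(), bond.GetEndAtomIdx()
        adjacency[i, j] = adjacency[j, i] = order
    graph = MolecularGraph(
        smiles=smiles,
        atom_count=n,
        atom_features=features,
        adjacency=adjacency,
        atom_order=list(range(n)),
    )
    graph.validate()
    return graph


def graphs_from_csv(path: str, smiles_column: str = "SMILES") -> list[MolecularGraph]:
    """Featurize every SMILES in a CSV column."""
    import pandas as pd

    frame = pd.read_csv(path)
    if smiles_column not in frame.columns:
        raise KeyError(f"column {smiles_column!r} not found in {path}")
    return [mol_from_smiles(s) for s in frame[smiles_column]]


def save_graphs(path: str, graphs: list[MolecularGraph]) -> None:
    """Cache featurized graphs as a compressed archive of per-molecule matrices."""
    arrays: dict[str, np.ndarray] = {
        "smiles": np.array([g.smiles for g in graphs], dtype=str)
    }
    for k, g in enumerate(graphs):
        arrays[f"features_{k}"] = g.atom_features
        arrays[f"adjacency_{k}"] = g.adjacency
    np.savez_compressed(path, **arrays)


def load_graphs(path: str) -> list[MolecularGraph]:
    data = np.load(path)
    smiles = list(data["smiles"])
    graphs = []
    for k, s in enumerate(smiles):
        features = data[f"features_{k}"]
        adjacency = data[f"adjacency_{k}"]
        graphs.append(
            MolecularGraph(
                smiles=str(s),
                atom_count=features.shape[0],
                atom_features=features,
                adjacency=adjacency,
                atom_order=list(range(features.shape[0])),
            )
        )
    return graphs
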