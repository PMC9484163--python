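"""Synthetic compound tables with planted, recoverable ground truth.

The generator emulates the shape of the screening dataset the pipeline is
built for — one SMILES column, 729 numeric molecular descriptors, one
continuous pIC50 activity and five roughly balanced binary ADMET labels —
while keeping every signal recoverable by construction:

* molecules are concatenations of one or two random drug-like SMILES
  fragments from a small pool (every fragment chains into valid SMILES)
  plus the planted content described below;
* a designated signal substructure (an anilide, by default) is present in
  about half the molecules and raises the activity and the ADMET latents —
  this is the part of the label only the topological branch can see.
  Molecules WITHOUT the signal carry the same atoms as two disconnected
  decoy fragments (a carbonyl plus an aniline), so the two classes are
  composition-matched at the atom-feature level and separating them
  requires resolving the carbonyl-nitrogen bond by message passing;
* the ADMET latents also depend on each molecule's nitrogen-minus-oxygen
  atom balance (n_N - n_O)/n — a signed counting quantity that an averaged
  readout expresses directly but a max-pool readout cannot;
* ten planted descriptor columns carry linear signal into the activity and
  the ADMET latents — the part only the descriptor branch can see; the
  remaining columns are standard normal noise;
* binary labels are thresholded latent scores, thresholded at the quantile
  that realizes the requested positive fraction per task.

Everything is reproducible from the spec seed, byte-identically for the
emitted CSV.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .molgraph import mol_from_smiles
from .predictor import CLASSIFICATION_TASKS

#: chainable fragments: each starts with an atom and ends in an atom that
#: accepts one more bond, so any concatenation is a valid SMILES
DEFAULT_FRAGMENT_POOL: tuple[str, ...] = (
    "C", "CC", "CCC", "C(C)C",
    "CO", "COC", "CN", "CNC", "N(C)C",
    "C(=O)", "C(=O)O", "C(=O)OC", "C=C", "C#CC", "C=NC",
    "c1ccccc1", "c1ccncc1", "c1ccsc1",
    "C1CCCCC1", "C1CCNCC1", "C1CCOCC1",
    "C(Cl)", "C(F)", "C(Br)", "C(C(F)(F)F)",
    "C(O)", "C(N)", "CS", "S(=O)(=O)C",
)

DEFAULT_SIGNAL = "C(=O)Nc1ccccc1"

#: decoy fragments planted together in signal-free molecules; their union
#: carries exactly the signal substructure's atoms, so the amide bond
#: itself — not atom composition — is what distinguishes the classes
DECOY_CARBONYL = "C(=O)"
DECOY_AMINE = "Nc1ccccc1"

LABEL_COLUMNS = {
    "eralpha": "pIC50",
    "caco2": "Caco2",
    "cyp3a4": "CYP3A4",
    "herg": "hERG",
    "hob": "HOB",
    "mn": "MN",
}


@dataclass
class SyntheticSpec:
    """Parameters of the generator; defaults mirror the study conditions
    (1974 compounds, 729 descriptors, ten informative ones, labels close
    to 1:1)."""

    n_compounds: int = 1974
    fragment_pool: tuple[str, ...] = DEFAULT_FRAGMENT_POOL
    signal_substructure: str = DEFAULT_SIGNAL
    signal_rate: float = 0.5
    signal_bonus: float = 1.5
    decoy_rate: float = 1.0
    n_descriptors: int = 729
    informative_set: tuple[int, ...] = (3, 76, 149, 222, 295, 368, 441, 514, 587, 660)
    effect_sizes: tuple[float, ...] = (
        1.0, -0.9, 0.85, -0.8, 0.75, -0.7, 0.65, -0.6, 0.55, 0.5,
    )
    admet_signal_weight: float = 2.0
    admet_descriptor_weight: float = 1.0
    admet_composition_weight: float = 0.8
    admet_noise_sd: float = 0.5
    noise_sd: float = 0.5
    admet_balance: float = 0.5
    # free (random) fragments per molecule, on top of the planted content
    min_fragments: int = 1
    max_fragments: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.informative_set) != len(self.effect_sizes):
            raise ValueError("informative_set and effect_sizes lengths differ")
        if max(self.informative_set) >= self.n_descriptors:
            raise ValueError("informative descriptor index out of range")

    def descriptor_names(self) -> list[str]:
        return [f"D{j + 1:04d}" for j in range(self.n_descriptors)]

    def informative_names(self) -> list[str]:
        names = self.descriptor_names()
        return [names[j] for j in self.informative_set]


@dataclass
class SyntheticDataset:
    """Generated table plus the ground truth used by recovery tests."""

    spec: SyntheticSpec
    frame: pd.DataFrame
    has_signal: np.ndarray
    latents: dict[str, np.ndarray] = field(default_factory=dict)

    def to_csv(self, path: str) -> None:
        self.frame.to_csv(path, index=False)

    @property
    def smiles(self) -> list[str]:
        return list(self.frame["SMILES"])


def _no_balance(smiles: str) -> float:
    """Signed nitrogen-minus-oxygen balance (n_N - n_O) / n_atoms."""
    graph = mol_from_smiles(smiles)
    symbols = graph.atom_features[:, :12]  # atom-type one-hot block
    return float(symbols[:, 1].sum() - symbols[:, 2].sum()) / graph.atom_count


def _build_molecule(
    rng: np.random.Generator, spec: SyntheticSpec, with_signal: bool, with_decoy: bool
) -> str:
    for _ in range(40):
        n_free = int(rng.integers(spec.min_fragments, spec.max_fragments + 1))
        frags = [
            spec.fragment_pool[int(rng.integers(len(spec.fragment_pool)))]
            for _ in range(n_free)
        ]
        if with_signal:
            frags.insert(int(rng.integers(n_free + 1)), spec.signal_substructure)
        elif with_decoy:
            # same atoms as the signal and the same number of free
            # fragments, but the carbonyl and the aniline sit in
            # disconnected fragments; the aniline never opens the SMILES,
            # so its nitrogen keeps the amide nitrogen's degree
            frags.insert(int(rng.integers(n_free + 1)), DECOY_CARBONYL)
            frags.insert(1 + int(rng.integers(len(frags))), DECOY_AMINE)
        smiles = "".join(frags)
        try:
            mol_from_smiles(smiles)
        except Exception:  # constructed string did not parse; resample
            warnings.warn(f"skipping unparsable constructed SMILES {smiles!r}")
            continue
        if with_signal or spec.signal_substructure not in smiles:
            return smiles
    raise RuntimeError("fragment pool cannot produce a valid molecule")


def generate(spec: SyntheticSpec) -> SyntheticDataset:
    """Generate the compound table; fully reproducible from ``spec.seed``."""
    rng = np.random.default_rng(spec.seed)
    n = spec.n_compounds
    has_signal = rng.random(n) < spec.signal_rate
    has_decoy = rng.random(n) < spec.decoy_rate
    smiles = [
        _build_molecule(rng, spec, bool(s), bool(d))
        for s, d in zip(has_signal, has_decoy)
    ]

    X = rng.standard_normal((n, spec.n_descriptors))
    info = np.asarray(spec.informative_set)
    w = np.asarray(spec.effect_sizes)
    activity = (
        X[:, info] @ w
        + spec.signal_bonus * has_signal
        + rng.normal(0.0, spec.noise_sd, size=n)
    )

    # global-composition covariate: signed N-minus-O balance per atom —
    # an averaged counting property a mean-pooling readout represents
    # directly but a max-pool readout cannot
    balance = np.array([_no_balance(s) for s in smiles])
    balance_std = balance.std() or 1.0
    balance_z = (balance - balance.mean()) / balance_std

    sig_centered = has_signal.astype(float) - spec.signal_rate
    labels: dict[str, np.ndarray] = {}
    latents: dict[str, np.ndarray] = {"pIC50": activity}
    for t, task in enumerate(CLASSIFICATION_TASKS):
        cols = info[np.arange(t, t + 3) % len(info)]
        w_t = np.array([1.0, -0.8, 0.6])
        w_t = spec.admet_descriptor_weight * w_t / np.linalg.norm(w_t)
        latent = (
            spec.admet_signal_weight * sig_centered
            + spec.admet_composition_weight * balance_z
            + X[:, cols] @ w_t
            + rng.normal(0.0, spec.admet_noise_sd, size=n)
        )
        cut = np.quantile(latent, 1.0 - spec.admet_balance)
        labels[task] = (latent > cut).astype(int)
        latents[task] = latent

    data = {"compound_id": [f"CPD{i + 1:05d}" for i in range(n)], "SMILES": smiles}
    for j, name in enumerate(spec.descriptor_names()):
        data[name] = X[:, j]
    data["pIC50"] = activity
    for task in CLASSIFICATION_TASKS:
        data[LABEL_COLUMNS[task]] = labels[task]
    return SyntheticDataset(
        spec=spec,
        frame=pd.DataFrame(data),
        has_signal=has_signal.astype(int),
        latents=latents,
    )
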