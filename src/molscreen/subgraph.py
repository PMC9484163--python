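"""SMILES pair encoding and per-molecule substructure extraction.

A byte-pair-encoding-style procedure over atom-wise SMILES tokens: the most
frequent adjacent token pair in the corpus is merged, repeatedly, yielding a
vocabulary of multi-atom substructure tokens. Tokenizing a molecule with the
learned merges then maps each multi-atom token back to the heavy-atom
indices it spans, giving vertex-induced substructure subgraphs that are fed
through the same gated graph network as the parent molecule.

The base tokenizer is the standard SMILES regex: bracket atoms and
two-letter elements are single tokens; ring-closure digits, bond symbols
and parentheses are their own (atom-free) tokens. Ring bonds internal to a
token's atom span are kept by induced-subgraph semantics even when the span
is not contiguous in the SMILES string.
"""

from __future__ import annotations

import re
from collections import Counter
from dataclasses import dataclass, field

import numpy as np

from .molgraph import MolecularGraph

_TOKEN_RE = re.compile(
    r"(\[[^\]]+\]|Br|Cl|Si|Se|N|O|S|P|F|I|B|C|b|c|n|o|s|p"
    r"|\(|\)|\.|=|#|-|\+|\\|/|:|~|@|\?|>|\*|\$|%\d{2}|\d)"
)

# tokens (outside brackets) that correspond to one heavy atom
_ATOM_TOKEN_RE = re.compile(r"^(\[[^\]]+\]|Br|Cl|Si|Se|[NOSPFIBC]|[bcnosp])$")


class TokenizationError(ValueError):
    pass


def base_tokenize(smiles: str) -> list[str]:
    """Split a SMILES string into atom-wise base tokens (lossless)."""
    tokens = _TOKEN_RE.findall(smiles)
    if "".join(tokens) != smiles:
        raise TokenizationError(f"cannot tokenize SMILES {smiles!r}")
    return tokens


def token_atom_count(token: str) -> int:
    """Number of heavy atoms a (possibly merged) token covers."""
    return sum(1 for t in base_tokenize(token) if _ATOM_TOKEN_RE.match(t))


@dataclass
class SpeVocabulary:
    """Learned merge rules plus the multi-atom tokens they produce.

    ``merges`` replay deterministically on any tokenized SMILES; every
    retained token has corpus frequency >= ``min_frequency``.
    """

    merges: list[tuple[str, str, int]] = field(default_factory=list)
    tokens: dict[str, int] = field(default_factory=dict)
    min_frequency: int = 5
    max_vocab: int = 300

    def save(self, path: str) -> None:
        """Plain-text merge table: one `left<TAB>right<TAB>frequency` per line."""
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(f"# min_frequency={self.min_frequency} max_vocab={self.max_vocab}\n")
            for left, right, freq in self.merges:
                fh.write(f"{left}\t{right}\t{freq}\n")

    @classmethod
    def load(cls, path: str) -> "SpeVocabulary":
        merges: list[tuple[str, str, int]] = []
        min_frequency, max_vocab = 5, 300
        with open(path, encoding="utf-8") as fh:
            for line in fh:
                line = line.rstrip("\n")
                if line.startswith("#"):
                    opts = dict(kv.split("=") for kv in line[1:].split())
                    min_frequency = int(opts.get("min_frequency", min_frequency))
                    max_vocab = int(opts.get("max_vocab", max_vocab))
                    continue
                if not line:
                    continue
                left, right, freq = line.split("\t")
                merges.append((left, right, int(freq)))
        vocab = cls(merges=merges, min_frequency=min_frequency, max_vocab=max_vocab)
        vocab.tokens = {left + right: freq for left, right, freq in merges}
        return vocab


@dataclass
class SubstructureSet:
    """Multi-atom substructure tokens of one molecule with their atom spans.

    Members are ordered by descending corpus frequency, ties broken
    lexicographically by token then by first atom index.
    """

    parent_smiles: str
    members: list[tuple[str, frozenset[int]]] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.members)


def _merge_sequence(tokens: list[str], pair: tuple[str, str]) -> list[str]:
    out: list[str] = []
    i = 0
    while i < len(tokens):
        if i + 1 < len(tokens) and (tokens[i], tokens[i + 1]) == pair:
            out.append(tokens[i] + tokens[i + 1])
            i += 2
        else:
            out.append(tokens[i])
            i += 1
    return out


def learn_vocab(
    corpus: list[str], max_vocab: int = 300, min_frequency: int = 5
) -> SpeVocabulary:
    """Learn merge rules by iterated most-frequent-adjacent-pair merging.

    Stops after ``max_vocab`` merges or when no pair reaches
    ``min_frequency``. Ties between equally frequent pairs break
    lexicographically so learning is deterministic.
    """
    if not corpus:
        raise ValueError("empty corpus: cannot learn a vocabulary")
    if max_vocab < 1:
        raise ValueError("max_vocab must be >= 1")
    sequences = [base_tokenize(s) for s in corpus]
    merges: list[tuple[str, str, int]] = []
    for _ in range(max_vocab):
        counts: Counter[tuple[str, str]] = Counter()
        for seq in sequences:
            for a, b in zip(seq, seq[1:]):
                counts[(a, b)] += 1
        if not counts:
            break
        best_freq = max(counts.values())
        if best_freq < min_frequency:
            break
        pair = min(p for p, c in counts.items() if c == best_freq)
        merges.append((pair[0], pair[1], best_freq))
        sequences = [_merge_sequence(seq, pair) for seq in sequences]
    vocab = SpeVocabulary(merges=merges, min_frequency=min_frequency, max_vocab=max_vocab)
    vocab.tokens = {left + right: freq for left, right, freq in merges}
    return vocab


def tokenize(smiles: str, vocab: SpeVocabulary) -> list[str]:
    """Tokenize with the learned merges; concatenation reproduces the input."""
    tokens = base_tokenize(smiles)
    for left, right, _ in vocab.merges:
        tokens = _merge_sequence(tokens, (left, right))
    return tokens


def tokenize_with_atoms(
    smiles: str, vocab: SpeVocabulary
) -> list[tuple[str, tuple[int, ...]]]:
    """Tokenize and carry, per token, the heavy-atom indices it spans."""
    base = base_tokenize(smiles)
    atom_idx = 0
    annotated: list[tuple[str, tuple[int, ...]]] = []
    for tok in base:
        if _ATOM_TOKEN_RE.match(tok):
            annotated.append((tok, (atom_idx,)))
            atom_idx += 1
        else:
            annotated.append((tok, ()))
    for left, right, _ in vocab.merges:
        out: list[tuple[str, tuple[int, ...]]] = []
        i = 0
        while i < len(annotated):
            if (
                i + 1 < len(annotated)
                and annotated[i][0] == left
                and annotated[i + 1][0] == right
            ):
                out.append(
                    (left + right, annotated[i][1] + annotated[i + 1][1])
                )
                i += 2
            else:
                out.append(annotated[i])
                i += 1
        annotated = out
    return annotated


def extract_substructures(
    graph: MolecularGraph, vocab: SpeVocabulary, n_max: int = 8
) -> SubstructureSet:
    """Multi-atom tokens of ``graph`` mapped to their atom-index sets.

    Tokens spanning fewer than two atoms (ring-closure digits, bare
    punctuation) are discarded; at most ``n_max`` members are kept in the
    documented frequency ordering. Deterministic given (graph, vocab, n_max).
    """
    if n_max < 0:
        raise ValueError("n_max must be >= 0")
    members: list[tuple[str, frozenset[int]]] = []
    for token, atoms in tokenize_with_atoms(graph.smiles, vocab):
        if len(atoms) >= 2:
            members.append((token, frozenset(atoms)))
    members.sort(key=lambda m: (-vocab.tokens.get(m[0], 0), m[0], min(m[1])))
    return SubstructureSet(parent_smiles=graph.smiles, members=members[:n_max])


def induced_subgraph(graph: MolecularGraph, atom_indices: frozenset[int]) -> MolecularGraph:
    """Vertex-induced subgraph: parent feature rows plus adjacency submatrix."""
    idx = sorted(atom_indices)
    if len(idx) < 2:
        raise ValueError("an induced substructure needs at least 2 atoms")
    if idx[0] < 0 or idx[-1] >= graph.atom_count:
        raise IndexError(f"atom index out of range for {graph.smiles!r}: {idx}")
    sub = MolecularGraph(
        smiles=graph.smiles,
        atom_count=len(idx),
        atom_features=graph.atom_features[idx].copy(),
        adjacency=graph.adjacency[np.ix_(idx, idx)].copy(),
        atom_order=idx,
    )
    sub.validate()
    return sub
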