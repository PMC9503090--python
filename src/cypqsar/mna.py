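"""Multilevel Neighborhoods of Atoms (MNA) descriptors.

An MNA descriptor of level n rooted at atom a is the string

    D0(a) = label(a)
    Dn(a) = label(a) + "(" + concat(sorted {Dn-1(b) : b adjacent to a}) + ")"

where label(a) is the element symbol, prefixed with "-" when the atom does
not lie on any cycle. Children are sorted by plain byte-wise string
comparison, which makes the descriptor independent of input atom numbering.
A molecule's descriptor set is the union, over all atoms, of its level
1..max_level descriptors (set semantics: kinds, not occurrences).

For an atom with no neighbors the recursion descends through a phantom
empty child, so the level-n descriptor of an isolated atom keeps one nested
pair of parentheses per level ("-He()", "-He(())", ...).

The frozen descriptor→index vocabulary supports the applicability-domain
rule of the classifier: the fraction of a query molecule's descriptors
absent from the training vocabulary ("novelty") measures how far the
molecule sits from the training chemical space.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from typing import Iterable, Mapping, Sequence

from .chem_model import Atom, Molecule

DEFAULT_MAX_LEVEL = 2


@dataclass(frozen=True)
class MnaDescriptor:
    text: str
    level: int

    def __str__(self) -> str:
        return self.text


def atom_label(atom: Atom) -> str:
    """Element symbol, "-"-prefixed iff the atom is not in a ring."""
    return atom.element if atom.in_ring else f"-{atom.element}"


def _phantom(level: int) -> str:
    # D_n of the phantom empty child: "" , "()", "(())", ...
    if level == 0:
        return ""
    return "(" + _phantom(level - 1) + ")"


def mna_descriptor(molecule: Molecule, atom_index: int, level: int
                   ) -> MnaDescriptor:
    """Level-``level`` MNA descriptor rooted at ``atom_index``."""
    if not (0 <= atom_index < molecule.n_atoms):
        raise IndexError(f"atom index {atom_index} out of range "
                         f"[0, {molecule.n_atoms})")
    if level < 0:
        raise ValueError("level must be non-negative")
    return MnaDescriptor(_descr(molecule, atom_index, level), level)


def _descr(molecule: Molecule, i: int, level: int) -> str:
    label = atom_label(molecule.atoms[i])
    if level == 0:
        return label
    nbrs = molecule.neighbors(i)
    if not nbrs:
        return label + "(" + _phantom(level - 1) + ")"
    children = sorted(_descr(molecule, j, level - 1) for j in nbrs)
    return label + "(" + "".join(children) + ")"


@dataclass(frozen=True)
class MnaSet:
    """Unique MNA descriptors of one molecule at levels 1..max_level."""

    descriptors: frozenset[str]
    max_level: int

    def __len__(self) -> int:
        return len(self.descriptors)

    def __iter__(self):
        return iter(sorted(self.descriptors))

    def __contains__(self, text: str) -> bool:
        return text in self.descriptors


def mna_set(molecule: Molecule, max_level: int = DEFAULT_MAX_LEVEL) -> MnaSet:
    """Union over all atoms of level 1..max_level descriptors."""
    if max_level < 1:
        raise ValueError("max_level must be >= 1")
    texts: set[str] = set()
    for i in range(molecule.n_atoms):
        for lvl in range(1, max_level + 1):
            texts.add(_descr(molecule, i, lvl))
    return MnaSet(frozenset(texts), max_level)


class MnaVocabulary:
    """Frozen descriptor→index registry with training document frequencies.

    Built once from the training molecules' descriptor sets; lookups of
    unseen text report novelty instead of assigning an index.
    """

    def __init__(self, index: Mapping[str, int],
                 doc_freq: Mapping[str, int] | None = None):
        self._index = dict(index)
        self._doc_freq = dict(doc_freq or {})

    @classmethod
    def fit(cls, descriptor_sets: Iterable[MnaSet]) -> "MnaVocabulary":
        freq: dict[str, int] = {}
        for ds in descriptor_sets:
            for text in ds.descriptors:
                freq[text] = freq.get(text, 0) + 1
        index = {text: i for i, text in enumerate(sorted(freq))}
        return cls(index, freq)

    def __len__(self) -> int:
        return len(self._index)

    def __contains__(self, text: str) -> bool:
        return text in self._index

    def index_of(self, text: str) -> int | None:
        """Index of a known descriptor, or None for a new descriptor."""
        return self._index.get(text)

    def document_frequency(self, text: str) -> int:
        return self._doc_freq.get(text, 0)

    def top_by_frequency(self, m: int) -> list[str]:
        """The m most frequent training descriptors (ties broken by text)."""
        ranked = sorted(self._index, key=lambda t: (-self._doc_freq.get(t, 0), t))
        return ranked[:m]

    def to_frame(self):
        import pandas as pd
        rows = [(i, t, self._doc_freq.get(t, 0))
                for t, i in sorted(self._index.items(), key=lambda kv: kv[1])]
        return pd.DataFrame(rows, columns=["index", "descriptor", "doc_freq"])

    @classmethod
    def from_frame(cls, df) -> "MnaVocabulary":
        index = dict(zip(df["descriptor"], df["index"].astype(int)))
        freq = dict(zip(df["descriptor"], df["doc_freq"].astype(int)))
        return cls(index, freq)


def novelty_fraction(descriptor_set: MnaSet | Iterable[str],
                     vocab: MnaVocabulary) -> float:
    """Fraction of a molecule's descriptors absent from the vocabulary."""
    texts = set(descriptor_set.descriptors
                if isinstance(descriptor_set, MnaSet) else descriptor_set)
    if not texts:
        raise ValueError("empty descriptor set has no novelty fraction")
    unknown = sum(1 for t in texts if t not in vocab)
    return unknown / len(texts)
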