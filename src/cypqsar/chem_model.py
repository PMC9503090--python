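"""Molecule ingestion and standardization.

Every descriptor in this package operates on a constitution-only view of a
molecule: an ordered atom list with ring-membership flags and a symmetric
adjacency matrix. Structures are standardized on input (largest covalent
fragment, stereochemistry stripped, hydrogens made explicit) so that the
MNA and QNA descriptor modules see a single canonical representation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterator, Sequence

import numpy as np
from rdkit import Chem
from rdkit.Chem import rdmolops
from rdkit import RDLogger

RDLogger.DisableLog("rdApp.*")

logger = logging.getLogger(__name__)


class SmilesParseError(ValueError):
    """Raised when a SMILES string cannot be parsed or sanitized.

    ``position`` is the 0-based index of the offending token when it can be
    located (unbalanced parentheses/brackets, unclosed ring bonds), else None.
    """

    def __init__(self, message: str, text: str, position: int | None = None):
        self.text = text
        self.position = position
        loc = f" at position {position}" if position is not None else ""
        super().__init__(f"{message}{loc}: {text!r}")


@dataclass(frozen=True)
class Atom:
    element: str
    in_ring: bool
    index: int


@dataclass(frozen=True)
class StandardizationPolicy:
    keep_largest_fragment: bool = True
    add_explicit_hydrogens: bool = True
    strip_stereo: bool = True


DEFAULT_POLICY = StandardizationPolicy()


@dataclass
class Molecule:
    """Standardized molecular graph.

    ``adjacency`` is a dense symmetric 0/1 matrix with zero diagonal over
    atom indices; ``atoms[i].index == i`` always holds.
    """

    atoms: list[Atom]
    adjacency: np.ndarray
    id: str = ""
    smiles: str = ""
    _rdmol: Chem.Mol | None = field(default=None, repr=False, compare=False)

    def __post_init__(self):
        n = len(self.atoms)
        if self.adjacency.shape != (n, n):
            raise ValueError("adjacency shape does not match atom count")
        if not np.array_equal(self.adjacency, self.adjacency.T):
            raise ValueError("adjacency must be symmetric")
        if np.any(np.diag(self.adjacency) != 0):
            raise ValueError("adjacency diagonal must be zero")

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    def neighbors(self, i: int) -> list[int]:
        return [int(j) for j in np.nonzero(self.adjacency[i])[0]]

    def heavy_atom_indices(self) -> list[int]:
        return [a.index for a in self.atoms if a.element != "H"]


def _locate_syntax_error(text: str) -> int | None:
    """Best-effort location of the offending SMILES token."""
    depth = 0
    ring_open: dict[str, int] = {}
    in_bracket = False
    bracket_pos = 0
    i = 0
    while i < len(text):
        ch = text[i]
        if in_bracket:
            if ch == "]":
                in_bracket = False
            i += 1
            continue
        if ch == "[":
            in_bracket = True
            bracket_pos = i
        elif ch == "(":
            depth += 1
        elif ch == ")":
            depth -= 1
            if depth < 0:
                return i
        elif ch.isdigit():
            if ch in ring_open:
                del ring_open[ch]
            else:
                ring_open[ch] = i
        elif ch == "%" and i + 2 < len(text):
            lbl = text[i : i + 3]
            if lbl in ring_open:
                del ring_open[lbl]
            else:
                ring_open[lbl] = i
            i += 2
        i += 1
    if in_bracket:
        return bracket_pos
    if depth != 0:
        return text.rindex("(")
    if ring_open:
        return min(ring_open.values())
    return None


def _standardize(rdmol: Chem.Mol, policy: StandardizationPolicy) -> Chem.Mol:
    if policy.keep_largest_fragment:
        frags = rdmolops.GetMolFrags(rdmol, asMols=True, sanitizeFrags=False)
        if len(frags) > 1:
            rdmol = max(frags, key=lambda f: f.GetNumAtoms())
    if policy.strip_stereo:
        Chem.RemoveStereochemistry(rdmol)
    Chem.SanitizeMol(rdmol)
    if policy.add_explicit_hydrogens:
        rdmol = Chem.AddHs(rdmol)
    return rdmol


def _from_rdmol(rdmol: Chem.Mol, mol_id: str) -> Molecule:
    atoms = [
        Atom(element=a.GetSymbol(), in_ring=a.IsInRing(), index=a.GetIdx())
        for a in rdmol.GetAtoms()
    ]
    n = rdmol.GetNumAtoms()
    adj = np.zeros((n, n), dtype=np.int8)
    for b in rdmol.GetBonds():
        i, j = b.GetBeginAtomIdx(), b.GetEndAtomIdx()
        adj[i, j] = adj[j, i] = 1
    canonical = Chem.MolToSmiles(Chem.RemoveHs(Chem.Mol(rdmol)))
    return Molecule(atoms=atoms, adjacency=adj, id=mol_id, smiles=canonical,
                    _rdmol=rdmol)


def parse_smiles(text: str, policy: StandardizationPolicy = DEFAULT_POLICY,
                 mol_id: str = "") -> Molecule:
    """Parse one SMILES string into a standardized :class:`Molecule`.

    Raises :class:`SmilesParseError` on malformed input, with the offending
    token position when it can be determined.
    """
    if not text or not text.strip():
        raise SmilesParseError("empty SMILES", text)
    text = text.strip()
    rdmol = Chem.MolFromSmiles(text, sanitize=False)
    if rdmol is None:
        raise SmilesParseError("unparsable SMILES", text,
                               _locate_syntax_error(text))
    try:
        rdmol = _standardize(rdmol, policy)
    except Exception as exc:  # sanitization failures (valence etc.)
        raise SmilesParseError(f"sanitization failed ({exc})", text,
                               _locate_syntax_error(text)) from exc
    return _from_rdmol(rdmol, mol_id)


def write_canonical(mol: Molecule) -> str:
    """Canonical (hydrogen-suppressed, stereo-free) SMILES of a molecule."""
    return mol.smiles


def parse_sdf(stream, policy: StandardizationPolicy = DEFAULT_POLICY
              ) -> Iterator[Molecule]:
    """Parse SD-file content (a path, file object, or string) lazily.

    Records that fail sanitization are skipped and logged with their
    0-based record index; record order is preserved.
    """
    if hasattr(stream, "read"):
        data = stream.read()
    elif isinstance(stream, str) and "\n" not in stream and stream.endswith(
            (".sdf", ".sd", ".mol")):
        with open(stream) as fh:
            data = fh.read()
    else:
        data = stream
    supplier = Chem.SDMolSupplier()
    supplier.SetData(data, sanitize=False, removeHs=False)
    for idx, rdmol in enumerate(supplier):
        if rdmol is None:
            logger.warning("SDF record %d: unreadable, skipped", idx)
            continue
        mol_id = rdmol.GetProp("_Name") if rdmol.HasProp("_Name") else str(idx)
        try:
            rdmol = _standardize(rdmol, policy)
        except Exception as exc:
            logger.warning("SDF record %d (%s): sanitization failed (%s), "
                           "skipped", idx, mol_id, exc)
            continue
        yield _from_rdmol(rdmol, mol_id or str(idx))


def canonical_smiles(text: str, policy: StandardizationPolicy = DEFAULT_POLICY
                     ) -> str:
    """Canonical SMILES of a standardized structure — the structure-identity
    key used for duplicate and conflict detection during curation."""
    return parse_smiles(text, policy).smiles


def molecules_to_sdf(mols: Sequence[Molecule], path: str,
                     props: Sequence[dict] | None = None) -> None:
    """Write molecules (hydrogen-suppressed) to an SD file with optional
    per-molecule data fields."""
    writer = Chem.SDWriter(path)
    try:
        for i, mol in enumerate(mols):
            rd = Chem.MolFromSmiles(mol.smiles)
            rd.SetProp("_Name", mol.id or str(i))
            if props is not None:
                for key, val in props[i].items():
                    rd.SetProp(str(key), str(val))
            writer.write(rd)
    finally:
        writer.close()
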