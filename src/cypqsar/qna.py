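"""Quantitative Neighborhoods of Atoms (QNA) descriptors.

Each heavy atom i of a molecule carries two dimensionless values built
from ground-state atomic ionization potentials (IP) and electron
affinities (EA), propagated through the exponential of the heavy-atom
connectivity matrix C:

    A_k = (IP_k + EA_k) / 2        (Mulliken electronegativity, eV)
    B_k = IP_k − EA_k              (chemical hardness scale, eV)
    E   = exp(−C)                  (symmetric matrix exponential)
    P_i = B_i^{−1/2} Σ_k E_ik B_k^{−1/2} A_k
    Q_i = B_i^{−1/2} Σ_k E_ik B_k^{−1/2}

C is the unweighted adjacency matrix of the hydrogen-suppressed graph.
The matrix exponential is evaluated through the symmetric
eigendecomposition, so P and Q are deterministic to ~1e−10 across
platforms and invariant under atom renumbering.

Molecule-level feature vectors for regression are means over atoms of
Chebyshev-polynomial products T_j(P̃)·T_k(Q̃) with j + k ≤ max_degree,
where P̃, Q̃ are P, Q affinely mapped into [−1, 1] using training-set
bounds (values outside the bounds are clipped). An alternative feature
source is a binary presence vector over the most frequent training MNA
descriptors; consensus models mix sub-models built on either source.

The shipped IP/EA table (data/element_properties.csv) holds NIST
ground-state atomic values in eV for the elements common in drug-like
molecules (H, B, C, N, O, F, Si, P, S, Cl, As, Se, Br, Sn, Te, I).
"""

from __future__ import annotations

import importlib.resources
import logging
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from numpy.polynomial import chebyshev as _cheb
from scipy.linalg import eigh

from .chem_model import Molecule
from .mna import MnaSet, MnaVocabulary, mna_set

logger = logging.getLogger(__name__)

DEFAULT_MAX_DEGREE = 4


class ElementProperties:
    """Per-element ionization potential / electron affinity table (eV)."""

    def __init__(self, table: Mapping[str, tuple[float, float]]):
        for el, (ip, ea) in table.items():
            if not ip > ea:
                raise ValueError(f"IP must exceed EA for {el}")
        self._table = dict(table)

    @classmethod
    def default(cls) -> "ElementProperties":
        path = importlib.resources.files("cypqsar.data") / \
            "element_properties.csv"
        df = pd.read_csv(path)
        return cls({row.element: (row.ionization_potential_ev,
                                  row.electron_affinity_ev)
                    for row in df.itertuples()})

    def __contains__(self, element: str) -> bool:
        return element in self._table

    def ip(self, element: str) -> float:
        return self._lookup(element)[0]

    def ea(self, element: str) -> float:
        return self._lookup(element)[1]

    def _lookup(self, element: str) -> tuple[float, float]:
        try:
            return self._table[element]
        except KeyError:
            raise KeyError(
                f"element {element!r} missing from the IP/EA table") from None


@dataclass
class QnaAtomValues:
    """P, Q values for the heavy atoms of one molecule (molecule order)."""

    heavy_indices: list[int]
    p: np.ndarray
    q: np.ndarray


def qna_atom_values(mol: Molecule, props: ElementProperties | None = None
                    ) -> QnaAtomValues:
    """Compute per-heavy-atom (P, Q) via the connectivity-matrix exponential."""
    props = props or ElementProperties.default()
    heavy = mol.heavy_atom_indices()
    if not heavy:
        raise ValueError("molecule has no heavy atoms")
    elements = [mol.atoms[i].element for i in heavy]
    for el in elements:
        if el not in props:
            raise KeyError(f"element {el!r} missing from the IP/EA table")
    ip = np.array([props.ip(el) for el in elements])
    ea = np.array([props.ea(el) for el in elements])
    a_vec = 0.5 * (ip + ea)
    b_vec = ip - ea
    c = mol.adjacency[np.ix_(heavy, heavy)].astype(float)
    # exp(−C) through the symmetric eigendecomposition
    w, v = eigh(-c)
    e = (v * np.exp(w)) @ v.T
    b_isqrt = 1.0 / np.sqrt(b_vec)
    p = b_isqrt * (e @ (b_isqrt * a_vec))
    q = b_isqrt * (e @ b_isqrt)
    return QnaAtomValues(heavy_indices=list(heavy), p=p, q=q)


@dataclass(frozen=True)
class QnaFeatureSpec:
    """Feature recipe carried with every trained model."""

    max_degree: int = DEFAULT_MAX_DEGREE
    p_bounds: tuple[float, float] = (-1.0, 1.0)
    q_bounds: tuple[float, float] = (-1.0, 1.0)

    @property
    def n_features(self) -> int:
        d = self.max_degree
        return (d + 1) * (d + 2) // 2

    @property
    def degree_pairs(self) -> list[tuple[int, int]]:
        return [(j, k) for j in range(self.max_degree + 1)
                for k in range(self.max_degree + 1 - j)]


def fit_qna_bounds(mols: Sequence[Molecule],
                   props: ElementProperties | None = None,
                   max_degree: int = DEFAULT_MAX_DEGREE) -> QnaFeatureSpec:
    """Training-set (min, max) bounds of P and Q for the affine scaling."""
    props = props or ElementProperties.default()
    ps, qs = [], []
    for m in mols:
        vals = qna_atom_values(m, props)
        ps.append(vals.p)
        qs.append(vals.q)
    p_all = np.concatenate(ps)
    q_all = np.concatenate(qs)
    return QnaFeatureSpec(max_degree=max_degree,
                          p_bounds=(float(p_all.min()), float(p_all.max())),
                          q_bounds=(float(q_all.min()), float(q_all.max())))


def _scale(x: np.ndarray, bounds: tuple[float, float]) -> np.ndarray:
    lo, hi = bounds
    if hi <= lo:
        warnings.warn("degenerate scaling bounds (min == max); coordinate "
                      "maps to 0", stacklevel=2)
        return np.zeros_like(x)
    return np.clip(2.0 * (x - lo) / (hi - lo) - 1.0, -1.0, 1.0)


def _cheb_t(x: np.ndarray, max_degree: int) -> np.ndarray:
    """T_0..T_max_degree evaluated at x; shape (len(x), max_degree+1)."""
    cols = []
    for j in range(max_degree + 1):
        coef = np.zeros(j + 1)
        coef[j] = 1.0
        cols.append(_cheb.chebval(x, coef))
    return np.stack(cols, axis=1)


def qna_features(mol: Molecule, props: ElementProperties | None,
                 spec: QnaFeatureSpec) -> np.ndarray:
    """Molecule-level QNA feature vector: atom means of T_j(P̃)·T_k(Q̃)."""
    vals = qna_atom_values(mol, props or ElementProperties.default())
    p_t = _cheb_t(_scale(vals.p, spec.p_bounds), spec.max_degree)
    q_t = _cheb_t(_scale(vals.q, spec.q_bounds), spec.max_degree)
    feats = [np.mean(p_t[:, j] * q_t[:, k]) for j, k in spec.degree_pairs]
    return np.asarray(feats)


def mna_count_features(mol_descriptors: MnaSet | Molecule,
                       vocab: MnaVocabulary, top_m: int,
                       max_level: int = 2) -> np.ndarray:
    """Binary presence vector over the top_m most frequent training MNA
    descriptors."""
    if top_m > len(vocab):
        warnings.warn(f"top_m={top_m} exceeds vocabulary size {len(vocab)}; "
                      "truncated", stacklevel=2)
        top_m = len(vocab)
    ds = mol_descriptors if isinstance(mol_descriptors, MnaSet) \
        else mna_set(mol_descriptors, max_level)
    top = vocab.top_by_frequency(top_m)
    return np.array([1.0 if t in ds else 0.0 for t in top])
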