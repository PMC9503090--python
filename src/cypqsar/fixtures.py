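"""Seeded synthetic bioactivity data with planted structure–activity signal.

Molecules are assembled from a small library of RDKit-sanitizable ring
scaffolds (benzene, pyridine, cyclohexane, furan) decorated at up to two
sites with common medicinal-chemistry fragments (halogen, amino, hydroxy,
alkyl, nitrile, trifluoromethyl, ...). The library lives in packaged CSV
data, not code.

Planted signal:

* classification — a molecule is truly active iff it carries a
  pharmacophore decoration (Cl, Br or CF3); observed labels flip with
  probability ε;
* regression — pIC50 = scaffold base value + Σ decoration contributions
  + Gaussian(0, σ).

The raw-table generator emits the same two delimited dialects the
curation module reads (ChEMBL-export style and PubChem-bioassay style),
deliberately exercising every curation rule: each relation sign, IC50
values at and around the 10,000 / 20,000 nM cuts, % inhibition at and
around 50%, a planted inhibitor/noninhibitor conflict pair, duplicate
structures for median aggregation, and "Complete curve" annotations.

These fixtures validate machinery, not chemistry: they make no attempt
to mimic real CYP structure–activity relationships.
"""

from __future__ import annotations

import importlib.resources
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .chem_model import Molecule, parse_smiles
from .curation import ActivityRecord, ClassificationSet, RegressionSet

DEFAULT_N_MOLECULES = 120
DEFAULT_SIGMA = 0.3


def _load_library() -> tuple[pd.DataFrame, pd.DataFrame]:
    data = importlib.resources.files("cypqsar.data")
    scaffolds = pd.read_csv(data / "fixture_scaffolds.csv")
    decorations = pd.read_csv(data / "fixture_decorations.csv",
                              keep_default_na=False)
    return scaffolds, decorations


@dataclass(frozen=True)
class FixtureSpec:
    """Generation recipe; identical specs produce byte-identical output."""

    n_molecules: int = DEFAULT_N_MOLECULES
    seed: int = 0
    epsilon: float = 0.0  # classification label-flip probability
    sigma: float = DEFAULT_SIGMA  # regression noise SD (pIC50 units)
    isoform: str = "3A4"

    def __post_init__(self):
        if not (0.0 <= self.epsilon < 0.5):
            raise ValueError("epsilon must be in [0, 0.5)")
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")
        if self.n_molecules < 10:
            raise ValueError("n_molecules must be >= 10")


@dataclass
class GeneratedMolecule:
    molecule: Molecule
    scaffold: str
    decorations: tuple[str, str]
    has_pharmacophore: bool
    true_value: float  # noiseless pIC50


def _assemble_smiles(template: str, frag_a: str, frag_b: str) -> str:
    s = template
    s = s.replace("({a})", f"({frag_a})" if frag_a else "")
    s = s.replace("({b})", f"({frag_b})" if frag_b else "")
    return s


def generate_molecules(spec: FixtureSpec) -> list[GeneratedMolecule]:
    """Seeded sample of unique decorated scaffolds with their noiseless
    planted values."""
    scaffolds, decorations = _load_library()
    rng = np.random.default_rng(spec.seed)
    contr = dict(zip(decorations.fragment, decorations.contribution))
    pharma = {f for f, p in zip(decorations.fragment,
                                decorations.pharmacophore) if p == 1}
    frags = list(decorations.fragment)
    out: list[GeneratedMolecule] = []
    seen: set[str] = set()
    attempts = 0
    while len(out) < spec.n_molecules and attempts < 50 * spec.n_molecules:
        attempts += 1
        srow = scaffolds.iloc[int(rng.integers(len(scaffolds)))]
        fa = frags[int(rng.integers(len(frags)))]
        fb = frags[int(rng.integers(len(frags)))]
        smi = _assemble_smiles(srow.template, fa, fb)
        try:
            mol = parse_smiles(smi, mol_id=f"FX{len(out):04d}")
        except ValueError:
            continue
        if mol.smiles in seen:
            continue
        seen.add(mol.smiles)
        out.append(GeneratedMolecule(
            molecule=mol, scaffold=srow["name"], decorations=(fa, fb),
            has_pharmacophore=(fa in pharma or fb in pharma),
            true_value=float(srow.base_value + contr[fa] + contr[fb])))
    if len(out) < spec.n_molecules:
        raise ValueError("scaffold library exhausted before reaching "
                         f"{spec.n_molecules} unique molecules")
    return out


def gen_classification_fixture(spec: FixtureSpec
                               ) -> tuple[ClassificationSet, list[int]]:
    """Returns the observed (possibly flipped) set and the ground truth."""
    gens = generate_molecules(spec)
    rng = np.random.default_rng(spec.seed + 1)
    truth = [1 if g.has_pharmacophore else 0 for g in gens]
    flips = rng.random(len(gens)) < spec.epsilon
    observed = [int(t ^ int(f)) for t, f in zip(truth, flips)]
    if len(set(observed)) < 2:
        raise ValueError("fixture yielded a single class; adjust the spec")
    entries = [(g.molecule, y) for g, y in zip(gens, observed)]
    cset = ClassificationSet(
        isoform=spec.isoform, entries=entries,
        n_pos=sum(observed), n_neg=len(observed) - sum(observed))
    return cset, truth


def gen_regression_fixture(spec: FixtureSpec
                           ) -> tuple[RegressionSet, dict]:
    """Returns the noisy set and the true generative parameters."""
    gens = generate_molecules(spec)
    rng = np.random.default_rng(spec.seed + 2)
    noise = rng.normal(0.0, spec.sigma, size=len(gens))
    entries = [(g.molecule, g.true_value + float(e))
               for g, e in zip(gens, noise)]
    values = [y for _, y in entries]
    rset = RegressionSet(isoform=spec.isoform, entries=entries,
                         value_interval=(min(values), max(values)),
                         mean_value=float(np.mean(values)))
    _, decorations = _load_library()
    truth = {
        "true_values": [g.true_value for g in gens],
        "noise": noise.tolist(),
        "contributions": dict(zip(decorations.fragment,
                                  decorations.contribution)),
        "sigma": spec.sigma,
    }
    return rset, truth


# ---------------------------------------------------------------------------
# Raw table dialects

#: iodoarenes reserved for hand-planted curation rows — iodine never occurs
#: in the decoration library, so these cannot collide with seeded molecules
_PLANT_CONFLICT = "Ic1ccccc1"
_PLANT_MEDIAN = "Ic1ccc(I)cc1"
_PLANT_BOUNDARY = ["Ic1ccc(C)cc1", "Ic1ccc(N)cc1", "Ic1ccc(O)cc1",
                   "Ic1ccc(Cl)cc1", "Ic1ccc(CC)cc1", "Ic1ccc(C#N)cc1"]
_PLANT_PERCENT = ["Ic1ccc(OC)cc1", "Ic1ccc(Br)cc1", "Ic1cccc(C)c1"]


def gen_raw_tables(spec: FixtureSpec, out_dir) -> dict[str, Path]:
    """Write one ChEMBL-dialect and one PubChem-dialect table exercising
    every curation rule, plus a truth sidecar of intended labels."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    gens = generate_molecules(spec)
    rng = np.random.default_rng(spec.seed + 3)
    iso = spec.isoform

    chembl_rows: list[dict] = []
    pubchem_rows: list[dict] = []
    truth_rows: list[dict] = []

    def crow(cid, smi, stype, rel, val):
        chembl_rows.append({
            "compound_id": cid, "smiles": smi, "standard_type": stype,
            "standard_relation": rel, "standard_value": val,
            "standard_units": "nM" if stype == "IC50" else "%",
            "isoform": iso})

    # seeded molecules: IC50 rows from the planted pIC50 (nM = 10^(9−pIC50))
    for i, g in enumerate(gens):
        noise = float(rng.normal(0.0, spec.sigma))
        pic50 = g.true_value + noise
        nm = 10.0 ** (9.0 - pic50)
        crow(f"CH{i:04d}", g.molecule.smiles, "IC50", "=", round(nm, 3))
        intended = "inhibitor" if nm < 10_000 else (
            "noninhibitor" if nm > 20_000 else "indeterminate")
        truth_rows.append({"compound_id": f"CH{i:04d}",
                           "smiles": g.molecule.smiles,
                           "intended_label": intended,
                           "intended_pic50": round(pic50, 6)})
        # PubChem dialect echoes the truth with curve annotations
        active = g.has_pharmacophore
        pubchem_rows.append({
            "compound_id": f"PC{i:04d}", "smiles": g.molecule.smiles,
            "activity_outcome": "active" if active else "inactive",
            "curve_class": "Complete curve" if active else "",
            "isoform": iso})

    # boundary rows: cuts at 10,000 / 20,000 nM and each relation sign
    b = _PLANT_BOUNDARY
    crow("BND-9999", b[0], "IC50", "=", 9_999.0)     # inhibitor
    crow("BND-10000", b[1], "IC50", "=", 10_000.0)   # gap: indeterminate
    crow("BND-20000", b[2], "IC50", "=", 20_000.0)   # gap: indeterminate
    crow("BND-20001", b[3], "IC50", ">", 20_001.0)   # noninhibitor
    crow("BND-LT", b[4], "IC50", "<", 5_000.0)       # inhibitor (sign ok)
    crow("BND-GE", b[5], "IC50", ">=", 50_000.0)     # noninhibitor (sign ok)
    for cid, smi, lab in [("BND-9999", b[0], "inhibitor"),
                          ("BND-10000", b[1], "indeterminate"),
                          ("BND-20000", b[2], "indeterminate"),
                          ("BND-20001", b[3], "noninhibitor"),
                          ("BND-LT", b[4], "inhibitor"),
                          ("BND-GE", b[5], "noninhibitor")]:
        truth_rows.append({"compound_id": cid, "smiles": smi,
                           "intended_label": lab, "intended_pic50": ""})

    # % inhibition rows at and around the 50% cut
    pct = _PLANT_PERCENT
    crow("PCT-51", pct[0], "Inhibition", "=", 51.0)  # inhibitor
    crow("PCT-50", pct[1], "Inhibition", "=", 50.0)  # noninhibitor (not >50)
    crow("PCT-49", pct[2], "Inhibition", "=", 49.0)  # noninhibitor
    for cid, smi, lab in [("PCT-51", pct[0], "inhibitor"),
                          ("PCT-50", pct[1], "noninhibitor"),
                          ("PCT-49", pct[2], "noninhibitor")]:
        truth_rows.append({"compound_id": cid, "smiles": smi,
                           "intended_label": lab, "intended_pic50": ""})

    # planted conflict pair: same structure, both rules fire → removed
    crow("CONF-A", _PLANT_CONFLICT, "IC50", "=", 5_000.0)
    crow("CONF-B", _PLANT_CONFLICT, "IC50", "=", 25_000.0)
    truth_rows.append({"compound_id": "CONF-A/CONF-B",
                       "smiles": _PLANT_CONFLICT,
                       "intended_label": "conflict_removed",
                       "intended_pic50": ""})

    # planted duplicate trio for median aggregation → pIC50 6.0
    for j, nm in enumerate((100.0, 1_000.0, 10_000.0)):
        crow(f"DUP-{j}", _PLANT_MEDIAN, "IC50", "=", nm)
    truth_rows.append({"compound_id": "DUP-*", "smiles": _PLANT_MEDIAN,
                       "intended_label": "median_pic50",
                       "intended_pic50": 6.0})

    # PubChem: one active lacking curve support → indeterminate
    pubchem_rows.append({"compound_id": "PC-NOCURVE", "smiles": b[0],
                         "activity_outcome": "active", "curve_class": "",
                         "isoform": iso})

    paths = {
        "chembl": out / "chembl_dialect.csv",
        "pubchem": out / "pubchem_dialect.csv",
        "truth": out / "truth.csv",
    }
    pd.DataFrame(chembl_rows).to_csv(paths["chembl"], index=False)
    pd.DataFrame(pubchem_rows).to_csv(paths["pubchem"], index=False)
    pd.DataFrame(truth_rows).to_csv(paths["truth"], index=False)
    return paths
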