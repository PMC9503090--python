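"""Bioactivity-record curation into classification and regression sets.

Raw CYP inhibition records come in two dialects: a ChEMBL-export style
(IC50 in nM with a relation sign, or % inhibition at a single
concentration) and a PubChem-bioassay style (an activity outcome backed,
or not, by a complete concentration-response curve). The rules here turn
them into per-isoform training sets:

* ChEMBL IC50 < 10,000 nM (relation =, ≤, <) → inhibitor;
  IC50 > 20,000 nM (relation =, ≥, >) → noninhibitor; the 10–20 µM gap
  and sign-incompatible records are indeterminate.
* ChEMBL % inhibition > 50 → inhibitor, otherwise noninhibitor.
* PubChem outcome "active" backed by a complete curve → inhibitor;
  outcome "inactive" → noninhibitor; active without curve support is
  indeterminate.
* Structures carrying both labels are removed entirely (conflicts);
  same-label duplicates collapse to one entry.
* The regression endpoint keeps only relation "=" IC50 records, takes the
  per-structure median on the nM scale, and converts to
  pIC50 = −log10(IC50 in M).
"""

from __future__ import annotations

import logging
import math
import statistics
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .chem_model import Molecule, StandardizationPolicy, DEFAULT_POLICY, \
    parse_smiles, molecules_to_sdf

logger = logging.getLogger(__name__)

ISOFORMS = ("1A2", "2C9", "2C19", "2D6", "3A4")

# Curation thresholds (overridable through ReportConfig / CLI config).
IC50_INHIBITOR_NM = 10_000.0
IC50_NONINHIBITOR_NM = 20_000.0
PERCENT_INHIBITION_CUT = 50.0

_INHIBITOR_RELATIONS = {"=", "<", "<=", "≤"}
_NONINHIBITOR_RELATIONS = {"=", ">", ">=", "≥"}


class ClassLabel(str, Enum):
    INHIBITOR = "inhibitor"
    NONINHIBITOR = "noninhibitor"
    INDETERMINATE = "indeterminate"


@dataclass(frozen=True)
class ActivityRecord:
    """One raw bioactivity measurement."""

    compound_id: str
    smiles: str
    isoform: str
    endpoint: str  # "ic50" | "percent_inhibition" | "outcome"
    value: float | None = None  # nM for ic50, % for percent_inhibition
    relation: str | None = None
    outcome_flag: str | None = None  # "active" | "inactive" | None
    curve_flag: str | None = None  # "complete_curve" | "other" | None
    source: str = "chembl"  # "chembl" | "pubchem"

    def __post_init__(self):
        if self.endpoint == "ic50" and self.value is not None \
                and self.value <= 0:
            raise ValueError(f"IC50 must be positive, got {self.value}")
        if self.endpoint == "percent_inhibition" and self.value is not None:
            if not (-100.0 <= self.value <= 200.0):
                raise ValueError(
                    f"% inhibition {self.value} outside accepted [-100, 200]")
            if not (0.0 <= self.value <= 100.0):
                logger.warning("%% inhibition %s for %s outside [0, 100]",
                               self.value, self.compound_id)


@dataclass
class ClassificationSet:
    """Per-isoform binary training set with provenance counts."""

    isoform: str
    entries: list[tuple[Molecule, int]]  # label 1 = inhibitor, 0 = noninhibitor
    n_pos: int = 0
    n_neg: int = 0
    n_conflicts_removed: int = 0
    n_indeterminate: int = 0

    @property
    def molecules(self) -> list[Molecule]:
        return [m for m, _ in self.entries]

    @property
    def labels(self) -> list[int]:
        return [y for _, y in self.entries]


@dataclass
class RegressionSet:
    """Per-isoform (structure, pIC50) set after median aggregation."""

    isoform: str
    entries: list[tuple[Molecule, float]]
    value_interval: tuple[float, float] = (math.nan, math.nan)
    mean_value: float = math.nan

    @property
    def molecules(self) -> list[Molecule]:
        return [m for m, _ in self.entries]

    @property
    def values(self) -> list[float]:
        return [y for _, y in self.entries]


def pic50_from_nM(ic50_nm: float) -> float:
    """pIC50 = −log10(IC50 in molar), IC50 given in nM."""
    if ic50_nm <= 0:
        raise ValueError(f"IC50 must be positive, got {ic50_nm}")
    return -math.log10(ic50_nm * 1e-9)


def label_chembl_record(rec: ActivityRecord,
                        ic50_inhibitor_nm: float = IC50_INHIBITOR_NM,
                        ic50_noninhibitor_nm: float = IC50_NONINHIBITOR_NM,
                        percent_cut: float = PERCENT_INHIBITION_CUT
                        ) -> ClassLabel:
    """Apply the IC50 / % inhibition classification rules to a ChEMBL-dialect
    record. Records in the 10–20 µM gap, or whose relation sign is not
    compatible with the rule's direction, are indeterminate."""
    if rec.source != "chembl":
        raise ValueError("label_chembl_record requires a chembl-dialect record")
    if rec.endpoint == "ic50":
        if rec.value is None:
            logger.warning("IC50 record %s has no value; indeterminate",
                           rec.compound_id)
            return ClassLabel.INDETERMINATE
        rel = (rec.relation or "=").strip()
        if rec.value < ic50_inhibitor_nm and rel in _INHIBITOR_RELATIONS:
            return ClassLabel.INHIBITOR
        if rec.value > ic50_noninhibitor_nm and rel in _NONINHIBITOR_RELATIONS:
            return ClassLabel.NONINHIBITOR
        return ClassLabel.INDETERMINATE
    if rec.endpoint == "percent_inhibition":
        if rec.value is None:
            logger.warning("%% inhibition record %s has no value; "
                           "indeterminate", rec.compound_id)
            return ClassLabel.INDETERMINATE
        return ClassLabel.INHIBITOR if rec.value > percent_cut \
            else ClassLabel.NONINHIBITOR
    return ClassLabel.INDETERMINATE


def label_pubchem_record(rec: ActivityRecord) -> ClassLabel:
    """Outcome "active" backed by a complete curve → inhibitor; "inactive"
    → noninhibitor; anything else indeterminate."""
    if rec.source != "pubchem":
        raise ValueError("label_pubchem_record requires a pubchem-dialect "
                         "record")
    if rec.outcome_flag == "active" and rec.curve_flag == "complete_curve":
        return ClassLabel.INHIBITOR
    if rec.outcome_flag == "inactive":
        return ClassLabel.NONINHIBITOR
    return ClassLabel.INDETERMINATE


def label_record(rec: ActivityRecord, **thresholds) -> ClassLabel:
    if rec.source == "chembl":
        return label_chembl_record(rec, **thresholds)
    return label_pubchem_record(rec)


def build_classification_set(records: Iterable[ActivityRecord], isoform: str,
                             policy: StandardizationPolicy = DEFAULT_POLICY,
                             **thresholds) -> ClassificationSet:
    """Label records, drop indeterminates, remove conflicting structures
    entirely and collapse same-label duplicates to one entry."""
    by_structure: dict[str, dict] = {}
    n_indet = 0
    for rec in records:
        if rec.isoform != isoform:
            continue
        lab = label_record(rec, **thresholds)
        if lab is ClassLabel.INDETERMINATE:
            n_indet += 1
            continue
        mol = parse_smiles(rec.smiles, policy, mol_id=rec.compound_id)
        entry = by_structure.setdefault(mol.smiles, {"mol": mol,
                                                     "labels": set()})
        entry["labels"].add(lab)
    entries: list[tuple[Molecule, int]] = []
    n_conflicts = 0
    for key in sorted(by_structure):
        info = by_structure[key]
        if len(info["labels"]) > 1:
            n_conflicts += 1
            continue
        lab = next(iter(info["labels"]))
        entries.append((info["mol"], 1 if lab is ClassLabel.INHIBITOR else 0))
    if not entries:
        raise ValueError(f"no usable classification records for CYP {isoform}")
    n_pos = sum(y for _, y in entries)
    return ClassificationSet(isoform=isoform, entries=entries, n_pos=n_pos,
                             n_neg=len(entries) - n_pos,
                             n_conflicts_removed=n_conflicts,
                             n_indeterminate=n_indet)


def build_regression_set(records: Iterable[ActivityRecord], isoform: str,
                         policy: StandardizationPolicy = DEFAULT_POLICY
                         ) -> RegressionSet:
    """Keep only relation "=" IC50 records from the ChEMBL dialect, take the
    per-structure median on the nM scale, convert to pIC50."""
    by_structure: dict[str, dict] = {}
    for rec in records:
        if rec.isoform != isoform or rec.source != "chembl":
            continue
        if rec.endpoint != "ic50" or rec.value is None:
            continue
        if (rec.relation or "").strip() != "=":
            continue
        mol = parse_smiles(rec.smiles, policy, mol_id=rec.compound_id)
        entry = by_structure.setdefault(mol.smiles, {"mol": mol, "vals": []})
        entry["vals"].append(float(rec.value))
    if not by_structure:
        raise ValueError(f"no usable regression records for CYP {isoform}")
    entries = []
    for key in sorted(by_structure):
        info = by_structure[key]
        median_nm = statistics.median(info["vals"])
        entries.append((info["mol"], pic50_from_nM(median_nm)))
    values = [y for _, y in entries]
    return RegressionSet(isoform=isoform, entries=entries,
                         value_interval=(min(values), max(values)),
                         mean_value=sum(values) / len(values))


# ---------------------------------------------------------------------------
# Table dialect I/O

CHEMBL_COLUMNS = {
    "compound_id": "compound_id", "smiles": "smiles",
    "standard_type": "standard_type", "standard_relation": "standard_relation",
    "standard_value": "standard_value", "standard_units": "standard_units",
    "isoform": "isoform",
}
PUBCHEM_COLUMNS = {
    "compound_id": "compound_id", "smiles": "smiles",
    "activity_outcome": "activity_outcome", "curve_class": "curve_class",
    "isoform": "isoform",
}


def read_chembl_table(path, column_map: dict | None = None
                      ) -> list[ActivityRecord]:
    """Read a ChEMBL-dialect delimited table (CSV/TSV, header required)."""
    cols = dict(CHEMBL_COLUMNS, **(column_map or {}))
    df = _read_delimited(path)
    records = []
    for _, row in df.iterrows():
        st = str(row[cols["standard_type"]]).strip().lower()
        if st in ("ic50",):
            endpoint = "ic50"
        elif st in ("inhibition", "percent_inhibition", "% inhibition"):
            endpoint = "percent_inhibition"
        else:
            logger.warning("unknown standard_type %r; record skipped", st)
            continue
        records.append(ActivityRecord(
            compound_id=str(row[cols["compound_id"]]),
            smiles=str(row[cols["smiles"]]),
            isoform=str(row[cols["isoform"]]),
            endpoint=endpoint,
            value=float(row[cols["standard_value"]]),
            relation=str(row[cols["standard_relation"]]).strip(),
            source="chembl"))
    return records


def read_pubchem_table(path, column_map: dict | None = None
                       ) -> list[ActivityRecord]:
    """Read a PubChem-bioassay-dialect delimited table."""
    cols = dict(PUBCHEM_COLUMNS, **(column_map or {}))
    df = _read_delimited(path)
    records = []
    for _, row in df.iterrows():
        curve = str(row[cols["curve_class"]]).strip().lower()
        curve_flag = "complete_curve" if curve in ("complete curve",
                                                   "complete_curve") else \
            ("other" if curve and curve != "nan" else None)
        records.append(ActivityRecord(
            compound_id=str(row[cols["compound_id"]]),
            smiles=str(row[cols["smiles"]]),
            isoform=str(row[cols["isoform"]]),
            endpoint="outcome",
            outcome_flag=str(row[cols["activity_outcome"]]).strip().lower(),
            curve_flag=curve_flag,
            source="pubchem"))
    return records


def _read_delimited(path) -> pd.DataFrame:
    path = str(path)
    sep = "\t" if path.endswith((".tsv", ".tab")) else ","
    return pd.read_csv(path, sep=sep)


def write_curated_sets(out_dir, classification: ClassificationSet | None,
                       regression: RegressionSet | None) -> None:
    """Write curated sets as SD files with class / pIC50 data fields plus a
    CSV audit log of provenance counts."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    audit_rows = []
    if classification is not None:
        mols = classification.molecules
        props = [{"CLASS": "inhibitor" if y else "noninhibitor",
                  "CYP": classification.isoform}
                 for y in classification.labels]
        molecules_to_sdf(mols, str(out / f"cyp{classification.isoform}_class.sdf"),
                         props)
        audit_rows.append({
            "isoform": classification.isoform, "set": "classification",
            "n_pos": classification.n_pos, "n_neg": classification.n_neg,
            "n_conflicts_removed": classification.n_conflicts_removed,
            "n_indeterminate": classification.n_indeterminate})
    if regression is not None:
        props = [{"pIC50": f"{y:.4f}", "CYP": regression.isoform}
                 for y in regression.values]
        molecules_to_sdf(regression.molecules,
                         str(out / f"cyp{regression.isoform}_pic50.sdf"), props)
        lo, hi = regression.value_interval
        audit_rows.append({
            "isoform": regression.isoform, "set": "regression",
            "n_compounds": len(regression.entries),
            "pic50_min": round(lo, 4), "pic50_max": round(hi, 4),
            "pic50_mean": round(regression.mean_value, 4)})
    pd.DataFrame(audit_rows).to_csv(out / "audit.csv", index=False)
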