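"""The three-table prediction report.

For one query molecule the report combines:

* table A (qsar) — per-isoform numerical pIC50 from the consensus QSAR
  models, with an applicability-domain flag; a compound is flagged a
  potential inhibitor of an isoform when its predicted pIC50 exceeds 6
  *and* the prediction is inside the applicability domain;
* table B (inhibitor) — classifier activities "CYP x inhibitor" filtered
  to Pa > Pi (the table is legitimately empty when nothing passes);
* table C (inducer) — same schema for user-supplied inducer activities.

All thresholds are carried in :class:`ReportConfig` and default to the
package-wide constants; missing model components degrade gracefully to a
"not available" table.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import pandas as pd
import yaml

from .chem_model import Molecule
from .curation import ClassificationSet, RegressionSet
from .gusar_qsar import ConsensusModel, build_consensus, consensus_predict
from .pass_classifier import PassModel, fit as pass_fit, predict_profile

PIC50_POTENTIAL_INHIBITOR = 6.0


@dataclass(frozen=True)
class ReportConfig:
    """Every decision threshold of the pipeline, overridable from YAML."""

    ic50_inhibitor_nm: float = 10_000.0
    ic50_noninhibitor_nm: float = 20_000.0
    percent_inhibition_cut: float = 50.0
    r2_min: float = 0.6
    q2_min: float = 0.5
    ad_novelty_threshold: float = 0.25
    pic50_potential_inhibitor: float = PIC50_POTENTIAL_INHIBITOR

    @classmethod
    def from_yaml(cls, path) -> "ReportConfig":
        doc = yaml.safe_load(Path(path).read_text()) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(doc) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**doc)


@dataclass
class ModelBundle:
    """Per-isoform consensus QSAR models plus inhibitor/inducer classifiers."""

    qsar: dict[str, ConsensusModel] = field(default_factory=dict)
    inhibitor_model: PassModel | None = None
    inducer_model: PassModel | None = None

    def __post_init__(self):
        if not self.qsar and self.inhibitor_model is None \
                and self.inducer_model is None:
            raise ValueError("empty model bundle")


@dataclass
class Report:
    molecule_id: str
    smiles: str
    table_qsar: list[dict] | None  # None = component not available
    table_inhibitor: list[dict] | None
    table_inducer: list[dict] | None

    def to_json(self) -> str:
        return json.dumps({
            "molecule_id": self.molecule_id, "smiles": self.smiles,
            "table_qsar": self.table_qsar,
            "table_inhibitor": self.table_inhibitor,
            "table_inducer": self.table_inducer})

    @classmethod
    def from_json(cls, text: str) -> "Report":
        doc = json.loads(text)
        return cls(molecule_id=doc["molecule_id"], smiles=doc["smiles"],
                   table_qsar=doc["table_qsar"],
                   table_inhibitor=doc["table_inhibitor"],
                   table_inducer=doc["table_inducer"])

    def write_csv(self, out_dir) -> dict[str, Path]:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        written = {}
        schemas = {
            "qsar": (self.table_qsar,
                     ["isoform", "pic50", "in_ad", "potential_inhibitor"]),
            "inhibitor": (self.table_inhibitor,
                          ["activity", "pa", "pi"]),
            "inducer": (self.table_inducer, ["activity", "pa", "pi"]),
        }
        for name, (table, cols) in schemas.items():
            path = out / f"table_{name}.csv"
            if table is None:
                path.write_text("# not available\n")
            else:
                pd.DataFrame(table, columns=cols).to_csv(path, index=False)
            written[name] = path
        return written


def _qsar_rows(bundle: ModelBundle, mol: Molecule, config: ReportConfig
               ) -> list[dict] | None:
    if not bundle.qsar:
        return None
    rows = []
    for isoform in sorted(bundle.qsar):
        pred = consensus_predict(bundle.qsar[isoform], mol)
        potential = (pred.value is not None
                     and pred.value > config.pic50_potential_inhibitor
                     and pred.in_ad)
        rows.append({"isoform": isoform, "pic50": pred.value,
                     "in_ad": pred.in_ad,
                     "potential_inhibitor": bool(potential)})
    return rows


def _profile_rows(model: PassModel | None, mol: Molecule) -> list[dict] | None:
    if model is None:
        return None
    preds = predict_profile(model, mol)
    return [{"activity": p.activity, "pa": p.pa, "pi": p.pi}
            for p in preds if p.pa > p.pi]


def predict_report(bundle: ModelBundle, mol: Molecule,
                   config: ReportConfig = ReportConfig()) -> Report:
    """Populate the three tables for one standardized molecule."""
    return Report(
        molecule_id=mol.id, smiles=mol.smiles,
        table_qsar=_qsar_rows(bundle, mol, config),
        table_inhibitor=_profile_rows(bundle.inhibitor_model, mol),
        table_inducer=_profile_rows(bundle.inducer_model, mol))


@dataclass
class TrainingRegistries:
    """The training sets behind a bundle, for honest external prediction."""

    qsar: dict[str, RegressionSet] = field(default_factory=dict)
    inhibitor: dict[str, ClassificationSet] = field(default_factory=dict)
    inducer: dict[str, ClassificationSet] = field(default_factory=dict)


def _without_structure(entries: list, smiles: str) -> list:
    return [(m, y) for m, y in entries if m.smiles != smiles]


def exclude_and_predict(bundle: ModelBundle, mol: Molecule,
                        registries: TrainingRegistries,
                        config: ReportConfig = ReportConfig()) -> Report:
    """Predict with the query removed from every training set it occurs in.

    Affected models are refitted without the structure before prediction,
    so a training compound is assessed as an external query rather than
    reinforcing itself. Molecules absent from every registry yield the
    same report as :func:`predict_report`.
    """
    eff = ModelBundle.__new__(ModelBundle)
    eff.qsar = dict(bundle.qsar)
    eff.inhibitor_model = bundle.inhibitor_model
    eff.inducer_model = bundle.inducer_model

    for isoform, reg_set in registries.qsar.items():
        if isoform not in eff.qsar:
            continue
        kept = _without_structure(reg_set.entries, mol.smiles)
        if len(kept) == len(reg_set.entries):
            continue
        vals = [y for _, y in kept]
        reduced = RegressionSet(isoform=isoform, entries=kept,
                                value_interval=(min(vals), max(vals)),
                                mean_value=sum(vals) / len(vals))
        old = eff.qsar[isoform]
        eff.qsar[isoform] = build_consensus(
            reduced, old.n_candidates, old.seed,
            r2_min=old.r2_min, q2_min=old.q2_min)

    for attr, registry in (("inhibitor_model", registries.inhibitor),
                           ("inducer_model", registries.inducer)):
        model = getattr(eff, attr)
        if model is None or not registry:
            continue
        touched = False
        reduced_sets = {}
        for act, cset in registry.items():
            kept = _without_structure(cset.entries, mol.smiles)
            if len(kept) != len(cset.entries):
                touched = True
            n_pos = sum(y for _, y in kept)
            reduced_sets[act] = ClassificationSet(
                isoform=cset.isoform, entries=kept, n_pos=n_pos,
                n_neg=len(kept) - n_pos)
        if touched:
            setattr(eff, attr, pass_fit(reduced_sets,
                                        max_level=model.max_level,
                                        ad_threshold=model.ad_threshold))
    return predict_report(eff, mol, config)
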