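"""Versioned plain-text (JSON) model archives.

Each archive is a single JSON document with a ``format`` tag and a
``version`` so future readers can refuse what they do not understand.
Arrays are stored as nested lists; vocabularies as (descriptor, index,
document-frequency) triples.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .gusar_qsar import ConsensusModel, SubModel, SubModelConfig
from .mna import MnaVocabulary
from .pass_classifier import PassModel, PassStats
from .qna import QnaFeatureSpec

FORMAT_VERSION = 1


def _vocab_to_obj(vocab: MnaVocabulary) -> list:
    df = vocab.to_frame()
    return df.values.tolist()  # [index, descriptor, doc_freq]


def _vocab_from_obj(obj: list) -> MnaVocabulary:
    index = {row[1]: int(row[0]) for row in obj}
    freq = {row[1]: int(row[2]) for row in obj}
    return MnaVocabulary(index, freq)


def save_pass_model(model: PassModel, path) -> None:
    doc = {
        "format": "cypqsar-pass-model", "version": FORMAT_VERSION,
        "max_level": model.max_level,
        "ad_threshold": model.ad_threshold,
        "vocabulary": _vocab_to_obj(model.vocab),
        "activities": {},
    }
    for act, st in model.stats.items():
        pos_scores, neg_scores = model.loo_scores[act]
        doc["activities"][act] = {
            "n_pos": st.n_pos, "n_neg": st.n_neg,
            "pos_counts": st.pos_counts, "neg_counts": st.neg_counts,
            "loo_pos": sorted(pos_scores.tolist()),
            "loo_neg": sorted(neg_scores.tolist()),
        }
    Path(path).write_text(json.dumps(doc))


def load_pass_model(path) -> PassModel:
    doc = json.loads(Path(path).read_text())
    if doc.get("format") != "cypqsar-pass-model":
        raise ValueError(f"{path}: not a classifier archive")
    if doc.get("version") > FORMAT_VERSION:
        raise ValueError(f"{path}: unsupported archive version")
    stats, loo = {}, {}
    for act, obj in doc["activities"].items():
        stats[act] = PassStats(obj["n_pos"], obj["n_neg"],
                               dict(obj["pos_counts"]),
                               dict(obj["neg_counts"]))
        loo[act] = (np.asarray(obj["loo_pos"]), np.asarray(obj["loo_neg"]))
    return PassModel(stats, _vocab_from_obj(doc["vocabulary"]), loo,
                     doc["max_level"], ad_threshold=doc["ad_threshold"])


def _submodel_to_obj(sub: SubModel) -> dict:
    return {
        "config": vars(sub.config) | {},
        "seed": sub.seed,
        "qna_spec": None if sub.qna_spec is None else {
            "max_degree": sub.qna_spec.max_degree,
            "p_bounds": list(sub.qna_spec.p_bounds),
            "q_bounds": list(sub.qna_spec.q_bounds)},
        "vocabulary": None if sub.vocab is None else _vocab_to_obj(sub.vocab),
        "subset_idx": sub.subset_idx.tolist(),
        "rbf_centers": None if sub.rbf_centers is None
        else sub.rbf_centers.tolist(),
        "rbf_width": sub.rbf_width,
        "mask": sub.mask.tolist(),
        "coefs": sub.coefs.tolist(),
        "intercept": sub.intercept,
        "r2": sub.r2, "q2_loo": sub.q2_loo, "rmse": sub.rmse,
        "training_features": sub.training_features.tolist(),
        "loo_abs_residuals": sub.loo_abs_residuals.tolist(),
        "leverage_pinv": sub.leverage_pinv.tolist(),
    }


def _submodel_from_obj(obj: dict) -> SubModel:
    spec = obj["qna_spec"]
    return SubModel(
        config=SubModelConfig(**obj["config"]),
        seed=obj["seed"],
        qna_spec=None if spec is None else QnaFeatureSpec(
            max_degree=spec["max_degree"],
            p_bounds=tuple(spec["p_bounds"]),
            q_bounds=tuple(spec["q_bounds"])),
        vocab=None if obj["vocabulary"] is None
        else _vocab_from_obj(obj["vocabulary"]),
        subset_idx=np.asarray(obj["subset_idx"], dtype=int),
        rbf_centers=None if obj["rbf_centers"] is None
        else np.asarray(obj["rbf_centers"]),
        rbf_width=obj["rbf_width"],
        mask=np.asarray(obj["mask"], dtype=bool),
        coefs=np.asarray(obj["coefs"]),
        intercept=obj["intercept"],
        r2=obj["r2"], q2_loo=obj["q2_loo"], rmse=obj["rmse"],
        training_features=np.asarray(obj["training_features"]),
        loo_abs_residuals=np.asarray(obj["loo_abs_residuals"]),
        leverage_pinv=np.asarray(obj["leverage_pinv"]))


def save_consensus_model(model: ConsensusModel, path) -> None:
    doc = {
        "format": "cypqsar-consensus-model", "version": FORMAT_VERSION,
        "isoform": model.isoform,
        "r2_min": model.r2_min, "q2_min": model.q2_min,
        "training_interval": list(model.training_interval),
        "training_mean": model.training_mean,
        "n_candidates": model.n_candidates,
        "seed": model.seed,
        "submodels": [_submodel_to_obj(s) for s in model.submodels],
    }
    Path(path).write_text(json.dumps(doc))


def load_consensus_model(path) -> ConsensusModel:
    doc = json.loads(Path(path).read_text())
    if doc.get("format") != "cypqsar-consensus-model":
        raise ValueError(f"{path}: not a consensus-model archive")
    if doc.get("version") > FORMAT_VERSION:
        raise ValueError(f"{path}: unsupported archive version")
    return ConsensusModel(
        submodels=[_submodel_from_obj(o) for o in doc["submodels"]],
        isoform=doc["isoform"], r2_min=doc["r2_min"], q2_min=doc["q2_min"],
        training_interval=tuple(doc["training_interval"]),
        training_mean=doc["training_mean"],
        n_candidates=doc["n_candidates"], seed=doc.get("seed", 0))
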