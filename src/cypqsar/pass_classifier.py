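"""Naïve-Bayes multi-activity classifier with Pa/Pi estimates and IAP.

The engine follows the biological-activity-spectrum prediction scheme:
molecules are represented by their MNA descriptor sets; for each activity
the model stores, per descriptor d, how many positive and negative
training molecules contain d. A query's raw score for an activity is

    score = mean over known d in the molecule of (2·p̂(d) − 1),
    p̂(d) = (n_pos(d) + 1) / (n_pos(d) + n_neg(d) + 2)    (Laplace),

where "known" means the descriptor occurs in at least one training
molecule of that activity. The probabilities "to be active" (Pa) and
"to be inactive" (Pi) are empirical tail probabilities of the score
against the leave-one-out score distributions of the training positives
and negatives (half weight to ties). Activities with Pa > Pi are flagged
as possible.

Leave-one-out scores are obtained exactly by count subtraction: removing
a molecule's contribution from the per-descriptor counts reproduces the
model refitted without it, so LOO validation costs no refits.

Applicability domain: a query whose descriptor set contains more than 25%
descriptors unseen in training (over the model-wide vocabulary) is outside
the domain; the threshold is inclusive.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .chem_model import Molecule
from .curation import ClassificationSet
from .mna import DEFAULT_MAX_LEVEL, MnaSet, MnaVocabulary, mna_set, \
    novelty_fraction

AD_NOVELTY_THRESHOLD = 0.25  # inclusive


@dataclass
class PassStats:
    """Per-activity descriptor count statistics."""

    n_pos: int
    n_neg: int
    pos_counts: dict[str, int]
    neg_counts: dict[str, int]

    def total_count(self, d: str) -> int:
        return self.pos_counts.get(d, 0) + self.neg_counts.get(d, 0)


@dataclass
class PassPrediction:
    activity: str
    pa: float
    pi: float
    score: float
    novelty: float
    in_ad: bool

    @property
    def possible(self) -> bool:
        return self.pa > self.pi


def _laplace_contrib(np_d: int, nn_d: int) -> float:
    p_hat = (np_d + 1.0) / (np_d + nn_d + 2.0)
    return 2.0 * p_hat - 1.0


def _score_from_counts(descriptors: Iterable[str], pos_counts: Mapping[str, int],
                       neg_counts: Mapping[str, int]) -> float:
    contribs = []
    for d in descriptors:
        np_d = pos_counts.get(d, 0)
        nn_d = neg_counts.get(d, 0)
        if np_d + nn_d == 0:
            continue  # unknown for this activity: feeds novelty, not score
        contribs.append(_laplace_contrib(np_d, nn_d))
    if not contribs:
        return 0.0
    return float(np.mean(contribs))


class PassModel:
    """Fitted multi-activity classifier.

    ``loo_scores[activity]`` holds the leave-one-out scores of the training
    positives and negatives, backing the Pa/Pi estimator and IAP.
    """

    def __init__(self, stats: dict[str, PassStats], vocab: MnaVocabulary,
                 loo_scores: dict[str, tuple[np.ndarray, np.ndarray]],
                 max_level: int,
                 training_sets: dict[str, ClassificationSet] | None = None,
                 ad_threshold: float = AD_NOVELTY_THRESHOLD):
        self.stats = stats
        self.vocab = vocab
        self.loo_scores = loo_scores
        self.max_level = max_level
        self.training_sets = training_sets or {}
        self.ad_threshold = ad_threshold

    @property
    def activities(self) -> list[str]:
        return sorted(self.stats)

    def descriptor_set(self, mol: Molecule) -> MnaSet:
        return mna_set(mol, self.max_level)


def fit(training: Mapping[str, ClassificationSet],
        max_level: int = DEFAULT_MAX_LEVEL,
        ad_threshold: float = AD_NOVELTY_THRESHOLD) -> PassModel:
    """Fit per-activity descriptor counts and exact LOO score distributions.

    ``training`` maps an activity name (e.g. "CYP3A4 inhibitor") to its
    binary set. Each activity needs at least one molecule of each class.
    """
    all_sets: list[MnaSet] = []
    per_activity: dict[str, list[tuple[MnaSet, int]]] = {}
    for act in sorted(training):
        cset = training[act]
        labeled = []
        for mol, y in cset.entries:
            ds = mna_set(mol, max_level)
            labeled.append((ds, int(y)))
            all_sets.append(ds)
        n_pos = sum(y for _, y in labeled)
        if n_pos == 0 or n_pos == len(labeled):
            raise ValueError(
                f"activity {act!r} has a single class only; cannot fit")
        per_activity[act] = labeled
    vocab = MnaVocabulary.fit(all_sets)

    stats: dict[str, PassStats] = {}
    loo: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for act, labeled in per_activity.items():
        pos_counts: dict[str, int] = {}
        neg_counts: dict[str, int] = {}
        for ds, y in labeled:
            tgt = pos_counts if y == 1 else neg_counts
            for d in ds.descriptors:
                tgt[d] = tgt.get(d, 0) + 1
        n_pos = sum(y for _, y in labeled)
        n_neg = len(labeled) - n_pos
        st = PassStats(n_pos, n_neg, pos_counts, neg_counts)
        pos_scores, neg_scores = [], []
        for ds, y in labeled:
            s = _loo_score(st, ds, y)
            (pos_scores if y == 1 else neg_scores).append(s)
        stats[act] = st
        loo[act] = (np.asarray(pos_scores), np.asarray(neg_scores))
    return PassModel(stats, vocab, loo, max_level, dict(training),
                     ad_threshold)


def _loo_score(st: PassStats, ds: MnaSet, y: int) -> float:
    """Score of a training molecule under the model refitted without it,
    computed by subtracting its own contribution from the counts."""
    contribs = []
    for d in ds.descriptors:
        np_d = st.pos_counts.get(d, 0) - (1 if y == 1 else 0)
        nn_d = st.neg_counts.get(d, 0) - (1 if y == 0 else 0)
        if np_d + nn_d == 0:
            continue  # descriptor unique to this molecule: out of the
            # refitted activity's support
        contribs.append(_laplace_contrib(np_d, nn_d))
    if not contribs:
        return 0.0
    return float(np.mean(contribs))


def score(model: PassModel, descriptors: MnaSet, activity: str) -> float:
    """Raw naïve-Bayes statistic of a query for one activity."""
    st = model.stats[activity]
    return _score_from_counts(descriptors.descriptors, st.pos_counts,
                              st.neg_counts)


def _ecdf_tail(values: np.ndarray, s: float, side: str) -> float:
    """Fraction of values strictly beyond s on the given side, ties half."""
    if len(values) == 0:
        return 0.0
    if side == "below":
        strictly = np.sum(values < s)
    else:
        strictly = np.sum(values > s)
    ties = np.sum(values == s)
    return float((strictly + 0.5 * ties) / len(values))


def pa_pi(model: PassModel, mol: Molecule | MnaSet, activity: str
          ) -> PassPrediction:
    """Pa/Pi for one activity.

    Pa is the fraction of training positives whose LOO score falls below
    the query's score (half weight to ties); Pi mirrors it over the
    negatives. The applicability-domain flag comes from the new-descriptor
    fraction against the model vocabulary (inclusive threshold).
    """
    ds = mol if isinstance(mol, MnaSet) else model.descriptor_set(mol)
    s = score(model, ds, activity)
    pos_scores, neg_scores = model.loo_scores[activity]
    pa = _ecdf_tail(pos_scores, s, "below")
    pi = _ecdf_tail(neg_scores, s, "above")
    nov = novelty_fraction(ds, model.vocab)
    return PassPrediction(activity=activity, pa=pa, pi=pi, score=s,
                          novelty=nov, in_ad=nov <= model.ad_threshold)


def predict_profile(model: PassModel, mol: Molecule | MnaSet
                    ) -> list[PassPrediction]:
    """One prediction per activity, ranked by Pa − Pi descending."""
    preds = [pa_pi(model, mol, act) for act in model.activities]
    preds.sort(key=lambda p: (-(p.pa - p.pi), p.activity))
    return preds


def _pairwise_auc(pos: np.ndarray, neg: np.ndarray) -> float:
    """P(random positive outscores random negative) + half ties, by exact
    enumeration of all pos×neg pairs."""
    if len(pos) == 0 or len(neg) == 0:
        raise ValueError("IAP needs both classes")
    pos = np.asarray(pos, dtype=float)[:, None]
    neg = np.asarray(neg, dtype=float)[None, :]
    wins = np.sum(pos > neg) + 0.5 * np.sum(pos == neg)
    return float(wins / (pos.shape[0] * neg.shape[1]))


def iap_loo(model: PassModel, activity: str) -> float:
    """Invariant Accuracy of Prediction from the stored LOO scores —
    numerically the ROC AUC of LOO scores."""
    pos_scores, neg_scores = model.loo_scores[activity]
    return _pairwise_auc(pos_scores, neg_scores)


def iap_kfold(training: Mapping[str, ClassificationSet], activity: str,
              k: int, seed: int, max_level: int = DEFAULT_MAX_LEVEL) -> float:
    """IAP under seeded stratified k-fold cross-validation.

    Folds are drawn so that every training remainder retains both classes
    (so each fold's model is fittable); held-out molecules are scored by
    the model fitted on the remainder and the pooled scores yield the
    pairwise IAP. At k = n this reproduces leave-one-out exactly.
    """
    cset = training[activity]
    n = len(cset.entries)
    if k < 2 or k > n:
        raise ValueError(f"k must be in [2, {n}]")
    labels = np.asarray(cset.labels)
    rng = np.random.default_rng(seed)
    folds = _stratified_folds(labels, k, rng)
    desc_sets = [mna_set(m, max_level) for m in cset.molecules]
    pooled_pos, pooled_neg = [], []
    for fold in folds:
        held = set(fold.tolist())
        train_entries = [(cset.entries[i]) for i in range(n) if i not in held]
        sub = ClassificationSet(isoform=cset.isoform, entries=train_entries)
        sub_model = fit({activity: sub}, max_level=max_level)
        st = sub_model.stats[activity]
        for i in fold:
            s = _score_from_counts(desc_sets[i].descriptors, st.pos_counts,
                                   st.neg_counts)
            (pooled_pos if labels[i] == 1 else pooled_neg).append(s)
    return _pairwise_auc(np.asarray(pooled_pos), np.asarray(pooled_neg))


def _stratified_folds(labels: np.ndarray, k: int, rng: np.random.Generator,
                      max_retries: int = 20) -> list[np.ndarray]:
    """Class-stratified fold assignment; redraw (bounded) until every
    training remainder keeps both classes."""
    n = len(labels)
    for _ in range(max_retries):
        pos = np.flatnonzero(labels == 1)
        neg = np.flatnonzero(labels == 0)
        rng.shuffle(pos)
        rng.shuffle(neg)
        order = np.concatenate([pos, neg])
        assignment = np.empty(n, dtype=int)
        assignment[order] = np.arange(n) % k
        folds = [np.flatnonzero(assignment == f) for f in range(k)]
        ok = True
        for fold in folds:
            rest = np.delete(labels, fold)
            if rest.sum() == 0 or rest.sum() == len(rest):
                ok = False
                break
        if ok:
            return folds
    raise ValueError("could not draw folds whose training remainders retain "
                     "both classes")
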