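"""Naive-Bayes classifier: counts, exact LOO, Pa/Pi, IAP, folds, AD."""

import numpy as np
import pytest

from cypqsar import ClassificationSet, MnaSet, MnaVocabulary, parse_smiles
from cypqsar.mna import mna_set
from cypqsar import pass_classifier as pc


def _cset(smiles_labels, isoform="3A4"):
    entries = [(parse_smiles(s), y) for s, y in smiles_labels]
    n_pos = sum(y for _, y in entries)
    return ClassificationSet(isoform=isoform, entries=entries, n_pos=n_pos,
                             n_neg=len(entries) - n_pos)


def test_fit_counts_descriptors_per_class():
    cset = _cset([("CCO", 1), ("CCO", 1), ("c1ccccc1", 0), ("c1ccncc1", 0)])
    model = pc.fit({"act": cset})
    st = model.stats["act"]
    d = "-O(-C-H)"  # hydroxyl root, present only in the actives
    assert st.pos_counts[d] == 2
    assert st.neg_counts.get(d, 0) == 0


def test_single_class_activity_errors():
    with pytest.raises(ValueError, match="single class"):
        pc.fit({"act": _cset([("CCO", 1), ("CCN", 1)])})


def test_score_laplace_arithmetic():
    # one descriptor with n_pos(d)=3, n_neg(d)=0 -> 2*(4/5)-1 = 0.6
    st = pc.PassStats(3, 3, {"d1": 3}, {})
    model = pc.PassModel({"act": st}, MnaVocabulary({"d1": 0}),
                         {"act": (np.zeros(3), np.zeros(3))}, max_level=2)
    ds = MnaSet(frozenset({"d1"}), 2)
    assert pc.score(model, ds, "act") == pytest.approx(0.6)


def test_score_balanced_descriptor_is_zero():
    st = pc.PassStats(2, 2, {"d1": 1}, {"d1": 1})
    model = pc.PassModel({"act": st}, MnaVocabulary({"d1": 0}),
                         {"act": (np.zeros(2), np.zeros(2))}, max_level=2)
    assert pc.score(model, MnaSet(frozenset({"d1"}), 2), "act") == 0.0


def test_unknown_descriptors_feed_novelty_not_score():
    st = pc.PassStats(2, 2, {"d1": 2}, {"d1": 1})
    model = pc.PassModel({"act": st}, MnaVocabulary({"d1": 0}),
                         {"act": (np.zeros(2), np.zeros(2))}, max_level=2)
    ds = MnaSet(frozenset({"u1", "u2"}), 2)
    pred = pc.pa_pi(model, ds, "act")
    assert pred.score == 0.0
    assert pred.novelty == 1.0
    assert not pred.in_ad


def test_loo_by_subtraction_equals_explicit_retrain(
        small_classification_set):
    cset, _ = small_classification_set
    act = "CYP 3A4 inhibitor"
    model = pc.fit({act: cset})
    pos_scores, neg_scores = model.loo_scores[act]
    stored = {}
    i_pos = i_neg = 0
    for idx, (_, y) in enumerate(cset.entries):
        if y == 1:
            stored[idx] = pos_scores[i_pos]; i_pos += 1
        else:
            stored[idx] = neg_scores[i_neg]; i_neg += 1
    for idx in range(len(cset.entries)):
        rest = [e for j, e in enumerate(cset.entries) if j != idx]
        sub = ClassificationSet(isoform=cset.isoform, entries=rest)
        refit = pc.fit({act: sub})
        ds = mna_set(cset.entries[idx][0], model.max_level)
        assert pc.score(refit, ds, act) == stored[idx]  # exact


def test_pa_pi_ecdf_extremes():
    st = pc.PassStats(3, 3, {"d": 3}, {})
    loo = {"act": (np.array([0.1, 0.2, 0.3]), np.array([-0.3, -0.2, -0.1]))}
    model = pc.PassModel({"act": st}, MnaVocabulary({"d": 0}), loo, 2)
    hi = pc.pa_pi(model, MnaSet(frozenset({"d"}), 2), "act")  # score 0.6
    assert (hi.pa, hi.pi) == (1.0, 0.0)
    lo = pc._ecdf_tail(loo["act"][0], -5.0, "below")
    assert lo == 0.0


def test_pa_pi_monotone_in_score():
    pos = np.array([0.0, 0.3, 0.5, 0.5, 0.9])
    neg = np.array([-0.5, -0.2, 0.0, 0.1])
    scores = np.linspace(-1, 1, 41)
    pa = [pc._ecdf_tail(pos, s, "below") for s in scores]
    pi = [pc._ecdf_tail(neg, s, "above") for s in scores]
    assert all(a <= b + 1e-15 for a, b in zip(pa, pa[1:]))
    assert all(a >= b - 1e-15 for a, b in zip(pi, pi[1:]))


def test_iap_hand_enumeration():
    assert pc._pairwise_auc(np.array([1., 2., 3.]),
                            np.array([-1., -2., -3.])) == 1.0
    assert pc._pairwise_auc(np.ones(4), np.ones(3)) == 0.5
    # 3 pos / 3 neg, one tied pair -> 8.5/9; one inverted pair -> 8/9
    pos = np.array([0.1, 0.5, 0.9])
    tied = np.array([-0.5, -0.1, 0.1])
    inverted = np.array([-0.5, -0.1, 0.2])
    for neg, expected in ((tied, 8.5 / 9), (inverted, 8.0 / 9)):
        wins = sum(1.0 if p > n else (0.5 if p == n else 0.0)
                   for p in pos for n in neg)
        assert wins / 9 == pytest.approx(expected)
        assert pc._pairwise_auc(pos, neg) == pytest.approx(expected)


def test_iap_matches_sklearn_roc_auc(medium_classification_set):
    from sklearn.metrics import roc_auc_score
    cset, _ = medium_classification_set
    act = "CYP 3A4 inhibitor"
    model = pc.fit({act: cset})
    pos, neg = model.loo_scores[act]
    y = np.r_[np.ones(len(pos)), np.zeros(len(neg))]
    auc = roc_auc_score(y, np.r_[pos, neg])
    assert pc.iap_loo(model, act) == pytest.approx(auc, abs=1e-12)


def test_label_swap_maps_iap_to_complement(small_classification_set):
    # exchanging which class counts as positive, at fixed scores,
    # complements the pairwise win probability
    cset, _ = small_classification_set
    act = "CYP 3A4 inhibitor"
    model = pc.fit({act: cset})
    pos, neg = model.loo_scores[act]
    assert pc._pairwise_auc(neg, pos) == \
        pytest.approx(1.0 - pc._pairwise_auc(pos, neg), abs=1e-12)


def test_refit_with_swapped_labels_negates_scores(small_classification_set):
    # relabelling the training set negates every Laplace contribution,
    # so the refitted LOO scores are the negated originals with roles swapped
    cset, _ = small_classification_set
    act = "CYP 3A4 inhibitor"
    swapped = ClassificationSet(isoform=cset.isoform,
                                entries=[(m, 1 - y) for m, y in cset.entries])
    pos, neg = pc.fit({act: cset}).loo_scores[act]
    pos_sw, neg_sw = pc.fit({act: swapped}).loo_scores[act]
    np.testing.assert_allclose(np.sort(pos_sw), np.sort(-neg), atol=1e-15)
    np.testing.assert_allclose(np.sort(neg_sw), np.sort(-pos), atol=1e-15)


def test_kfold_at_n_reproduces_loo(small_classification_set):
    cset, _ = small_classification_set
    act = "CYP 3A4 inhibitor"
    model = pc.fit({act: cset})
    loo = pc.iap_loo(model, act)
    kn = pc.iap_kfold({act: cset}, act, k=len(cset.entries), seed=5)
    assert kn == pytest.approx(loo, abs=1e-12)


def test_kfold_deterministic_under_seed(small_classification_set):
    cset, _ = small_classification_set
    act = "CYP 3A4 inhibitor"
    a = pc.iap_kfold({act: cset}, act, k=5, seed=9)
    b = pc.iap_kfold({act: cset}, act, k=5, seed=9)
    assert a == b


def test_predict_profile_ranking_and_flags(medium_classification_set):
    cset, _ = medium_classification_set
    model = pc.fit({"act": cset})
    active_mol = next(m for m, y in cset.entries if y == 1)
    preds = pc.predict_profile(model, active_mol)
    assert preds[0].possible == (preds[0].pa > preds[0].pi)
    deltas = [p.pa - p.pi for p in preds]
    assert deltas == sorted(deltas, reverse=True)


def test_pa_equal_pi_not_flagged():
    p = pc.PassPrediction("act", pa=0.4, pi=0.4, score=0.0, novelty=0.0,
                          in_ad=True)
    assert not p.possible
    q = pc.PassPrediction("act", pa=0.3, pi=0.2, score=0.0, novelty=0.0,
                          in_ad=True)
    assert q.possible


def test_ad_threshold_inclusive(medium_classification_set):
    cset, _ = medium_classification_set
    model = pc.fit({"act": cset})
    vocab_texts = sorted(model.stats["act"].pos_counts)[:75]
    at_25 = MnaSet(frozenset(vocab_texts + [f"novel{i}" for i in range(25)]), 2)
    over_25 = MnaSet(frozenset(vocab_texts[:74]
                               + [f"novel{i}" for i in range(26)]), 2)
    assert pc.pa_pi(model, at_25, "act").in_ad          # 25% exactly: inside
    assert not pc.pa_pi(model, over_25, "act").in_ad    # 26%: outside
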