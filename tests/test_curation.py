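"""Curation rules: labelling cuts, conflict removal, median aggregation."""

import math
import random

import pytest

from cypqsar import ActivityRecord, ClassLabel, build_classification_set, \
    build_regression_set, label_chembl_record, label_pubchem_record, \
    pic50_from_nM


def _ic50(value, relation="=", smiles="CCO", cid="X1"):
    return ActivityRecord(compound_id=cid, smiles=smiles, isoform="3A4",
                          endpoint="ic50", value=value, relation=relation,
                          source="chembl")


def _pct(value, smiles="CCO", cid="X1"):
    return ActivityRecord(compound_id=cid, smiles=smiles, isoform="3A4",
                          endpoint="percent_inhibition", value=value,
                          relation="=", source="chembl")


def _pubchem(outcome, curve, smiles="CCO", cid="P1"):
    return ActivityRecord(compound_id=cid, smiles=smiles, isoform="3A4",
                          endpoint="outcome", outcome_flag=outcome,
                          curve_flag=curve, source="pubchem")


@pytest.mark.parametrize("value,relation,expected", [
    (5_000, "=", ClassLabel.INHIBITOR),
    (9_999, "<", ClassLabel.INHIBITOR),
    (9_999, "≤", ClassLabel.INHIBITOR),
    (25_000, ">", ClassLabel.NONINHIBITOR),
    (25_000, "=", ClassLabel.NONINHIBITOR),
    (50_000, "≥", ClassLabel.NONINHIBITOR),
    (15_000, "=", ClassLabel.INDETERMINATE),   # the 10-20 uM gap
    (10_000, "=", ClassLabel.INDETERMINATE),   # cuts are strict
    (20_000, "=", ClassLabel.INDETERMINATE),
    (5_000, ">", ClassLabel.INDETERMINATE),    # sign incompatible with rule
    (25_000, "<", ClassLabel.INDETERMINATE),
])
def test_ic50_labelling(value, relation, expected):
    assert label_chembl_record(_ic50(value, relation)) is expected


@pytest.mark.parametrize("value,expected", [
    (50.1, ClassLabel.INHIBITOR),
    (50.0, ClassLabel.NONINHIBITOR),  # strictly greater than 50 required
    (12.0, ClassLabel.NONINHIBITOR),
])
def test_percent_inhibition_labelling(value, expected):
    assert label_chembl_record(_pct(value)) is expected


@pytest.mark.parametrize("outcome,curve,expected", [
    ("active", "complete_curve", ClassLabel.INHIBITOR),
    ("active", "other", ClassLabel.INDETERMINATE),
    ("active", None, ClassLabel.INDETERMINATE),
    ("inactive", None, ClassLabel.NONINHIBITOR),
    ("inconclusive", None, ClassLabel.INDETERMINATE),
])
def test_pubchem_labelling(outcome, curve, expected):
    assert label_pubchem_record(_pubchem(outcome, curve)) is expected


def test_wrong_dialect_rejected():
    with pytest.raises(ValueError):
        label_pubchem_record(_ic50(100))
    with pytest.raises(ValueError):
        label_chembl_record(_pubchem("active", "complete_curve"))


def test_conflicting_structure_removed_entirely():
    records = [
        _ic50(5_000, "=", "c1ccccc1C", "A"),   # inhibitor
        _ic50(25_000, "=", "Cc1ccccc1", "B"),  # same structure, noninhibitor
        _ic50(100, "=", "CCO", "C"),
        _ic50(90_000, "=", "CCN", "D"),
    ]
    cset = build_classification_set(records, "3A4")
    assert cset.n_conflicts_removed == 1
    smiles = {m.smiles for m in cset.molecules}
    assert not any("c1" in s for s in smiles)
    assert cset.n_pos == 1 and cset.n_neg == 1


def test_same_label_duplicates_collapse():
    records = [_ic50(100, "=", "CCO", "A"), _ic50(200, "=", "OCC", "B"),
               _ic50(90_000, "=", "CCN", "C")]
    cset = build_classification_set(records, "3A4")
    assert len(cset.entries) == 2
    assert cset.n_pos == 1 and cset.n_neg == 1


def test_counts_add_up():
    records = [_ic50(100, "=", s, f"A{i}") for i, s in
               enumerate(["CCO", "CCN", "CCC"])] + \
              [_ic50(90_000, "=", s, f"B{i}") for i, s in
               enumerate(["CCCl", "CCBr"])]
    cset = build_classification_set(records, "3A4")
    assert (cset.n_pos, cset.n_neg) == (3, 2)
    assert cset.n_pos + cset.n_neg == len(cset.entries)


def test_empty_retained_set_errors():
    with pytest.raises(ValueError, match="2D6"):
        build_classification_set([_ic50(15_000, "=")], "2D6")


@pytest.mark.parametrize("nm,expected", [
    (10_000, 5.0), (1.0, 9.0), (1e9, 0.0), (1_000, 6.0)])
def test_pic50_conversion(nm, expected):
    assert pic50_from_nM(nm) == pytest.approx(expected, abs=1e-12)


def test_pic50_rejects_nonpositive():
    with pytest.raises(ValueError):
        pic50_from_nM(0.0)
    with pytest.raises(ValueError):
        pic50_from_nM(-5.0)


def test_regression_median_of_duplicates():
    records = [_ic50(v, "=", "CCO", f"D{i}")
               for i, v in enumerate([100, 1_000, 10_000])] + \
              [_ic50(50, "=", "CCN", "E")]
    rset = build_regression_set(records, "3A4")
    by_smiles = {m.smiles: y for m, y in rset.entries}
    assert by_smiles[max(by_smiles, key=len)] or True
    ethanol = [y for m, y in rset.entries if "O" in m.smiles][0]
    assert ethanol == pytest.approx(6.0, abs=1e-12)


def test_regression_keeps_only_equality_relation():
    records = [_ic50(100, "=", "CCO", "A"), _ic50(100, ">", "CCN", "B"),
               _ic50(100, "<", "CCC", "C")]
    rset = build_regression_set(records, "3A4")
    assert len(rset.entries) == 1


def test_regression_interval_and_mean():
    records = [_ic50(10, "=", "CCO", "A"), _ic50(1_000, "=", "CCN", "B")]
    rset = build_regression_set(records, "3A4")
    assert rset.value_interval == pytest.approx((6.0, 8.0))
    assert rset.mean_value == pytest.approx(7.0)


def test_median_permutation_invariant():
    base = [_ic50(v, "=", "CCO", f"R{i}")
            for i, v in enumerate([40, 70, 100, 550, 9000, 12])]
    ref = build_regression_set(base, "3A4").entries[0][1]
    rng = random.Random(3)
    for _ in range(5):
        shuffled = base[:]
        rng.shuffle(shuffled)
        assert build_regression_set(shuffled, "3A4").entries[0][1] == ref


def test_relabeling_reproduces_retained_labels():
    records = [_ic50(100, "=", "CCO", "A"), _ic50(90_000, "=", "CCN", "B"),
               _pct(80.0, "CCC", "C")]
    cset = build_classification_set(records, "3A4")
    for mol, y in cset.entries:
        source = [r for r in records
                  if label_chembl_record(r) is not ClassLabel.INDETERMINATE]
        from cypqsar.chem_model import canonical_smiles
        labels = {label_chembl_record(r) for r in source
                  if canonical_smiles(r.smiles) == mol.smiles}
        assert labels == {ClassLabel.INHIBITOR if y else
                          ClassLabel.NONINHIBITOR}
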