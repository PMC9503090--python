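"""RBF-SCR fitting, consensus assembly, applicability domain, validation."""

import numpy as np
import pytest

from cypqsar import FixtureSpec, build_consensus, consensus_predict, \
    fit_submodel, gen_regression_fixture, metrics, scr_fit
from cypqsar.gusar_qsar import SubModelConfig, _ridge_solve, \
    assign_sorted_folds, passes_selection


# ---------------------------------------------------------------- metrics

def test_metrics_perfect_and_null():
    y = [1.0, 2.0, 3.0, 4.0]
    perfect = metrics(y, y)
    assert perfect["R2"] == 1.0 and perfect["RMSE"] == 0.0 \
        and perfect["SD"] == 0.0
    null = metrics(y, [2.5] * 4)
    assert null["R2"] == pytest.approx(0.0)


def test_metrics_rmse_arithmetic():
    m = metrics([0.0, 2.0], [1.0, 1.0])  # residuals (+1, -1)
    assert m["RMSE"] == pytest.approx(1.0)


def test_metrics_rejects_zero_variance():
    with pytest.raises(ValueError):
        metrics([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


def test_metrics_sd_uses_n_minus_1():
    resid = np.array([1.0, -1.0, 2.0, -2.0])
    y = np.arange(4.0)
    m = metrics(y, y - resid)
    assert m["SD"] == pytest.approx(np.std(resid, ddof=1))


# ------------------------------------------------------------- ridge/LOO

def test_hat_matrix_loo_equals_explicit_refits():
    rng = np.random.default_rng(0)
    for lam in (1e-3, 1e-1, 1.0):
        x = rng.normal(size=(40, 6))
        y = x @ rng.normal(size=6) + 0.1 * rng.normal(size=40) + 2.0
        _, _, _, loo = _ridge_solve(x, y, lam)
        for i in range(40):
            keep = np.arange(40) != i
            coefs, b0, _, _ = _ridge_solve(x[keep], y[keep], lam)
            pred_i = b0 + x[i] @ coefs
            assert loo[i] == pytest.approx(y[i] - pred_i, abs=1e-8)


# ------------------------------------------------------------------- SCR

def test_scr_recovers_planted_linear_signal():
    rng = np.random.default_rng(1)
    x = rng.normal(size=(60, 10))
    y = 3.0 * x[:, 2] - 2.0 * x[:, 7] + 1.0
    fit = scr_fit(x, y)
    assert fit.mask[2] and fit.mask[7]
    assert fit.r2 >= 0.999


def test_scr_constant_response_gives_intercept_only():
    rng = np.random.default_rng(2)
    x = rng.normal(size=(20, 5))
    fit = scr_fit(x, np.full(20, 4.2))
    assert not fit.mask.any()
    assert fit.coefs.size == 0
    assert fit.intercept == pytest.approx(4.2)
    assert fit.r2 == 0.0


def test_scr_drops_duplicate_columns():
    rng = np.random.default_rng(3)
    base = rng.normal(size=(50, 4))
    x = np.hstack([base, base[:, [0]]])  # column 4 duplicates column 0
    y = 2.0 * base[:, 0] + base[:, 1] + 0.01 * rng.normal(size=50)
    fit = scr_fit(x, y)
    assert not (fit.mask[0] and fit.mask[4])


def test_scr_rejects_degenerate_input():
    with pytest.raises(ValueError):
        scr_fit(np.zeros((20, 3)), np.arange(20.0))
    with pytest.raises(ValueError):
        scr_fit(np.ones((5, 2)), np.arange(5.0))  # too few rows


# ------------------------------------------------------------ sub-models

def test_fit_submodel_deterministic(regression_set_sigma03):
    rset, _ = regression_set_sigma03
    config = SubModelConfig(feature_source="qna", rbf=True)
    a = fit_submodel(rset, config, seed=4)
    b = fit_submodel(rset, config, seed=4)
    assert a.r2 == b.r2 and a.q2_loo == b.q2_loo
    assert np.array_equal(a.coefs, b.coefs)
    assert np.array_equal(a.subset_idx, b.subset_idx)


def test_submodel_on_noiseless_fixture_has_high_q2():
    rset, _ = gen_regression_fixture(
        FixtureSpec(n_molecules=80, seed=21, sigma=0.0))
    sub = fit_submodel(rset, SubModelConfig(feature_source="mna", rbf=False,
                                            top_m=96), seed=5)
    assert sub.q2_loo > 0.9


def test_submodel_requires_twenty_compounds(regression_set_sigma03):
    from cypqsar.curation import RegressionSet
    rset, _ = regression_set_sigma03
    tiny = RegressionSet(isoform="3A4", entries=rset.entries[:10])
    with pytest.raises(ValueError):
        fit_submodel(tiny, SubModelConfig(), seed=0)


# ------------------------------------------------------------- selection

def test_selection_filter_boundary_semantics(regression_set_sigma03):
    rset, _ = regression_set_sigma03
    sub = fit_submodel(rset, SubModelConfig(feature_source="mna", rbf=False),
                       seed=6)
    assert passes_selection(sub, r2_min=sub.r2 - 0.01, q2_min=sub.q2_loo - 0.01)
    assert not passes_selection(sub, r2_min=sub.r2, q2_min=0.0)  # equality
    assert not passes_selection(sub, r2_min=0.0, q2_min=sub.q2_loo)


def test_consensus_retains_only_above_thresholds(regression_set_sigma03):
    rset, _ = regression_set_sigma03
    model = build_consensus(rset, n_candidates=6, seed=8)
    assert model.n_models >= 1
    for sub in model.submodels:
        assert sub.r2 > model.r2_min and sub.q2_loo > model.q2_min


def test_consensus_zero_retained_errors(regression_set_sigma03):
    rset, _ = regression_set_sigma03
    with pytest.raises(ValueError, match="threshold"):
        build_consensus(rset, n_candidates=2, seed=8, r2_min=0.999999,
                        q2_min=0.999999)


# ---------------------------------------------------------------------- AD

@pytest.fixture(scope="module")
def fitted_submodel():
    rset, _ = gen_regression_fixture(
        FixtureSpec(n_molecules=60, seed=31, sigma=0.2))
    sub = fit_submodel(rset, SubModelConfig(feature_source="qna", rbf=False),
                       seed=9)
    return sub


def test_training_row_is_in_domain(fitted_submodel):
    sub = fitted_submodel
    x = sub.training_features[0]
    weight, in_ad = sub.ad_assess(x)
    assert in_ad and weight > 0
    sims = (sub.training_features @ x) / np.clip(
        np.linalg.norm(sub.training_features, axis=1) * np.linalg.norm(x),
        1e-12, None)
    assert sims.max() == pytest.approx(1.0)


def test_leverage_matches_oracle_formula(fitted_submodel):
    sub = fitted_submodel
    xt = sub.training_features
    oracle = np.linalg.pinv(xt.T @ xt)
    x = xt[3]
    assert x @ sub.leverage_pinv @ x == pytest.approx(x @ oracle @ x,
                                                      abs=1e-10)


def test_far_extrapolation_fails_leverage(fitted_submodel):
    sub = fitted_submodel
    x = sub.training_features[0] * 100.0
    weight, in_ad = sub.ad_assess(x)
    assert not in_ad and weight == 0.0


def test_orthogonal_query_out_of_domain(fitted_submodel):
    sub = fitted_submodel
    p = sub.training_features.shape[1]
    # least-squares residual of a random vector against the training row
    # space is orthogonal to every training row
    rng = np.random.default_rng(0)
    v = rng.normal(size=p)
    xt = sub.training_features
    coef, *_ = np.linalg.lstsq(xt.T, v, rcond=None)
    resid = v - xt.T @ coef
    if np.linalg.norm(resid) > 1e-8:
        weight, in_ad = sub.ad_assess(resid)
        assert weight == 0.0 and not in_ad


# -------------------------------------------------------------- consensus

def test_consensus_prediction_is_convex(regression_set_sigma03):
    rset, _ = regression_set_sigma03
    model = build_consensus(rset, n_candidates=4, seed=12)
    mol = rset.molecules[0]
    pred = consensus_predict(model, mol)
    values = [s.predict_value(s.featurize(mol)) for s in model.submodels]
    assert pred.value is not None
    assert min(values) - 1e-9 <= pred.value <= max(values) + 1e-9
    assert pred.weights and abs(sum(pred.weights) - 1.0) < 1e-9


def test_weighted_average_arithmetic():
    assert np.dot([1.0, 0.0], [5.0, 9.0]) / 1.0 == 5.0


def test_noiseless_training_molecule_recovered():
    rset, truth = gen_regression_fixture(
        FixtureSpec(n_molecules=80, seed=41, sigma=0.0))
    model = build_consensus(rset, n_candidates=4, seed=13)
    errs = []
    for (mol, y) in rset.entries[:20]:
        pred = consensus_predict(model, mol)
        if pred.value is not None:
            errs.append(abs(pred.value - y))
    assert errs and float(np.median(errs)) <= 0.1


# ------------------------------------------------------------- validation

def test_sorted_fold_assignment_rule():
    values = list(range(10))
    assert assign_sorted_folds(values, 5).tolist() == \
        [0, 1, 2, 3, 4, 0, 1, 2, 3, 4]
    shuffled = [3.0, 0.0, 4.0, 1.0, 2.0]
    assert assign_sorted_folds(shuffled, 5).tolist() == [3, 0, 4, 1, 2]


def test_folds_span_activity_range(regression_set_sigma03):
    rset, _ = regression_set_sigma03
    y = np.asarray(rset.values)
    folds = assign_sorted_folds(y, 5)
    fold_means = [y[folds == f].mean() for f in range(5)]
    assert max(fold_means) - min(fold_means) < y.std()
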