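"""RBF–SCR consensus QSAR for pIC50 prediction.

Sub-models are ridge regressions with self-consistent variable selection
(SCR): starting from a QNA-polynomial or MNA-count feature block,
optionally augmented with Gaussian radial-basis columns centred on a
seeded sample of training compounds, the ridge weight is picked from a
grid by leave-one-out Q² (exact, via the hat-matrix identity
e_i/(1−h_ii)), then the least significant feature — smallest
|coefficient|·column-norm — is repeatedly eliminated while Q² does not
degrade by more than a tolerance.

A consensus model keeps only sub-models whose training R² exceeds 0.6
and Q² exceeds 0.5 (strict inequalities). A query is predicted by the
similarity-weighted average of the retained sub-models; each sub-model's
weight comes from its applicability-domain assessment, which combines
three checks:

* similarity — mean cosine similarity to the k = 3 nearest training rows;
* leverage   — h(x) = x (XᵀX)⁻¹ xᵀ must not exceed 3p/n;
* accuracy   — the mean |LOO residual| of those k neighbours must not
  exceed twice the sub-model's training RMSE.

The 5-fold validation protocol sorts compounds by ascending pIC50 and
assigns rank i to fold i mod 5, so every fold spans the activity range;
per fold a consensus is rebuilt on the remainder and the held-out
compounds are predicted, yielding pooled R², RMSE and the fraction of
test compounds inside the applicability domain.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .chem_model import Molecule
from .curation import RegressionSet
from .mna import MnaSet, MnaVocabulary, mna_set
from .qna import ElementProperties, QnaFeatureSpec, fit_qna_bounds, \
    mna_count_features, qna_features

logger = logging.getLogger(__name__)

R2_MIN = 0.6
Q2_MIN = 0.5
DEFAULT_RIDGE_GRID = (1e-4, 1e-3, 1e-2, 1e-1, 1.0, 10.0)
SCR_TOL = 1e-4
AD_K_NEIGHBORS = 3


def metrics(y: Sequence[float], y_hat: Sequence[float]) -> dict[str, float]:
    """R², RMSE and the (n−1)-denominator standard deviation of residuals."""
    y = np.asarray(y, dtype=float)
    y_hat = np.asarray(y_hat, dtype=float)
    if len(y) != len(y_hat) or len(y) < 2:
        raise ValueError("metrics needs two equal-length vectors of size >= 2")
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0:
        raise ValueError("R2 undefined: zero variance in observed values")
    resid = y - y_hat
    r2 = 1.0 - float(np.sum(resid ** 2)) / ss_tot
    rmse = float(np.sqrt(np.mean(resid ** 2)))
    sd = float(np.std(resid, ddof=1))
    return {"R2": r2, "RMSE": rmse, "SD": sd}


# ---------------------------------------------------------------------------
# Ridge with exact LOO through the hat matrix

def _ridge_solve(x: np.ndarray, y: np.ndarray, lam: float
                 ) -> tuple[np.ndarray, float, np.ndarray, np.ndarray]:
    """Ridge with unpenalized intercept.

    Returns (coefs, intercept, fitted, loo_residuals); the LOO residuals
    use the exact linear-smoother identity e_i / (1 − h_ii).
    """
    n, p = x.shape
    z = np.hstack([np.ones((n, 1)), x])
    penalty = np.diag([0.0] + [lam] * p)
    gram = z.T @ z + penalty
    ginv = np.linalg.pinv(gram)
    beta = ginv @ z.T @ y
    fitted = z @ beta
    h = np.einsum("ij,jk,ik->i", z, ginv, z)
    resid = y - fitted
    denom = np.clip(1.0 - h, 1e-12, None)
    loo_resid = resid / denom
    return beta[1:], float(beta[0]), fitted, loo_resid


def _q2_from_press(y: np.ndarray, loo_resid: np.ndarray) -> float:
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0:
        return 0.0
    return 1.0 - float(np.sum(loo_resid ** 2)) / ss_tot


@dataclass
class ScrFit:
    mask: np.ndarray  # boolean over input columns
    coefs: np.ndarray  # over surviving columns
    intercept: float
    ridge_weight: float
    r2: float
    q2_loo: float
    rmse: float
    loo_residuals: np.ndarray


def scr_fit(features: np.ndarray, y: Sequence[float],
            ridge_grid: Sequence[float] = DEFAULT_RIDGE_GRID,
            seed: int = 0, tol: float = SCR_TOL) -> ScrFit:
    """Self-consistent regression: grid-selected ridge + backward
    elimination of insignificant features guided by hat-matrix Q².

    The procedure is deterministic; ``seed`` is accepted for interface
    uniformity with the stochastic fitting layers above it.
    """
    x = np.asarray(features, dtype=float)
    y = np.asarray(y, dtype=float)
    n, p = x.shape
    if n != len(y) or n < 10:
        raise ValueError("scr_fit needs >= 10 rows matching y")
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot <= 1e-12 * max(1.0, float(np.sum(y ** 2))):
        # (numerically) constant response: intercept-only model by convention
        return ScrFit(mask=np.zeros(p, dtype=bool), coefs=np.empty(0),
                      intercept=float(y.mean()), ridge_weight=ridge_grid[0],
                      r2=0.0, q2_loo=0.0, rmse=0.0,
                      loo_residuals=np.zeros(n))
    col_norm = np.linalg.norm(x, axis=0)
    if not np.any(col_norm > 0):
        raise ValueError("rank-0 design: all feature columns are zero")
    mask = col_norm > 0  # drop identically-zero columns up front

    def best_fit(m: np.ndarray):
        xs = x[:, m]
        best = None
        for lam in ridge_grid:
            coefs, b0, fitted, loo = _ridge_solve(xs, y, lam)
            q2 = _q2_from_press(y, loo)
            if best is None or q2 > best[0]:
                best = (q2, lam, coefs, b0, fitted, loo)
        return best

    current = best_fit(mask)
    while mask.sum() > 0:
        q2, lam, coefs, b0, fitted, loo = current
        sig = np.abs(coefs) * col_norm[mask]
        order = np.argsort(sig, kind="stable")
        active = np.flatnonzero(mask)
        dropped = False
        for rank in order:
            trial_mask = mask.copy()
            trial_mask[active[rank]] = False
            if trial_mask.sum() == 0:
                trial = None
                # intercept-only: Q2 of predicting the (LOO) mean
                loo_mean = (y.sum() - y) / (len(y) - 1)
                q2_trial = _q2_from_press(y, y - loo_mean)
            else:
                trial = best_fit(trial_mask)
                q2_trial = trial[0]
            if q2_trial >= q2 - tol:
                mask = trial_mask
                if trial is None:
                    coefs = np.empty(0)
                    b0 = float(y.mean())
                    fitted = np.full(len(y), b0)
                    loo = y - loo_mean
                    current = (q2_trial, lam, coefs, b0, fitted, loo)
                else:
                    current = trial
                dropped = True
                break
        if not dropped or mask.sum() == 0:
            break
    q2, lam, coefs, b0, fitted, loo = current
    resid = y - fitted
    r2 = 1.0 - float(np.sum(resid ** 2)) / ss_tot
    rmse = float(np.sqrt(np.mean(resid ** 2)))
    return ScrFit(mask=mask, coefs=coefs, intercept=b0, ridge_weight=lam,
                  r2=r2, q2_loo=q2, rmse=rmse, loo_residuals=loo)


# ---------------------------------------------------------------------------
# Sub-models

@dataclass(frozen=True)
class SubModelConfig:
    feature_source: str = "qna"  # "qna" | "mna"
    subset_fraction: float = 1.0
    rbf: bool = True
    top_m: int = 128  # MNA-count block size
    max_degree: int = 4  # QNA Chebyshev degree cap
    max_level: int = 2  # MNA level for count features


@dataclass
class SubModel:
    """One retained RBF–SCR regression with its AD machinery."""

    config: SubModelConfig
    seed: int
    qna_spec: QnaFeatureSpec | None
    vocab: MnaVocabulary | None
    subset_idx: np.ndarray
    rbf_centers: np.ndarray | None
    rbf_width: float | None
    mask: np.ndarray
    coefs: np.ndarray
    intercept: float
    r2: float
    q2_loo: float
    rmse: float
    training_features: np.ndarray  # surviving columns, training rows
    loo_abs_residuals: np.ndarray
    leverage_pinv: np.ndarray  # pinv(XᵀX) over surviving columns

    def _base_features(self, mol: Molecule,
                       props: ElementProperties | None = None) -> np.ndarray:
        if self.config.feature_source == "qna":
            vec = qna_features(mol, props, self.qna_spec)
        else:
            vec = mna_count_features(mol, self.vocab, self.config.top_m,
                                     self.config.max_level)
        return vec[self.subset_idx]

    def featurize(self, mol: Molecule,
                  props: ElementProperties | None = None) -> np.ndarray:
        base = self._base_features(mol, props)
        if self.rbf_centers is not None:
            base = np.concatenate([base, _rbf_columns(
                base[None, :], self.rbf_centers, self.rbf_width)[0]])
        return base[self.mask]

    def predict_value(self, x: np.ndarray) -> float:
        return float(self.intercept + x @ self.coefs)

    def ad_assess(self, x: np.ndarray, k: int = AD_K_NEIGHBORS
                  ) -> tuple[float, bool]:
        """(similarity weight, in_ad) for one featurized query."""
        xt = self.training_features
        n, p = xt.shape
        sims = _cosine_to_rows(x, xt)
        k = min(k, n)
        nearest = np.argsort(-sims, kind="stable")[:k]
        similarity = float(np.mean(sims[nearest]))
        leverage = float(x @ self.leverage_pinv @ x)
        leverage_ok = leverage <= 3.0 * max(p, 1) / n
        accuracy_ok = float(np.mean(self.loo_abs_residuals[nearest])) \
            <= 2.0 * self.rmse if self.rmse > 0 else True
        similarity_ok = similarity > 0
        in_ad = bool(leverage_ok and accuracy_ok and similarity_ok)
        weight = max(similarity, 0.0) if in_ad else 0.0
        return weight, in_ad


def _cosine_to_rows(x: np.ndarray, rows: np.ndarray) -> np.ndarray:
    xn = np.linalg.norm(x)
    rn = np.linalg.norm(rows, axis=1)
    denom = np.clip(xn * rn, 1e-12, None)
    return (rows @ x) / denom


def _rbf_columns(base: np.ndarray, centers: np.ndarray, width: float
                 ) -> np.ndarray:
    d2 = np.sum((base[:, None, :] - centers[None, :, :]) ** 2, axis=2)
    return np.exp(-d2 / (2.0 * width ** 2))


def _median_pairwise_distance(x: np.ndarray, rng: np.random.Generator,
                              max_pairs: int = 2000) -> float:
    n = x.shape[0]
    pairs = [(i, j) for i in range(n) for j in range(i + 1, n)]
    if len(pairs) > max_pairs:
        idx = rng.choice(len(pairs), size=max_pairs, replace=False)
        pairs = [pairs[i] for i in idx]
    dists = [np.linalg.norm(x[i] - x[j]) for i, j in pairs]
    med = float(np.median(dists))
    return med if med > 0 else 1.0


def fit_submodel(reg_set: RegressionSet, config: SubModelConfig, seed: int,
                 props: ElementProperties | None = None,
                 shared: dict | None = None) -> SubModel:
    """Assemble features per config (seeded subset + optional RBF columns)
    and run SCR. ``shared`` may carry precomputed base feature matrices
    keyed by feature source, to amortize work across candidates."""
    n = len(reg_set.entries)
    if n < 20:
        raise ValueError("fit_submodel needs at least 20 compounds")
    props = props or ElementProperties.default()
    rng = np.random.default_rng(seed)
    y = np.asarray(reg_set.values, dtype=float)

    shared = shared if shared is not None else {}
    qna_spec = None
    vocab = None
    if config.feature_source == "qna":
        key = ("qna", config.max_degree)
        if key not in shared:
            spec = fit_qna_bounds(reg_set.molecules, props, config.max_degree)
            mat = np.vstack([qna_features(m, props, spec)
                             for m in reg_set.molecules])
            shared[key] = (spec, mat)
        qna_spec, base_all = shared[key]
    elif config.feature_source == "mna":
        key = ("mna", config.max_level, config.top_m)
        if key not in shared:
            sets = [mna_set(m, config.max_level) for m in reg_set.molecules]
            voc = MnaVocabulary.fit(sets)
            mat = np.vstack([mna_count_features(ds, voc, config.top_m,
                                                config.max_level)
                             for ds in sets])
            shared[key] = (voc, mat)
        vocab, base_all = shared[key]
    else:
        raise ValueError(f"unknown feature source {config.feature_source!r}")

    p_base = base_all.shape[1]
    n_keep = max(2, int(round(config.subset_fraction * p_base)))
    subset_idx = np.sort(rng.choice(p_base, size=min(n_keep, p_base),
                                    replace=False))
    base = base_all[:, subset_idx]

    rbf_centers = None
    rbf_width = None
    feats = base
    if config.rbf:
        n_centers = min(50, max(2, n // 4))
        center_rows = rng.choice(n, size=n_centers, replace=False)
        rbf_centers = base[np.sort(center_rows)]
        rbf_width = _median_pairwise_distance(base, rng)
        feats = np.hstack([base, _rbf_columns(base, rbf_centers, rbf_width)])

    fit_res = scr_fit(feats, y, seed=seed)
    surviving = feats[:, fit_res.mask]
    gram_pinv = np.linalg.pinv(surviving.T @ surviving) \
        if surviving.shape[1] else np.zeros((0, 0))
    return SubModel(
        config=config, seed=seed, qna_spec=qna_spec, vocab=vocab,
        subset_idx=subset_idx, rbf_centers=rbf_centers, rbf_width=rbf_width,
        mask=fit_res.mask, coefs=fit_res.coefs, intercept=fit_res.intercept,
        r2=fit_res.r2, q2_loo=fit_res.q2_loo, rmse=fit_res.rmse,
        training_features=surviving,
        loo_abs_residuals=np.abs(fit_res.loo_residuals),
        leverage_pinv=gram_pinv)


# ---------------------------------------------------------------------------
# Consensus

@dataclass
class ConsensusModel:
    submodels: list[SubModel]
    isoform: str
    r2_min: float = R2_MIN
    q2_min: float = Q2_MIN
    training_interval: tuple[float, float] = (float("nan"), float("nan"))
    training_mean: float = float("nan")
    n_candidates: int = 0
    seed: int = 0

    @property
    def n_models(self) -> int:
        return len(self.submodels)


@dataclass
class RegressionPrediction:
    value: float | None
    in_ad: bool
    n_contributing: int
    weights: list[float]


def candidate_configs(n_candidates: int) -> list[SubModelConfig]:
    """Deterministic roster of varied sub-model configurations."""
    sources = ("qna", "mna")
    fractions = (1.0, 0.8, 0.6)
    rbf_opts = (True, False)
    configs = []
    i = 0
    while len(configs) < n_candidates:
        configs.append(SubModelConfig(
            feature_source=sources[i % 2],
            rbf=rbf_opts[(i // 2) % 2],
            subset_fraction=fractions[(i // 4) % 3]))
        i += 1
    return configs


def passes_selection(sub: SubModel, r2_min: float = R2_MIN,
                     q2_min: float = Q2_MIN) -> bool:
    """Strict-inequality consensus admission: R² and Q² must *exceed*
    their thresholds; equality is rejected."""
    return sub.r2 > r2_min and sub.q2_loo > q2_min


def build_consensus(reg_set: RegressionSet, n_candidates: int, seed: int,
                    r2_min: float = R2_MIN, q2_min: float = Q2_MIN,
                    props: ElementProperties | None = None) -> ConsensusModel:
    """Fit ``n_candidates`` varied sub-models and keep those with
    R² > r2_min and Q² > q2_min (strict)."""
    if n_candidates < 1:
        raise ValueError("n_candidates must be >= 1")
    props = props or ElementProperties.default()
    shared: dict = {}
    retained = []
    for i, config in enumerate(candidate_configs(n_candidates)):
        sub = fit_submodel(reg_set, config, seed=seed + i, props=props,
                           shared=shared)
        if passes_selection(sub, r2_min, q2_min):
            retained.append(sub)
        else:
            logger.debug("candidate %d rejected (R2=%.3f, Q2=%.3f)",
                         i, sub.r2, sub.q2_loo)
    if not retained:
        raise ValueError(
            "no sub-model exceeded the selection thresholds "
            f"(R2 > {r2_min}, Q2 > {q2_min}); review candidate "
            "configurations or the training set")
    lo, hi = reg_set.value_interval
    return ConsensusModel(submodels=retained, isoform=reg_set.isoform,
                          r2_min=r2_min, q2_min=q2_min,
                          training_interval=(lo, hi),
                          training_mean=reg_set.mean_value,
                          n_candidates=n_candidates, seed=seed)


def consensus_predict(model: ConsensusModel, mol: Molecule,
                      props: ElementProperties | None = None
                      ) -> RegressionPrediction:
    """Similarity-weighted average over in-AD sub-models; consensus AD flag
    set when at least half the sub-models report the query in-domain."""
    props = props or ElementProperties.default()
    values, weights, flags = [], [], []
    for sub in model.submodels:
        x = sub.featurize(mol, props)
        values.append(sub.predict_value(x))
        w, ok = sub.ad_assess(x)
        weights.append(w)
        flags.append(ok)
    total = sum(weights)
    n_contrib = sum(1 for w in weights if w > 0)
    in_ad = sum(flags) >= len(flags) / 2.0
    if total <= 0:
        return RegressionPrediction(value=None, in_ad=False,
                                    n_contributing=0, weights=weights)
    value = float(np.dot(weights, values) / total)
    return RegressionPrediction(value=value, in_ad=bool(in_ad),
                                n_contributing=n_contrib,
                                weights=[w / total for w in weights])


def assign_sorted_folds(values: Sequence[float], n_folds: int = 5
                        ) -> np.ndarray:
    """Fold id per compound: sort ascending by value, rank i → fold i mod k."""
    order = np.argsort(np.asarray(values), kind="stable")
    folds = np.empty(len(values), dtype=int)
    folds[order] = np.arange(len(values)) % n_folds
    return folds


def five_fold_protocol(reg_set: RegressionSet, n_candidates: int, seed: int,
                       n_folds: int = 5,
                       props: ElementProperties | None = None
                       ) -> dict[str, float]:
    """Sorted-ascending 5-fold external validation of the consensus builder.

    Returns pooled R², RMSE over held-out compounds and the percentage of
    held-out compounds inside the applicability domain. Held-out compounds
    with no contributing sub-model are predicted by the unweighted mean of
    the sub-model outputs (and counted outside the AD).
    """
    n = len(reg_set.entries)
    if n < 25:
        raise ValueError("five_fold_protocol needs at least 25 compounds")
    props = props or ElementProperties.default()
    folds = assign_sorted_folds(reg_set.values, n_folds)
    y_true, y_pred, in_ad_flags = [], [], []
    for f in range(n_folds):
        train_entries = [e for e, fl in zip(reg_set.entries, folds) if fl != f]
        test_entries = [e for e, fl in zip(reg_set.entries, folds) if fl == f]
        train_vals = [y for _, y in train_entries]
        sub_set = RegressionSet(
            isoform=reg_set.isoform, entries=train_entries,
            value_interval=(min(train_vals), max(train_vals)),
            mean_value=float(np.mean(train_vals)))
        model = build_consensus(sub_set, n_candidates, seed=seed + 1000 * f,
                                props=props)
        for mol, yv in test_entries:
            pred = consensus_predict(model, mol, props)
            if pred.value is None:
                fallback = [s.predict_value(s.featurize(mol, props))
                            for s in model.submodels]
                y_pred.append(float(np.mean(fallback)))
            else:
                y_pred.append(pred.value)
            y_true.append(yv)
            in_ad_flags.append(pred.in_ad)
    m = metrics(y_true, y_pred)
    return {"R2_5cv": m["R2"], "RMSE_5cv": m["RMSE"],
            "AD_percent": 100.0 * float(np.mean(in_ad_flags))}
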