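"""Build an RBF-SCR consensus QSAR for pIC50 and validate it 5-fold.

Candidate sub-models vary their feature source (QNA polynomial features
vs MNA presence counts), feature subsets and RBF augmentation; only
candidates with training R2 > 0.6 and leave-one-out Q2 > 0.5 enter the
consensus. Predictions are similarity-weighted averages with a
three-part applicability domain (similarity, leverage, accuracy).
"""

from cypqsar import FixtureSpec, build_consensus, consensus_predict, \
    five_fold_protocol, gen_regression_fixture

rset, _ = gen_regression_fixture(
    FixtureSpec(n_molecules=130, seed=11, sigma=0.3))
print(f"training set: {len(rset.entries)} compounds, "
      f"pIC50 in [{rset.value_interval[0]:.2f}, "
      f"{rset.value_interval[1]:.2f}], mean {rset.mean_value:.2f}")

model = build_consensus(rset, n_candidates=8, seed=3)
print(f"consensus: {model.n_models}/8 candidates retained "
      f"(R2 > {model.r2_min}, Q2 > {model.q2_min})")
for sub in model.submodels:
    print(f"  {sub.config.feature_source:3s} rbf={sub.config.rbf!s:5s} "
          f"R2={sub.r2:.3f} Q2={sub.q2_loo:.3f} RMSE={sub.rmse:.3f}")

mol, y = rset.entries[0]
pred = consensus_predict(model, mol)
print(f"\n{mol.smiles}: predicted pIC50 {pred.value:.2f} "
      f"(observed {y:.2f}), in_AD={pred.in_ad}, "
      f"{pred.n_contributing} sub-models contributing")

table = five_fold_protocol(rset, n_candidates=8, seed=3)
print(f"\n5-fold validation (sorted ascending, rank i -> fold i mod 5):")
print(f"  R2={table['R2_5cv']:.3f}  RMSE={table['RMSE_5cv']:.3f}  "
      f"AD={table['AD_percent']:.1f}%")
print("(R2/RMSE pooled over held-out folds; AD% = held-out compounds "
      "inside the applicability domain)")
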