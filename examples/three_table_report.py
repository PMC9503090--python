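"""The three-table prediction report for a query structure.

Table A: numerical pIC50 per isoform from the consensus QSAR (predicted
pIC50 above 6 inside the applicability domain flags a potential
inhibitor). Table B: classifier activities with Pa > Pi — legitimately
empty when nothing passes. Table C: inducer activities (absent here, so
reported as not available). The query is excluded from the training
sets before prediction, so a training compound is scored honestly.
"""

from cypqsar import FixtureSpec, ModelBundle, TrainingRegistries, \
    build_consensus, exclude_and_predict, fit, gen_classification_fixture, \
    gen_regression_fixture

cset, _ = gen_classification_fixture(
    FixtureSpec(n_molecules=80, seed=51, epsilon=0.0))
rset, _ = gen_regression_fixture(
    FixtureSpec(n_molecules=80, seed=52, sigma=0.2))
bundle = ModelBundle(qsar={"3A4": build_consensus(rset, 4, seed=53)},
                     inhibitor_model=fit({"CYP 3A4 inhibitor": cset}))
registries = TrainingRegistries(qsar={"3A4": rset},
                                inhibitor={"CYP 3A4 inhibitor": cset})

query = cset.molecules[0]  # a training compound: excluded before predicting
report = exclude_and_predict(bundle, query, registries)
print(f"query: {report.smiles}\n")

print("table A - consensus QSAR (pIC50):")
for row in report.table_qsar:
    val = "n/a" if row["pic50"] is None else f"{row['pic50']:.2f}"
    print(f"  CYP {row['isoform']}: pIC50={val} in_AD={row['in_ad']} "
          f"potential_inhibitor={row['potential_inhibitor']}")

print("\ntable B - inhibitor activities with Pa > Pi:")
if report.table_inhibitor:
    for row in report.table_inhibitor:
        print(f"  {row['activity']}: Pa={row['pa']:.3f} Pi={row['pi']:.3f}")
else:
    print("  (none - the compound is not classified as a CYP inhibitor)")

print("\ntable C - inducer activities:",
      "not available (no inducer model in this bundle)"
      if report.table_inducer is None else report.table_inducer)
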