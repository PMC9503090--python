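"""Curate raw bioactivity tables into training sets.

Generates the two raw table dialects (ChEMBL-export style with IC50/%
inhibition rows, PubChem-bioassay style with outcome + curve class),
then applies the curation rules: the 10,000 / 20,000 nM cuts, the >50%
inhibition rule, conflict removal and per-structure median aggregation.
"""

import tempfile
from pathlib import Path

from cypqsar import FixtureSpec, gen_raw_tables
from cypqsar.curation import build_classification_set, build_regression_set, \
    read_chembl_table, read_pubchem_table

with tempfile.TemporaryDirectory() as tmp:
    paths = gen_raw_tables(FixtureSpec(n_molecules=40, seed=17), tmp)
    chembl = read_chembl_table(paths["chembl"])
    pubchem = read_pubchem_table(paths["pubchem"])

    cset = build_classification_set(chembl + pubchem, "3A4")
    print(f"classification set (CYP {cset.isoform}): "
          f"{cset.n_pos} inhibitors, {cset.n_neg} noninhibitors")
    print(f"  conflicting structures removed: {cset.n_conflicts_removed}")
    print(f"  indeterminate records set aside: {cset.n_indeterminate}")

    rset = build_regression_set(chembl, "3A4")
    lo, hi = rset.value_interval
    print(f"regression set: {len(rset.entries)} structures, "
          f"pIC50 in [{lo:.2f}, {hi:.2f}], mean {rset.mean_value:.2f}")
    print("(only relation '=' IC50 records; duplicate structures collapsed "
          "to their nM-scale median)")
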