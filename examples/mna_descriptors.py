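"""Multilevel Neighborhoods of Atoms descriptors for a few small molecules.

Each descriptor is a string describing one atom's environment up to a
given bond radius; acyclic atoms carry a "-" mark. These strings are the
whole structural representation the inhibitor classifier sees.
"""

from cypqsar import mna_set, novelty_fraction, parse_smiles
from cypqsar.mna import MnaVocabulary

for name, smiles in [("methane", "C"), ("water", "O"),
                     ("benzene", "c1ccccc1"), ("paracetamol",
                                               "CC(=O)Nc1ccc(O)cc1")]:
    mol = parse_smiles(smiles)
    ds = mna_set(mol, max_level=2)
    print(f"{name} ({smiles}): {len(ds)} unique descriptors")
    for text in list(ds)[:4]:
        print("   ", text)

# a vocabulary frozen on two molecules, probed with a third: the fraction
# of unseen descriptors ("novelty") drives the applicability domain
vocab = MnaVocabulary.fit([mna_set(parse_smiles(s), 2)
                           for s in ("CCO", "c1ccccc1")])
query = mna_set(parse_smiles("CC(=O)Nc1ccc(O)cc1"), 2)
print(f"\nnovelty of paracetamol vs {{ethanol, benzene}} vocabulary: "
      f"{novelty_fraction(query, vocab):.2f}")
print("(fractions above 0.25 put a query outside the applicability domain)")
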