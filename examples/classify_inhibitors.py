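"""Fit the naive-Bayes inhibitor classifier and validate it with IAP.

The model counts, per activity and per MNA descriptor, how many positive
and negative training molecules contain it; Pa ("to be active") and Pi
("to be inactive") are tail probabilities of a query's score against the
training leave-one-out score distributions. IAP is the probability that
a random positive outscores a random negative (numerically a ROC AUC).
"""

from cypqsar import FixtureSpec, gen_classification_fixture
from cypqsar import pass_classifier as pc

ACT = "CYP 3A4 inhibitor"

cset, _ = gen_classification_fixture(
    FixtureSpec(n_molecules=120, seed=7, epsilon=0.0))
model = pc.fit({ACT: cset})
print(f"trained on {cset.n_pos} inhibitors / {cset.n_neg} noninhibitors, "
      f"vocabulary of {len(model.vocab)} descriptors")

print(f"IAP (leave-one-out): {pc.iap_loo(model, ACT):.3f}")
print(f"IAP (20-fold CV):    "
      f"{pc.iap_kfold({ACT: cset}, ACT, k=20, seed=1):.3f}")
print("(1.0 = perfect ranking of positives above negatives, 0.5 = chance)")

for mol, label in (cset.entries[0], next(e for e in cset.entries
                                         if e[1] != cset.entries[0][1])):
    pred = pc.pa_pi(model, mol, ACT)
    print(f"\n{mol.smiles}  (training label: "
          f"{'inhibitor' if label else 'noninhibitor'})")
    print(f"  Pa={pred.pa:.3f} Pi={pred.pi:.3f} "
          f"possible={pred.possible} in_AD={pred.in_ad} "
          f"novelty={pred.novelty:.2f}")
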