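# Methods

This note documents the models implemented in `cypqsar`, the choices
made where the published methodology leaves the details open, and what
the synthetic test data does and does not establish.

## Curation model

Raw records are single bioactivity measurements against one CYP isoform
(1A2, 2C9, 2C19, 2D6 or 3A4) in one of two dialects. The ChEMBL-export
dialect carries an endpoint (IC50 in nM, or % inhibition at a single
concentration), a relation sign and a value; the PubChem-bioassay
dialect carries a categorical outcome and a curve-class annotation.

Classification labels: IC50 < 10,000 nM with relation in {=, ≤, <} →
inhibitor; IC50 > 20,000 nM with relation in {=, ≥, >} → noninhibitor;
% inhibition strictly above 50 → inhibitor, otherwise noninhibitor;
PubChem "active" supported by a complete curve → inhibitor, "inactive"
→ noninhibitor. Everything else — the open (10, 20) µM gap, censored
values whose sign points the wrong way, unconfirmed actives — is
*indeterminate* and kept in an audit count rather than silently
dropped. Structure identity is the canonical SMILES of the standardized
molecule (largest covalent fragment, stereochemistry stripped). A
structure labelled both ways is a conflict and is removed entirely;
same-label duplicates collapse to one entry. All labelled records for a
structure participate in conflict detection, regardless of endpoint.

Regression sets keep only relation "=" IC50 records. Duplicate
structures are collapsed to the *median on the nM scale*, then
converted via pIC50 = −log₁₀(IC50·10⁻⁹). Median-then-log and
log-then-median agree for odd duplicate counts and differ slightly for
even ones; the nM-scale order is fixed here and tested.

## Standardization

Input structures (SMILES or SD files) are sanitized with RDKit; the
largest fragment is kept, stereochemistry is discarded and hydrogens
are made explicit (the descriptors below are constitution-only). "In
ring" means membership in any cycle of the molecular graph — a
representation-independent property. No tautomer canonicalization or
charge neutralization is attempted; structures that fail valence
sanitization are rejected (SMILES) or skipped with a logged index
(SDF).

## MNA descriptors

The level-n descriptor rooted at atom a is
`D0(a) = label(a)`, `Dn(a) = label(a) + "(" + sorted Dn−1(neighbors) + ")"`,
where the label is the element symbol with a "-" prefix on acyclic
atoms; children sort byte-wise, making the string independent of atom
numbering. A molecule's descriptor *set* is the union over atoms of
levels 1..2 by default (level 0 adds nothing beyond the level-1 roots;
the maximum level is configurable). Set semantics are deliberate: the
applicability-domain rule counts *kinds* of new descriptors, not
occurrences. Charges, isotopes and unusual valences are not marked —
the alphabet here is element + ring flag only. For an atom with no
neighbors the recursion descends through a phantom empty child, so
levels stay distinguishable ("-He()", "-He(())").

## Classifier (Pa/Pi, IAP)

For each activity the model stores, per descriptor d, the number of
positive and negative training molecules containing d. The raw score of
a query is the mean of 2p̂(d) − 1 over its descriptors known to that
activity, with Laplace smoothing p̂(d) = (n⁺(d)+1)/(n⁺(d)+n⁻(d)+2).
"Known to that activity" means a nonzero count within the activity:
this makes leave-one-out by count subtraction *exactly* equal to an
explicit refit (a refitted model has no support on descriptors unique
to the removed molecule), which the tests assert molecule by molecule.
Descriptors outside the model vocabulary never touch the score; they
only raise the novelty fraction.

Pa is the fraction of training positives whose LOO score lies strictly
below the query score, plus half the ties; Pi mirrors this over the
negatives from above. Both are therefore monotone in the score, and an
activity is "possible" when Pa > Pi (strict). IAP is the probability
that a random positive's LOO score exceeds a random negative's, ties at
half weight, computed by exact enumeration over all pairs — numerically
the ROC AUC, which an independent rank-based implementation confirms to
1e−12 in the tests.

k-fold IAP uses class-stratified folds drawn from a seeded generator;
the constraint is that every *training remainder* keeps both classes
(held-out folds may be single-class because scoring is pooled), so the
k = n limit reproduces leave-one-out exactly.

Applicability domain: a query whose descriptor set contains more than
25% descriptors unseen in training is outside the domain; the threshold
is inclusive ("up to 25%") and configurable.

## QNA descriptors and features

Per heavy atom, with IP/EA the tabulated ground-state atomic ionization
potential and electron affinity (eV), A = (IP+EA)/2, B = IP−EA,
E = exp(−C) for the unweighted heavy-atom adjacency C (evaluated by
symmetric eigendecomposition):

    P_i = B_i^{−1/2} Σ_k E_ik B_k^{−1/2} A_k,
    Q_i = B_i^{−1/2} Σ_k E_ik B_k^{−1/2}.

Hydrogens are excluded (H has no stable place in an EA-based table that
also treats it as a terminal decoration), C carries no bond-order
weights, and the element table ships as packaged CSV (NIST atomic
values for H, B, C, N, O, F, Si, P, S, Cl, As, Se, Br, Sn, Te, I).
These three choices are fixed conventions of this package.

Molecule-level features are means over atoms of Chebyshev products
T_j(P̃)·T_k(Q̃), j+k ≤ 4 (15 features), with P̃, Q̃ the values affinely
mapped into [−1, 1] by training-set bounds and clipped; degenerate
bounds map to 0 with a warning. The alternative feature source is a
binary presence vector over the most frequent training MNA descriptors
(128 by default — large enough to cover substituent-bearing descriptors
on the synthetic sets; frequency ties break by descriptor text).

## SCR, sub-models and consensus

A sub-model is a ridge regression with an unpenalized intercept. The
ridge weight is picked from a fixed grid {1e−4 … 10} by leave-one-out
Q², computed exactly through the hat-matrix identity
e_i/(1 − h_ii) (verified against explicit refits to 1e−8). Variable
selection then repeatedly eliminates the least significant feature —
smallest |coefficient|·column-norm, trying candidates in increasing
significance order — as long as Q² does not drop by more than 1e−4;
the procedure is deterministic. A numerically constant response yields
an intercept-only model with R² defined as 0.

Candidate sub-models vary the feature source (QNA / MNA counts), a
seeded feature-subset fraction (1.0 / 0.8 / 0.6) and optional RBF
augmentation: Gaussian kernel columns to a seeded sample of
min(50, n/4) training rows, kernel width set by the median pairwise
training distance. Only candidates with training R² > 0.6 *and* LOO
Q² > 0.5 — strict inequalities — enter the consensus; an empty
consensus is an error, not a silent fallback.

Applicability domain, per sub-model: (i) similarity — mean cosine
similarity to the k = 3 nearest training rows, which must be positive;
(ii) leverage — h(x) = x(XᵀX)⁻¹xᵀ ≤ 3p/n; (iii) accuracy — the mean
|LOO residual| of those k neighbours at most twice the training RMSE.
A query inside all three contributes its similarity as weight; the
consensus prediction is the weight-normalized average, the consensus AD
flag requires at least half the sub-models in-domain, and a query no
sub-model accepts yields an explicit "no prediction". The k, the 3p/n
cutoff, the 2·RMSE bound and the ≥-half rule are declared conventions.

Validation: compounds are sorted by ascending pIC50 and rank i goes to
fold i mod 5, so every fold spans the activity range; per fold the full
consensus is rebuilt on the remainder and held-out compounds are
predicted, giving pooled R², RMSE and the % of held-out compounds in
the AD. Held-out compounds rejected by every sub-model are scored by
the unweighted sub-model mean (and counted out-of-AD) so the pooled
metrics cover all compounds.

## Synthetic data

The generator assembles unique molecules from four ring scaffolds
(benzene, pyridine, cyclohexane, furan) decorated at two sites with 19
fragments, all in packaged CSV. Classification truth is carrying a
halogen/CF3 "pharmacophore" decoration, with labels flipped at
probability ε (default 0); regression truth is scaffold base value +
additive fragment contributions + Gaussian noise (σ = 0.3 by default,
roughly the replicate spread of public IC50 data). Defaults of 120–130
molecules keep the full 5-fold consensus protocol in the tens of
seconds. The raw-table generator additionally plants hand-written rows
(on iodoarenes, which the library cannot produce) covering every
relation sign, the exact 10/20 µM and 50% boundaries, one
inhibitor/noninhibitor conflict and one duplicate trio whose median is
exactly pIC50 6.

What passing on these fixtures shows: the rules, estimators and
cross-validation machinery are implemented exactly as stated, and the
engines can recover a planted additive/substructure signal through the
descriptor layer. What it does not show: predictive accuracy on real
CYP chemistry — real bioactivity data has scaffold diversity, assay
heterogeneity, activity cliffs and class imbalance that no fixture
here emulates. On these fixtures the binary MNA features dominate and
the 15 smooth QNA features are usually rejected by the admission
filter; on real, conformationally diverse sets the balance can differ.

## Known limitations

* The classifier's score and Pa/Pi estimator are declared forms (the
  published description of the underlying engine names the estimator
  family but not its exact statistic); likewise the SCR elimination
  rule, the RBF width/center rules and the AD constants. All are
  stated above and fixed by tests, but they are this package's canon,
  not a reverse-engineered original.
* Drug-name input, tautomer handling and charge-aware descriptors are
  out of scope; inducer activities are supported only as user-supplied
  training sets through the same classifier engine.
* Per-source vs pooled ("Total") training sets are the caller's
  choice: conflict removal runs on whatever record pool is passed in.
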