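# hotcontact

Characterization of **protein–protein binding hot spots** — interfacial
residues whose mutation to alanine raises the binding free energy change
by ΔΔG ≥ 2 kcal/mol — from the atomic contacts a mutation removes and
the way those contacts co-occur.

`hotcontact` is for structural bioinformaticians who have a protein
complex (PDB format, with crystallographic B factors), a table of
alanine mutations, and optionally experimental ΔΔG values, and who want
to (a) extract an interpretable atomic-contact descriptor per mutation,
(b) regress ΔΔG with a random forest under leave-complex-out
cross-validation, and (c) rank which contact classes drive hot spots.

## The method

**β atomic contacts.** Two atoms *i*, *j* are in contact when
dist(i, j) ≤ 1.25 (vdw_i + vdw_j) *and* no third atom k sees the pair
under an angle ∠(i, k, j) ≥ 85° — the lune ("forbidden region") test of
a β-skeleton. This keeps only contacts with unobstructed interaction
geometry; aromatic rings contribute through two pseudo-atoms placed
±0.5 Å along the ring normal, and buried waters (ASA < 1 Å², ≥ 3 β
contacts to donors/acceptors) join the graph.

**B-factor weighting.** Per complex, B factors are trimmed (1% lowest,
9% highest), normalized so the 90% band maps to [−1, 1], then shifted
and clamped to B″ ∈ [−2, 0] (rigid → −2, flexible → 0). Every contact
carries the weight (B″_i + B″_j)/2, so rigid, well-ordered contacts
contribute the most negative values.

**The 143-element descriptor** per alanine mutation concatenates:

| block | size | content |
|---|---|---|
| B factor | 8 | B_avg and B_dif of the mutated atoms, slotted by amino-acid class |
| ΔASA | 2 | ln(ΔASA+1) and ΔASA/ASA of the mutated residue |
| mutated contacts | 14 | weight sums per contact type touching the mutated atoms |
| neighborhood | 14 | cross-interface contacts within 3 covalent-bond steps |
| co-occurrence | 105 | unordered contact-type pairs within 3 bond steps |

Atoms fall into 10 chemical groups (C_c = carbons with no covalent bond
to O/N, C_on = carbons with one, donors, acceptors, π pseudo-atoms,
sulfur, water, …), contacts into 14 types (hydrogen bonds, hydrophobic
C_c–C_c, π-involving, acceptor–acceptor, …). Two contacts *co-occur*
when an endpoint of one is within 3 covalent-bond steps of an endpoint
of the other — co-occurring hydrogen bonds describe hydrogen-bond
networks, and co-occurring hydrophobic/π contacts describe packed
aromatic clusters.

**Regression.** A 500-tree random forest (terminal nodes ≥ 3 mutations,
features per split = one third of those retained) predicts ΔΔG from the
descriptor after dropping features with ≤ 3 non-zero values. Evaluation
uses leave-complex-out cross-validation (all mutations of one complex
are the test fold) with hot-spot calls at ΔΔG_p ≥ 1.5 kcal/mol, and
%IncMSE permutation importance (out-of-bag) ranks the features.

## Worked example

No curated crystal structures are needed to try the pipeline: the
package generates synthetic two-chain complexes with planted interface
motifs and a linear-plus-noise ΔΔG.

```python
from hotcontact.synthetic_fixtures import make_study
from hotcontact.rf_model import loco_cv, train, permutation_importance
from hotcontact.evaluation import pcc

study = make_study(n_complexes=20, seed=11)   # 232 mutations, 22% hot spots
cv = loco_cv(study, seed=5)
print(round(pcc(cv["ddg_pred"], cv["ddg_obs"]), 3))
# 0.846

model = train(study, seed=5)
print(permutation_importance(model, study, n_repeats=3, seed=5).head(3))
# mut_t03         135.556037
# cooc_t03_t03     41.267230
# bavg_g1           4.642893
```

The out-of-fold Pearson correlation of 0.846 shows the forest recovers
the planted contact signal across complexes it never saw, and the
top-ranked feature (`mut_t03`, mutated hydrophobic C_c–C_c contacts,
%IncMSE ≈ 136) is exactly the feature the generator weighted most.

On real data the same flow runs from the shell:

```bash
hotcontact extract complex.pdb A:B mutations.tsv -o features.tsv
hotcontact cv features.tsv -o cv_predictions.tsv
hotcontact evaluate cv_predictions.tsv
```

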