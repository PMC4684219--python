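# Methods

This note documents the models, parameters and design decisions behind
`hotcontact`, in the spirit of a methods supplement: what is computed,
under which assumptions, and what the synthetic benchmarks do and do not
demonstrate.

## Structural model

PDB entries are read through Biopython (first model only; mmCIF and
hydrogen placement are out of scope). Hydrogens are discarded — the
method is defined entirely on heavy atoms and pseudo-atoms, and typical
crystal structures lack hydrogens anyway. Alternate locations resolve to
the highest-occupancy conformer (first in file order on ties).
Non-standard residues are skipped with a warning; a missing chain or a
missing B factor is fatal, because the method cannot run without either.

Covalent bonds are inferred by distance (≤ 1.9 Å heavy–heavy, ≤ 2.2 Å
when sulfur is involved, C(i)–N(i+1) for consecutive residues) rather
than residue templates. This is robust to idealized synthetic geometry
and to mildly distorted real structures; on ideal amino-acid geometry it
reproduces the canonical bond sets exactly (tested).

Aromatic rings (PHE, TYR, HIS, both TRP rings) are augmented with two
pseudo-atoms at the centroid ± 0.5 Å along the least-squares plane
normal. Pseudo-atoms carry the mean B factor of their ring, the
aromatic-carbon van der Waals radius, and are covalently linked (one
step) to every ring atom so that "within 3 bond steps" semantics reach π
contacts. They may be contact endpoints but never interrupt other
contacts and never occlude surface area: they are bookkeeping
constructs, not matter. Incomplete rings are skipped with a warning.

Van der Waals radii ship as an editable TSV (Bondi-type heavy-atom
values; C 1.70, N 1.55, O 1.52, S 1.80 Å). An unknown element is fatal.

## β contacts and the interface graph

A pair (i, j) is a β contact when

1. dist(i, j) ≤ T_d = 1.25 · (vdw_i + vdw_j), and
2. no third atom k satisfies ∠(i, k, j) ≥ 85°, the angle measured at
   k's center.

The angle criterion is the lune characterization of a β-skeleton: an
atom lying between the pair sees it under a wide angle and interrupts
it. Interrupters are real atoms only (waters included, pseudo-atoms
excluded); interrupter radii do not inflate the forbidden region —
centers-only is an explicit assumption, with the factor 1.25 and 85°
configurable (td_factor meaningfully in [1.1, 1.6]).

Atom pairs of the same residue, and covalently bonded pairs, are never
contacts: an atomic contact is a non-bonded interaction, and without
this exclusion trivial 1-2/1-3 neighbor pairs would dominate every
feature. This exclusion is applied identically in the production search
and the brute-force oracle.

The production search uses a k-d tree twice (candidate pairs within the
largest T_d; interrupter candidates within d/sin β of the pair
midpoint, a bound that provably contains every atom with angle ≥ β).
Its output is required — and tested on random 60–300-atom fixtures — to
equal an O(n³) brute-force oracle exactly.

Graph assembly: interfacial atoms have ≥ 1 cross-interface contact;
supporting atoms are non-interfacial atoms contacting an interfacial
one (either side — the method does not restrict the chain); the
neighborhood adds all non-backbone atoms within 3 covalent-bond steps
of those. The graph keeps every contact touching the neighborhood. A
water joins when its ASA in the crystallized complex (waters present)
is below 1 Å² and it makes ≥ 3 β contacts with nitrogen or oxygen
atoms; water–water contacts are never recorded, and protein–water
contacts count as same-side. An empty interface is a warning, not an
error: the features of such a complex are legitimately zero.

## B-factor normalization

Per complex, over all parsed heavy atoms (waters included, pseudo-atoms
excluded): sort the B factors, drop floor(0.01 n) smallest (guards
against erroneous B = 0 entries) and floor(0.09 n) largest (outliers),
and take mean and population standard deviation of the rest. Then

    B_norm = (B − mean) / (1.645 · sd)        # 90% band → [−1, 1]
    B″     = clamp(B_norm − 1, [−2, 0])

The clamp sends values outside the band to whichever endpoint is
closer: −2 for rigid outliers, 0 for flexible ones. One subtlety is
deliberate: the printed form of this clamp in the literature source
evaluates to the constant 0 if read literally; the implementation
follows the accompanying prose ("either −2 or 0, whichever is closer"),
the only reading that yields a non-degenerate feature. B″ ∈ [−2, 0]
always (property-tested), and adding a constant to all B factors of a
complex leaves every B″ unchanged.

The 8-element block: amino acids fall into four classes
(ILE/VAL/LEU/MET/ALA/GLY; CYS/THR/SER/PRO/HIS/GLN/ASN;
GLU/ASP/LYS/ARG; PHE/TRP/TYR). For the mutated residue's class p
(0-indexed), position 2p holds B_avg (mean B″ over the mutated atoms)
and 2p+1 holds B_dif (B_avg minus the mean B″ of the residue's backbone
N and C atoms — taken literally as N and C, not CA/O). The other six
positions are exactly zero.

**Mutated atoms** are the side-chain heavy atoms beyond CB — the atoms
an X→Ala substitution removes — plus the residue's ring pseudo-atoms,
so that π-involving contacts of mutated aromatics register in the
mutated-contact block.

## ASA and ΔASA

ASA is a numerical Shrake–Rupley implementation on the package's own
atom model: 960 quasi-uniform (golden-spiral) points per atom at radius
vdw + 1.4 Å, a point being accessible when outside every other expanded
sphere. 960 points and the 1.4 Å probe are the conventional defaults;
single-atom ASA converges to the closed form 4π(r+w)² within 1% and
halving/doubling the point count is tested for stability. The two ΔASA
features of a mutation are ln(ΔASA + 1) (natural log; +1 guards the
zero case) and ΔASA/ASA_unbound, where ΔASA = ASA of the mutated
residue in its unbound side minus in the bound complex, clamped at 0,
waters excluded. The water-burial test of the contact graph instead
uses the complex as crystallized, waters included.

## Atom groups and contact types

The published 10-group/14-type supplementary tables are not available;
the bundled tables are **reconstructions** that honor every constraint
the main text fixes: type 0 = hydrogen-bond (donor–acceptor) contacts,
type 2 = C_c with O/N, type 3 = C_c–C_c, type 4 = C_on with O/N, type
5 = C_on–C_c, type 9 = π-involving, type 13 = acceptor–acceptor, where
C_c/C_on split carbons by covalent bonding to O/N. The remaining
freedom is filled by chemically natural splits: donor–donor (1),
C_on–C_on (6), sulfur–carbon (7), sulfur–polar (8), water–polar (10),
sulfur–sulfur (11), water–carbon (12). The ten atom groups are nitrogen
donors, carbonyl/carboxylate oxygens, hydroxyl oxygens (donor+acceptor),
histidine ring nitrogens, C_c, C_on, sulfur, π pseudo-atoms, proline
backbone N (acceptor only), and water oxygen. Both tables ship as
editable TSVs; retraining is required before comparing against models
built on the original tables, and exact replication of published
importance rankings is out of scope for that reason.

## Feature vectors

Contact weight: w(c) = (B″_i + B″_j)/2 ∈ [−2, 0]. The mutated block
sums w over graph contacts touching ≥ 1 mutated atom (once per contact,
even if both endpoints are mutated), by type. The neighborhood block
sums w over *cross-interface* contacts touching the mutation's own
neighborhood (mutated atoms ∪ their contact partners ∪ non-backbone
atoms within 3 bond steps). The co-occurrence block indexes unordered
type pairs (t ≤ t′) in row-major upper-triangular order (105 = 14·15/2
entries); two contacts co-occur when an endpoint of one is within 3
covalent-bond steps — step 0, a shared atom, included — of an endpoint
of the other, and the scope is pairs with ≥ 1 member among the mutated
contacts. Each unordered pair contributes w(c) + w(c′) exactly once.

All 143 positions are named; every per-element sum uses exact (fsum)
accumulation, so the assembled vector is bit-identical under any
permutation of the input atom order (tested).

## Random forest

scikit-learn's RandomForestRegressor with the two fixed hyperparameters
(500 trees, min terminal node 3) plus the regression convention of one
third of retained features per split (the source is silent; the value
is configurable). Features non-zero in ≤ 3 training rows are dropped
*inside each training fold* — fold-local filtering avoids test-fold
leakage; whether the published filter was global is ambiguous, and the
defensible choice is taken. Leave-complex-out CV trains one model per
complex on all others; every mutation is predicted exactly once by a
model that never saw its complex.

%IncMSE importance: (MSE_permuted − MSE_baseline)/MSE_baseline · 100,
both MSEs out-of-bag (per-tree unsampled rows, reconstructed exactly as
the forest's own OOB bookkeeping and verified against it), averaged
over permutation repeats, with an in-sample fallback if OOB bookkeeping
is unavailable.

## Evaluation

Hot-spot truth: ΔΔG ≥ 2 kcal/mol, or the label 'Strong' for
categorically annotated data (Intermediate/Weak/Insignificant are
non-hot). Predicted calls threshold ΔΔG_p at 1.5 kcal/mol by default —
the regressor systematically underestimates large ΔΔG, as ensemble
means do. Both comparisons are inclusive (≥); this convention is
validated by exact reproduction of a published three-complex comparison
(bundled as a data file): pooling the 12 decisions per method
reproduces every printed precision/recall/F1 triple of the five methods
to the printed precision. Ratios with empty denominators are reported
as undefined (None), never as 0.

## Synthetic fixtures: what they show and what they do not

The generator builds two short chains facing each other across a flat
interface: backbone atoms near z = 0 and z = 10.74 Å, side chains
extending perpendicular, one residue "column" every 3.6 Å. Planted
motif columns (hydrophobic LEU–LEU, hydroxyl–carboxylate hydrogen
bonds, amide stacks, thiol–amide, and two π arrangements where a GLN or
an aliphatic tip approaches a PHE ring face) meet at β-contact
distances; all other columns stay out of reach. Dedicated fixtures
plant a hydrogen-bond network (k hydroxyl partners sharing one central
OG, so the (hbond, hbond) co-occurrence element aggregates exactly
k(k−1)/2 pairs, k ≤ 3 — more partners would touch each other and
contaminate the count) and a water buried in an icosahedral cage of
hydroxyls (qualifying) or methyls (not qualifying). LYS and ARG are
absent from the motif catalog (their long side chains would clash at
the fixed chain separation); charged-group coverage comes from ASP/GLU.

Synthetic ΔΔG is a linear function of each mutation's own extracted
features — weights on mutated hydrophobic contacts (−0.5), neighborhood
hydrogen bonds (−0.35), the hydrophobic/π co-occurrence (−0.06) and the
hydrogen-bond-network co-occurrence (−0.2), intercept 0.3 — plus
Gaussian noise calibrated to a 2:1 signal-to-noise ratio. The weights
target the contact classes the method emphasizes; the intercept and
scales were fixed once, by simulation, to give a hot-spot prevalence
near 20% (observed 10–35% across seeds) and ΔΔG in a realistic −1 to
+6 kcal/mol range. The default study is 20 complexes of 12 columns
(~230 mutations, ~250 atoms per complex) — sizes chosen so the full
study, cross-validation and importance analysis complete in about two
minutes on one core.

Because the geometry is idealized and the response is linear in the
extracted features, passing the recovery benchmarks demonstrates that
the *pipeline* is internally correct end to end — geometry, typing,
weighting, grouped CV, importance — not that the method attains any
particular accuracy on real crystal structures. Every contact-level
quantity of every fixture is verified against brute-force oracles
(all-pairs O(n³) contact search; O(|C|²) co-occurrence double loop)
that share only the typing tables with the production code.

## Numerical conventions and degenerate inputs

Population (not sample) standard deviation in the B-factor statistics;
trim counts use floor; sort ties keep file order. Constant B factors,
fewer than 10 B values, constant regression responses, a single
complex in CV, coincident atom centers in the interruption test, and
unknown elements or categories are all fatal errors, not silent
defaults. Empty prediction classes yield undefined (None) metrics.
Seeds: every stochastic step (fixture generation, forests, permutation,
CV fold seeds) is an explicit function of a caller-supplied seed.

## Known limitations

- The typing tables are reconstructions; models trained with them are
  not weight-compatible with models built on the original tables.
- Centers-only interruption geometry; interrupter radii are ignored.
- No mmCIF input, no NMR multi-model handling, no hydrogen placement,
  no analytic ASA.
- The synthetic interface is flat and rotamer-free; real interfaces
  curve, pack, and bury waters in less symmetric ways.
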