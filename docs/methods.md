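# Methods

## Model

A structure is reduced to one representative point per residue: the Cβ atom,
or Cα for glycine (the standard coarse-grained convention). Native contacts
are representative-atom pairs within a cutoff of 8.0 Å whose author-numbering
separation is at least 3; both parameters are configurable
(`contact.cutoff_A`, `contact.min_sep`). Each contact carries a native pair
energy

    E(a, b, d) = eps[a][b] · w(d)

with `eps` a symmetric 20×20 residue-pair table and `w` a switching function
equal to 1 for d ≤ 6.5 Å, a cosine ramp from 1 to 0 between 6.5 and 8.0 Å,
and 0 beyond. The ramp avoids a discontinuity at the contact boundary, which
matters for the configurational decoys below (distances are resampled across
the whole observed range).

### The packaged potential

The default table is an analytic hydrophobicity-plus-charge potential:

    eps[a][b] = −(h_a + h_b)/2 + 0.5 · q_a · q_b

where `h` is the Kyte–Doolittle hydropathy scale normalised by its maximum
(4.5), and `q` the formal side-chain charge (D, E −1; K, R +1; H +0.5).
Burial of hydrophobic pairs is stabilising (Ile–Ile = −1.0), burial of like
charges is penalised (Arg–Arg = +1.5). The dominant additive hydrophobicity
term mirrors the rank-one structure that accounts for most of the variance
of knowledge-based contact matrices, and the charge product restores a
minimum of pair specificity. We ship an analytic table rather than a copied
knowledge-based matrix so every entry is auditable from two published
one-dimensional scales; any user table in the same plain-text format
(header row of codes, one row per code) can be substituted via
`potential.table`. All downstream statistics are Z-scores, which are
invariant to affine rescaling of the energy, so the table's absolute scale
is immaterial.

No burial, solvent or water-mediated terms are modelled: residue identities
and the pair distance are the only decoy degrees of freedom.

## Frustration index

For a native contact (i, j):

    FI_ij = ( mean(E_decoy) − E_native ) / sd(E_decoy)

so a native pair more stabilising than its decoys scores positive. Decoy
schemes:

* **mutational** — identities of both partners are redrawn from the chain's
  own composition at the native distance. Implementation draws chain
  *positions* uniformly (composition weighting falls out automatically),
  which also yields common random numbers across runs sharing a seed.
* **configurational** — identities are redrawn as above and the distance is
  additionally drawn uniformly from the multiset of the structure's own
  contact distances, perturbing both the identity and the location of the
  pair.

`sd` is the sample standard deviation (ddof = 1); an ensemble with zero
spread (e.g. a single-identity chain under the mutational scheme) raises a
degenerate-ensemble error rather than emitting ±∞. The default ensemble size
is 1000 decoys per contact. Each contact uses an independent RNG stream
keyed by (seed, i, j), so profiles are deterministic under a fixed seed and
wild-type/mutant pairs computed with the same seed differ only through the
mutation itself.

Classification: FI ≥ 0.78 minimally frustrated; FI < −1 highly frustrated;
neutral between. The 0.78 bound is read one-sided (≥ +0.78), since the
negative side has its own cutoff. Residue-level indices are arithmetic means
of incident contact indices — the simplest unbiased pooling; residues with
no contacts carry no index. Residues with residue-level FI < −2.0 form the
"frustrated site" highlight set used for structure mapping and collocation.

## Mutation scanning

Mutants are identity substitutions on the fixed wild-type backbone: no
side-chain placement, no relaxation. This reads the mutant profile as the
fold's energetic response to the substitution; it will miss effects mediated
by real conformational change, which is the main limitation when comparing
with refined mutant structures. Per-residue deltas (mutant − wild type) with
|Δ| ≥ 0.5 index units are labelled *local* within 10 Å (Cβ–Cβ) of the
mutated residue and *allosteric* beyond; both knobs are config-exposed, and
the distance boundary is an explicit operational stand-in for a qualitative
notion. The paired-state report flags a mutation as *activation-consistent*
when its net index change is negative (frustration up) in the inactive-state
structure and positive (frustration down) in the active-state structure.

## Subdomain annotation and collocation

The packaged partition splits the kinase catalytic core into SD1–SD12
(SD6 split into A/B), keyed to ABL 1IEP author numbering; boundaries are
inclusive on both ends and 315 (the ABL gatekeeper) falls in the SD5 hinge
region. Other kinases need a shifted or user-supplied partition file —
cross-gene structural alignment is out of scope.

`collocation_score` counts mutation sites within a radius (default 10 Å) of
at least one frustrated site and compares against a null in which the
frustrated-site labels are reassigned uniformly at random among all residues
(sampling without replacement, preserving the set size). A permutation null
is used instead of a hypergeometric one because radius overlap in 3D is not
exchangeable under an urn model. The p-value uses the add-one estimator,
bounded below by 1/(n_perm + 1).

## Flexibility

Crystallographic B-factors are the only flexibility proxy. The report pairs
every residue holding both a B-factor and a residue index and computes a
Spearman rank correlation by default (Pearson optional); rank correlation is
invariant to the crystal-specific scale of B. The expected direction is
negative (frustrated = mobile). Constant columns raise an explicit
undefined-correlation error.

## Synthetic benchmark folds

The generator builds ideal geometries — helix bundles (100°/residue twist,
1.5 Å rise, Cα at 2.3 Å and Cβ at 3.4 Å from the axis, axes ~10 Å apart,
antiparallel) and antiparallel pleated sheets (3.3 Å rise, 4.8 Å strand
spacing) — with no physics beyond producing realistic contact densities
(a 60-residue bundle has ≈170 contacts at the default definition).
Sequences are drawn from an average protein composition and then:

* **designed**: optimised for the fold by simulated annealing over
  composition-preserving identity swaps (10⁴ proposals, geometric
  temperature schedule 2.0 → 0.02), minimising total native contact energy;
* **scrambled**: a seeded permutation of the designed sequence — same
  composition, optimisation undone;
* **uniform**: one amino acid everywhere (exercises the degenerate-ensemble
  path).

Composition-preserving swaps are essential: unconstrained optimisation under
a burial-dominated potential would collapse to a poly-hydrophobic chain,
whose scramble would be itself. B-factor columns can be constant,
independent, or anticorrelated with the fold's own quick frustration profile
(B = 30 − 8·FI, clipped at 1), so the flexibility stage is testable end to
end. Fixtures are written as coarse-grained PDB files, one representative
atom per residue.

What the fixtures do *not* emulate: real side-chain packing, loops and
termini, crystallographic noise, and the specific architecture of the
bilobal kinase fold. Passing tests on them demonstrates the mathematics and
the designed-vs-scrambled separation logic of the method, not agreement with
any particular crystal structure.

## Numerical and design choices

* Z-score sign: (decoy mean − native)/sd, so stabilising natives are
  positive and the +0.78 cutoff marks minimal frustration.
* Contacts are counted as unordered pairs, stored once with i < j.
* The author (PDB) numbering is the residue key throughout, because all
  kinase annotations are conventional in author numbering.
* First alternate location wins; occupancy is ignored; MSE and similar
  residues map to their parent amino acid; the first model of multi-model
  files is used.
* Profiles require ≥ 20 residues; the parser itself accepts any chain length
  so that small hand-written fixtures remain loadable.
* Benchmark problem sizes (30–60 residue folds, 10³ decoys per contact,
  10⁵ decoys for the enumeration cross-check, 10 seeds for the separation
  property) are chosen so the whole suite reruns in minutes on one core
  while keeping Monte-Carlo errors well below the thresholds being tested.

## Known limitations

* The packaged potential is a deliberately compact stand-in for richer
  knowledge-based energy functions; absolute frustration values are not
  comparable across potentials, only the Z-score statistics and class
  structure are.
* Fixed-backbone mutants underestimate effects that require repacking.
* The subdomain partition applies literally only to structures numbered like
  the ABL 1IEP catalytic domain.
* Highly frustrated contacts are rare in designed toy folds (a few percent),
  so the 15–20% frustrated fraction seen in real kinase cores is not
  reproduced by the synthetic benchmark; the pooled-fraction statistic is
  reported for the designed ensemble as generated.
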