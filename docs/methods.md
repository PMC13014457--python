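# Methods

## Scope and model

`gluescreen` operates on coordinate files only.  A structure is decomposed
into polymer chains and ligand instances; waters are never ligands,
hydrogens are discarded on parse, alternate locations keep the
highest-occupancy conformer (ties by label order), multi-model files use
model 1, and single-atom metal hetero groups are retained as ligands.
Modified amino acids inside a chain (e.g. phosphoserine) are polymer
residues, not ligands.  Predicted dimer models are ordinary coordinate
files plus an optional interface-confidence number in [0, 1] that is
consumed, never computed, here; the `screen` command can gate targets at a
confidence floor (default 0.30).

## Interface rules

"Interacting" is defined as heavy-atom–heavy-atom distance ≤ 4.5 Å, the
common van-der-Waals contact convention; the cutoff is a single config
knob shared by residue–residue contacts, ligand–residue contacts and
pocket lining.  A residue counts once regardless of how many atom pairs
touch.  A chain pair is a valid dimer iff each side contributes ≥ 5
interacting residues; an interface-adjacent (IAP) ligand contacts ≥ 5
residues on each chain.  Contact search uses a k-d tree but is required —
and tested — to agree exactly with the all-pairs brute force.

## Cavity detection

A regular grid (default spacing 1.0 Å) covers the structure with a 3 Å
margin; the origin is snapped to a multiple of the spacing so results are
stable under translation.  A point is *empty* when farther than
(element vdW + probe) from every heavy-atom center, with vdW radii
C 1.7, N 1.55, O 1.52, S 1.8, P 1.8 (default 1.7) and probe 1.4 Å.  From
each empty point 14 rays are cast (6 axial, 8 body diagonals); a ray is
blocked when a protein atom center lies within 8 Å along it inside a
corridor of half-width 1.2 Å.  Points with ≥ 9 of 14 rays blocked are
pocket-like; 26-connected components form cavities with
volume = points × spacing³.  Points farther than 8 Å from every atom
cannot be blocked at all and are skipped outright.  Lining residues have a
heavy atom within 4.5 Å of a cavity point.  All constants are overridable;
they were chosen once as standard grid-buriedness values and are validated
against carved analytic geometry (a hollow 5×5×5 Å cube measures exactly
125 Å³ at 1 Å spacing).

A cavity is *interface adjacent* when its lining includes at least one
residue from each chain, or ≥ 3 residues that belong to the interface
residue sets.  The library filter keeps cavities with ≥ 10 lining residues
and ≥ 100 Å³.

## Pocket alignment

A pocket signature stores, per lining residue, the Cα position, the
side-chain heavy-atom centroid (collapsing to Cα for glycine), the
one-letter identity, and one of 8 chemistry classes
({GAVLIM}, {FYW}, {ST}, {C}, {P}, {NQ}, {DE}, {KRH}).  Alignment is
sequence-order independent:

* **Seeding.**  All residue triplets (exhaustive up to 16 residues, a
  seeded 600-triplet sample above) are paired across pockets when their
  chemistry classes match pointwise and the three triangle sides agree
  within 1.5 Å; pairs are ranked by total side disagreement and capped at
  200 seeds.  When the two pockets have equal size the identity
  correspondence is seeded as well, which makes self-alignment an exact
  fixed point.  If no chemistry-compatible triplet exists the seeding is
  retried on geometry alone — chemistry only weights the score, so it
  should not make alignment impossible.
* **Refinement.**  Each seed alternates a Kabsch superposition on the
  current correspondence with a one-to-one rematching on the score matrix
  `S_ij = [1+(d_ij/d0)²]⁻¹ (1 − w + w·χ_ij)` restricted to pairs with
  d ≤ 2·d0, until the correspondence is stable (max 50 iterations).
  Matching is the optimal assignment when the smaller pocket has < 9
  residues and deterministic greedy above; the greedy result can be
  marginally suboptimal, which is exactly why the small-pocket fallback
  exists, and the emitted correspondence is oracle-checked against
  `linear_sum_assignment` in the tests.
* **Scoring.**  `score = (1/min(|q|,|t|)) Σ S` over the final
  correspondence, in [0, 1]; defaults d0 = 3.0 Å, w = 0.3.  The best seed
  wins (ties: more aligned pairs, then lexicographic correspondence).  The
  pair is internally put in canonical order and the transform inverted on
  return, so the score is exactly symmetric in its arguments.  Degenerate
  (collinear) pockets raise an alignment error.

## Significance

Scores of unrelated pockets are modeled as Gumbel with location
μ(n) = a₀ + a₁·ln n and scale σ(n) = exp(c₀ + c₁·ln n) (log-parametrized
to keep σ > 0), n = min pocket size; the p-value is the survival function
1 − exp(−exp(−z)).  `fit_null` samples random non-self decoy pocket pairs,
initializes the four coefficients by maximum likelihood, then refines them
by minimizing the Cramér–von Mises distance of the fitted CDF values from
uniformity.  The refinement step matters: the empirical score distribution
is close to, but not exactly, Gumbel, and the null model's contract is
*calibration* — on held-out decoy pairs the p-values must be uniform (KS
at α = 0.01) with the p ≤ 0.05 fraction in the binomial band — rather than
any particular likelihood.  A default null fitted on 500 synthetic decoy
pairs (sizes 10–30, fixed seed recorded in the JSON) ships with the
package; sizes outside the fitted range are clamped with a warning.

## Screening and precision

Templates are (pocket, ligand) pairs: each ligand is assigned to the
detected cavity sharing the most ligand-contacting residues with its
lining (ties to the larger cavity), subject to the ≥ 10-residue / ≥ 100 Å³
filter.  Screening aligns every interface-adjacent target pocket against
every template, keeps p ≤ 0.05 (configurable), transfers the ligand by the
alignment's rigid transform, and reports the fraction of placed atoms
within 1.5 Å of target protein atoms as a clash fraction — reported, not
filtered, by default (an optional flag filters at 0.2).  Per
(pocket, ligand) only the best prediction survives (highest precision,
then lowest p-value, then library order), and predictions below the
precision threshold (default 0.15) are dropped.

The optional homolog filter excludes a template when its parent chain
exceeds the identity cutoff against *either* target chain.  Identity is a
global BLOSUM62 alignment with affine gaps (open −11, extend −1),
identical positions divided by alignment length excluding terminal gaps.

**Binding precision** is a binned lookup: p-value bins
{≤10⁻⁴, ≤10⁻³, ≤10⁻², ≤0.05} × identical-residue bins {<4, 4–7, ≥8}.  The
packaged table is a *synthetic placeholder* — a documented monotone
surface spanning 0–0.6 (non-increasing with p, non-decreasing with
identical count, validated at load time) — because a real calibration
requires retrospective benchmarking against experimental affinities that
no desk-scale fixture can supply.  Production screens must load their own
benchmarked table; everything downstream (thresholding, summaries,
cumulative curves) is agnostic to where the table came from.

## Ligand fingerprints and clustering

The 2048-bit fingerprint hashes every linear path of 1–7 bonds; the atom
invariant is (element, heavy degree, formal charge), the bond invariant
the bond order, paths are canonicalized by direction and hashed (CRC-32,
two bits per path); isolated atoms contribute one atom-type bit.  Bonds
come from an explicit graph, an RDKit Mol, or covalent-radius perception
(bonded within r₁+r₂+0.45 Å).  The fingerprint is implemented in-package
because screening fixtures are pseudo-molecules that cheminformatics
toolkits refuse to sanitize; on real molecules it behaves like any hashed
path ("Daylight-style") fingerprint, and absolute cluster counts are
fingerprint-implementation-dependent.  Clustering is leader/Butina at
Tanimoto ≥ threshold (default 0.8): the unassigned ligand with the most
unassigned neighbors becomes a centroid (ties: input order), absorbing
those neighbors, so clusters partition the input and every member is
within the Tanimoto radius of its centroid.

## Benchmarking

A target is *recovered* when a prediction matches a native IAP ligand's
component id — chemical identity only, no pose gate, since pose quality is
reported separately as the center-of-mass deviation (unweighted heavy-atom
mean; minimum over native copies; averaged over the best match per
target).  Aggregation over (identity cutoff, p-value threshold) conditions
produces the benchmark grid; cumulative precision curves report the
fraction of predictions at or above each precision level.

## Synthetic fixtures

`generate_dimer` builds two idealized strands (Cα spacing 3.8 Å) with an
exact, designed number of cross-chain contact residues (contact pairs at
4.0 Å, everything else > 4.5 Å).  `generate_glue_scenario` plants a
spherical cavity between the chains: a dense double shell of carbon
pseudo-atoms (inner shell radius = cavity radius + 3.1 Å exclusion,
backing shell 2.1 Å further out) grouped into exactly `pocket_size` lining
residues split between the chains by hemisphere, plus interface strands
clear of the pocket.  Shell radii derive from the requested cavity volume,
with a 2σ clearance added when coordinate noise is requested so the noised
template still passes the volume filter.  The template monomer is the
whole shell under a known rigid motion, optional isotropic Gaussian noise,
and optional identity mutations (resampled uniformly from the other 19
amino acids), with a synthetic ligand at the pocket center; the true pose
is that ligand in the target frame.  Decoy pockets are random compact
point sets (Cα–Cα ≥ 3.5 Å) with uniform identities.

What the fixtures do **not** emulate: real fold geometry, side-chain
packing, solvent, partial occupancy, crystal contacts, or the error modes
of predicted complexes beyond coordinate noise.  Passing the fixture suite
therefore demonstrates the *internal correctness* of the pipeline
(filters, alignment, transfer, calibration, bookkeeping), not
discovery performance on real structures, which additionally depends on a
PDB-scale template library and a benchmarked precision table.

## Problem sizes and determinism

Default study conditions: 100 seeded fixtures for the interface rules;
20 exact and 20 noisy (σ = 0.5 Å, 30% mutations) glue scenarios for
end-to-end recovery; 6 mutation-gradient scenarios for threshold
monotonicity; 80 decoys / 400 fitted + 500 held-out pairs for
calibration.  These sizes make the whole suite and the acceptance script
run in minutes on one CPU while keeping the binomial test bands
meaningful.  Every stochastic step flows from an explicit
`numpy.random.default_rng` seed; there is no time-, hash-order- or
platform-dependent branching, and repeated runs are byte-identical.

## Known limitations

* The precision table is a placeholder contract, not a benchmarked
  calibration (see above).
* The buriedness constants are documented defaults, not fitted to any
  reference cavity program; absolute volumes on real proteins will differ
  from tools with different probes or connectivity.
* The greedy matcher above 8 residues is not guaranteed optimal (the
  score-ordering heuristic is, however, deterministic and oracle-checked
  at small sizes where the optimal assignment is used instead).
* Sequence identity on very short pocket-parent sequences is noisy; the
  homolog filter is meaningful mainly when templates carry full-chain
  parent sequences.
* No pose relaxation, binding free-energy estimate, or ternary
  cooperativity score: transferred poses are rigid copies.
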