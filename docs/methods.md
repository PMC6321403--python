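# Methods

This note documents the models and procedures implemented in
`pharmsig`, the numerical choices behind them, what the synthetic
generators do and do not emulate, and the known limitations.

## Signature model

A pharmacophore is a complete graph over labelled 3D feature points;
edge labels are binned distances `floor(d / bin_step)` with half-open
bins. The floor convention is the simplest deterministic choice and is
stable under serialisation; `bin_step` (default 1.0 Å) controls the
fuzziness of matching — smaller steps discriminate more geometries and
match fewer conformers.

**Canonical quadruplet identifiers.** One refinement round suffices for
four vertices: an identifier is the vertex label plus the sorted
(binned distance, neighbour label) pairs to the other three. The sorted
identifier 4-tuple is the graph part of the quadruplet signature.

**Stereo signs.** The equality pattern of the four identifiers defines
five classes. AAAA (regular tetrahedron), AAAB (trigonal pyramid) and
AABC (symmetry plane through the AA midpoint) are achiral and always
signed 0. AABB and ABCD can be chiral: if the minimum angle between any
edge and the plane of the remaining three points is below the planarity
tolerance (degrees; default 0, with 5 and 10 the usual alternatives),
the base sign is 0, otherwise it is the sign of the scalar triple
product of the vectors from the identifier-ranked first vertex to the
other three. Numerical guards: a triple product below 1e-9 of its scale
counts as 0; a quadruplet with a collinear triple is treated as planar
(the conservative choice — an unstable sign is worse than a zero one);
angles below 1e-6° count as exactly planar.

**AABB tie-break.** The two A-identifier vertices are ranked first and
second, the B nearest (real distance) the first A third, the remaining
B fourth. Which A comes first is not determined by the identifiers, so
the implementation evaluates *every* ranking admissible under the rule
(both A orders; both B orders when their distances to the first A tie
within 1e-9 relative). When all rankings agree — the generic case,
because equal identifiers force matching binned-distance multisets —
that sign is used. When they disagree, the geometry is on a symmetric
knife edge where the rule itself is ambiguous; the smaller sign is
taken, which is deterministic, permutation-invariant, and maps a
configuration and its mirror to the same value (mirror discrimination
is deliberately given up exactly where it is ill-defined).

**Trapeze/parallelogram term.** Every AABB quadruplet receives
`10·sgn(cos θ)` on top of the base sign, with θ the B–A–A–B torsion
about the A–A axis (cos θ is invariant to the A and B orderings; a B on
the axis, or |cos θ| ≤ 1e-9, contributes 0). Applying the term to all
AABB quadruplets rather than only the planar degenerate ones was a
design decision: the cosine is reflection-invariant, so the ±1 part
keeps carrying the chirality, while the degenerate planar cases (base
sign 0) become distinguishable — trapeze +10, parallelogram −10.
Possible signs are therefore {0, ±1} generally and
{0, ±1, ±9, ±10, ±11} for AABB.

**Hash serialisation.** An identifier renders as
`label|b1:l1;b2:l2;b3:l3`; a quadruplet as its four identifier strings
sorted and joined with `/`, then `#` and the stereo sign; the hash
input is the sorted `<quad>*<count>` lines joined by newlines, UTF-8
encoded, digested with md5. Any fixed layout satisfies the
"equal digests ⇔ equal signature multisets" contract; this one is
documented so digests reproduce across machines. Feature labels may
not contain the delimiter characters (enforced at construction).
Bit-exact agreement with any other implementation of the same idea is
explicitly not a goal.

**Fingerprints.** One bit per distinct triplet signature: md5 of the
serialised signature, first 8 bytes seed Python's Mersenne Twister,
first draw modulo `n_bits` (default 2048) selects the bit. The
contract is the subset property (sub-pharmacophore bits ⊆ parent
bits), which makes the screening prefilter a Bloom filter with no
false negatives; the concrete bit positions are an implementation
detail.

## Screening

Stages run cheapest-first: fingerprint subset test, VF2 induced
subgraph isomorphism on the complete labelled graphs (labels on
vertices, binned distances on edges), then hash identity of the
candidate sub-pharmacophore induced by each embedding. All embeddings
are enumerated — two embeddings with the same graph signature can
differ in stereochemistry — and matching stops at the first
hash-identical one. Compounds are reported once per model regardless
of how many stereoisomers or conformers match.

## Training-set design

2D pharmacophore fingerprints (RDKit Gobbi) feed Butina
sphere-exclusion clustering at a Tanimoto-distance cutoff (grid 0.3 /
0.4 / 0.5; larger cutoffs give fewer clusters, hence smaller training
sets). Strategy I takes the centroid of every ≥ 5-member cluster of
the separately clustered actives and inactives into one training set.
Strategy II clusters jointly, samples 5 actives and up to 5 inactives
from each cluster with ≥ 5 actives (clusters with fewer inactives
contribute all they have — discarding the cluster would waste its
signal), adds the centroids of the inactive-only clustering to every
set, and de-duplicates. When no 2D fingerprints are available (fully
synthetic point-set data), the 3D triplet fingerprint of each
compound's first conformer serves as the clustering similarity; only a
similarity structure is needed at this stage.

## Iterative model search

Per compound, duplicate hashes across stereoisomers and conformers
collapse (statistics count parent compounds, never conformers), but
*every* witness instance of a hash is retained, because growth happens
per witness within its own conformer and dropping witnesses would lose
children. Selection: strategy I keeps F0.5 ≥ 0.8 (precision-leaning);
strategy II keeps F2 = 1, falling back to recall = 1 (its small
same-binding-mode training sets should be fully covered). With more
than 100 qualifying hashes, all hashes whose criterion equals the
100th-ranked value are kept; the secondary sort by hash string exists
only to make output order deterministic. Equality tests on scores use
a 1e-12 tolerance. The loop stops when an iteration selects nothing or
no witness can grow, returning the previous selection; models with ≤ 3
distinct coordinate points (coincident-feature collapse) are dropped.
Representative model coordinates come from the first witness in sorted
compound-id order — any witness is valid since all share the hash.

## Synthetic generators

`random_pharmacophore` draws uniform labels and coordinates in a box
(default 10 Å, rounded to 3 decimals so files round-trip exactly).
`make_planted_dataset` draws a planted k-point pharmacophore, redrawn
until its hash survives random rigid motions (rejecting bin-boundary
and near-planar knife edges), embeds a rigid-motion copy plus random
decoy features in every active conformer, and generates inactives with
the same feature count, rejection-sampled until no k-subset hashes to
the planted value — verified with the production engine itself, so
fixtures and engine cannot drift apart. Default conditions: 10 actives,
20 inactives, k = 5, 3 decoys, 2 conformers per compound.

The generator emulates exact common substructure under rigid motion.
It does **not** emulate conformational noise around the common
pharmacophore, correlated feature geometry from real chemistry,
feature-frequency imbalance, or near-miss decoys sharing most of the
planted geometry. Passing the planted-recovery tests therefore shows
the combinatorial search, scoring and screening machinery are correct;
it does not by itself predict enrichment on experimental datasets,
where the binning step absorbs (only) sub-bin geometric variation.

## Problem sizes and defaults

Tests and the acceptance script run on small synthetic instances
(pharmacophores of 4–8 features, datasets of ~30 compounds, 1000-trial
randomized suites), which exercise every code path while keeping the
suite fast on a single CPU. Ligand preparation defaults follow
standard practice: up to 100 conformers per stereoisomer, MMFF94
minimisation, 50 kcal/mol retention window (wide, to keep extended
conformers of flexible compounds), ETKDG embedding with a fixed seed.
Multi-atom SMARTS matches are placed at the centroid of the matched
atoms — the standard deterministic choice — and one atom set may carry
several labels, producing coincident points the signature engine
handles without special-casing. The shipped SMARTS table is a
reconstruction of common open feature definitions and is labelled as
such; screening results depend materially on these definitions and
serious applications should supply validated ones.

## Limitations

- No exclusion volumes or shape constraints: a model matches any
  compound embedding its features, however large.
- Matching is exact at bin resolution; variation straddling a bin
  boundary defeats it (the tolerance parameter relaxes planarity, not
  distance binning).
- The AABB ambiguity fallback sacrifices mirror discrimination on
  exactly symmetric tie configurations (measure zero for real data).
- No tautomer or protonation-state enumeration; input SMILES are taken
  as-is apart from stereoisomer enumeration.
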