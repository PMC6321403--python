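# pharmsig

Alignment-free 3D pharmacophore signatures and ligand-based
pharmacophore modeling.

## The problem

A 3D pharmacophore is the spatial arrangement of interaction features —
H-bond acceptors (A) and donors (D), aromatic (a), hydrophobic (H),
positively (P) and negatively (N) charged centres — responsible for a
ligand's activity. Most ligand-based tools find a pharmacophore common
to a set of actives by *aligning* conformers to a template, which
requires knowing a bioactive conformation. `pharmsig` instead encodes
each pharmacophore by a canonical signature such that **two
pharmacophores are identical (at a chosen distance resolution) iff
their signatures hash to the same md5 digest** — no alignment, no
template. Finding a common pharmacophore then reduces to counting hash
occurrences across compounds.

## The representation

A pharmacophore with features \(f_1..f_n\) is a complete graph with
vertex labels \(\ell_i\) and edge labels \(\lfloor d_{ij}/s \rfloor\)
(binned Euclidean distances, default step \(s = 1\) Å). For every
4-feature subset (a *quadruplet* — the smallest point set that can be
chiral in 3D):

1. each member gets a canonical identifier: its own label plus the
   sorted (binned distance, label) pairs to the other three (one round
   of Morgan-like refinement);
2. the equality pattern of the four identifiers places the quadruplet
   in one of five classes — AAAA, AAAB, AABC (achiral, stereo sign 0),
   AABB and ABCD (potentially chiral);
3. for AABB/ABCD quadruplets that are not planar (minimum edge-to-plane
   angle above a tolerance, default 0°), the sign of the scalar triple
   product of the vectors from the top-ranked vertex to the other
   three, ranked by identifier, gives a stereo sign ±1. AABB
   quadruplets additionally receive \(10\,\mathrm{sgn}(\cos\theta)\)
   for the B–A–A–B torsion θ, separating trapeze-like (+10) from
   parallelogram-like (−10) geometries that share a graph signature;
4. the sorted multiset of (signature, count) pairs over all quadruplets
   is serialised in a fixed layout and digested with md5.

Fingerprints do the same over feature *triplets* (never chiral) and set
one bit per distinct triplet signature in a 2048-bit string, giving a
Bloom-filter prefilter for screening: a model can only match a
candidate whose fingerprint contains the model's bits. Screening then
runs VF2 subgraph isomorphism on the labelled graphs and confirms
stereochemistry by hash identity of the embedded sub-pharmacophore.

## Model building

Given active and inactive compounds, training sets are designed with
Butina clustering of 2D pharmacophore fingerprints under two
strategies: **I** (one binding mode — centroids of clusters with ≥ 5
members form one diverse set) or **II** (several binding modes — each
joint cluster with ≥ 5 actives yields its own set of 5 sampled actives
and up to 5 cluster inactives plus the inactive-clustering centroids).
Starting from all distinct 4-point hashes of the training compounds
(over every stereoisomer and conformer, counted once per compound),
hashes are scored by occurrence in actives (TP) and inactives (FP) and
selected by F0.5 ≥ 0.8 (strategy I) or F2 = 1 with a recall = 1
fallback (strategy II), capped at 100 models with ties kept. Selected
pharmacophores grow by one feature within each witness conformer and
the cycle repeats; when an iteration selects nothing, the previous
selection is final. Models whose features occupy ≤ 3 distinct points
are discarded.

## Worked example

A synthetic dataset plants an exact 5-point pharmacophore (under random
rigid motions, plus 3 decoy features per conformer) into 10 actives and
guarantees 20 inactives contain no sub-pharmacophore with the planted
hash. Fitting on half the data:

```python
from pharmsig import LigandPharmacophoreModel, TrainingSet
from pharmsig.synthetic import make_planted_dataset

ds = make_planted_dataset(n_active=10, n_inactive=20, k=5, n_decoys=3,
                          n_conformers=2, seed=1)
spec = LigandPharmacophoreModel(ds.conformer_sets, ds.activities, strategy="II")
train = TrainingSet("demo",
                    tuple(s.compound_id for s in ds.actives[:5]),
                    tuple(s.compound_id for s in ds.inactives[:10]),
                    "II", 0.4)
res = spec.fit(training_sets=[train])
print(res.summary().to_string(index=False))
```

```
            model_id training_set strategy  n_features                             hash  TP  FP  P  N  precision  recall  F05  F2
demo.k5.275b561a6db9         demo       II           5 275b561a6db956463476f201173e321d   5   0  5 10        1.0     1.0  1.0 1.0
```

The search grew 4-point seeds to 5 points, stopped when no 6-point
pharmacophore satisfied F2 = 1, and returned exactly one model whose
hash `275b561a…` equals the planted hash: the common pharmacophore was
recovered without any alignment. External validation on the held-out
compounds (`res.validate()`) gives recall 1.0 at FPR 0.0 for the model
and for the consensus row (the de-duplicated union of hit lists across
models).

Real compound tables run the same way through
`LigandPharmacophoreModel.from_table("data.smi", strategy="I")`, which
enumerates unassigned stereocentres, embeds up to 100 conformers per
stereoisomer within a 50 kcal/mol MMFF94 window, and perceives features
with a SMARTS table (`src/pharmsig/data/features.smarts`; a
clearly-labelled reconstruction — supply your own validated
definitions for production work). The `pharmsig` CLI exposes `train`,
`screen`, `validate` and `fixtures make-planted`.

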