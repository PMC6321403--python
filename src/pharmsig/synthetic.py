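"""Deterministic synthetic pharmacophores and planted-model datasets.

These generators make the whole pipeline testable without any chemistry
backend: random labelled 3D point sets stand in for perceived
pharmacophores, and planted-model datasets embed a known common
pharmacophore (under random rigid motions) into every "active"
compound while guaranteeing — by exhaustive check with the real
signature engine — that no "inactive" contains it.  Because the
verification uses the same engine that model building uses, fixtures
and engine cannot drift apart.

The generated point sets are uniform in a box and make no attempt to
mimic realistic medicinal-chemistry feature statistics.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.transform import Rotation

from .features import DEFAULT_ALPHABET, FeaturePoint, Pharmacophore
from .prep import ConformerPharmSet
from .signatures import pharm_hash

__all__ = [
    "random_pharmacophore",
    "rigid_transform",
    "random_rigid_transform",
    "mirror",
    "PlantedDataset",
    "make_planted_dataset",
]


def _rng(seed_or_rng) -> np.random.Generator:
    if isinstance(seed_or_rng, np.random.Generator):
        return seed_or_rng
    return np.random.default_rng(seed_or_rng)


def random_pharmacophore(
    n: int,
    alphabet=DEFAULT_ALPHABET,
    box: float = 10.0,
    seed=0,
    bin_step: float = 1.0,
) -> Pharmacophore:
    """Uniformly random labelled point set in a cube of edge ``box`` Å.

    Coordinates are rounded to 3 decimals so serialisations round-trip
    bit-identically.  Deterministic for a fixed seed.
    """
    rng = _rng(seed)
    labels = rng.choice(list(alphabet), size=n)
    coords = np.round(rng.uniform(0.0, box, size=(n, 3)), 3)
    return Pharmacophore(
        (FeaturePoint(str(l), *map(float, c)) for l, c in zip(labels, coords)),
        bin_step=bin_step,
    )


def rigid_transform(
    p: Pharmacophore, rotation=None, translation=None
) -> Pharmacophore:
    """Apply a proper rotation and translation (distances preserved).

    ``rotation`` is a 3×3 proper rotation matrix or a
    ``scipy.spatial.transform.Rotation`` (identity if None);
    ``translation`` a length-3 vector (zero if None).
    """
    if rotation is None:
        R = np.eye(3)
    elif isinstance(rotation, Rotation):
        R = rotation.as_matrix()
    else:
        R = np.asarray(rotation, dtype=float)
    t = np.zeros(3) if translation is None else np.asarray(translation, dtype=float)
    coords = p.coords @ R.T + t
    return Pharmacophore(
        (
            FeaturePoint(f.label, *map(float, c))
            for f, c in zip(p.features, coords)
        ),
        bin_step=p.bin_step,
    )


def random_rigid_transform(p: Pharmacophore, seed=0, max_shift: float = 10.0):
    """Random proper rotation plus a uniform translation in ±``max_shift``."""
    rng = _rng(seed)
    rot = Rotation.random(rng=rng)
    shift = rng.uniform(-max_shift, max_shift, size=3)
    return rigid_transform(p, rotation=rot, translation=shift)


def mirror(p: Pharmacophore) -> Pharmacophore:
    """Reflection through the yz-plane: distances kept, handedness flipped."""
    return Pharmacophore(
        (FeaturePoint(f.label, -f.x, f.y, f.z) for f in p.features),
        bin_step=p.bin_step,
    )


def _hash_stable(p: Pharmacophore, tolerance: float, rng, trials: int = 3) -> bool:
    """True when the hash survives random rigid motions.

    Guards against planted pharmacophores whose signatures sit on a bin
    boundary or a planarity/torsion knife edge, where floating-point
    noise from a rotation could flip a component of the signature.
    """
    ref = pharm_hash(p, tolerance)
    return all(
        pharm_hash(random_rigid_transform(p, rng), tolerance) == ref
        for _ in range(trials)
    )


def _contains_hash(p: Pharmacophore, k: int, target: str, tolerance: float) -> bool:
    return any(
        pharm_hash(p.subset(idx), tolerance) == target
        for idx in itertools.combinations(range(len(p)), k)
    )


@dataclass
class PlantedDataset:
    """A labelled synthetic dataset with a known common pharmacophore.

    Every active conformer embeds an exact rigid-motion copy of the
    planted pharmacophore plus random decoy features; inactives have
    the same feature-count distribution but — verified exhaustively at
    generation time — no sub-pharmacophore hashing to the planted hash.
    """

    planted: Pharmacophore
    planted_hash: str
    actives: list = field(default_factory=list)
    inactives: list = field(default_factory=list)
    seed: int = 0

    @property
    def conformer_sets(self) -> dict:
        out = {s.compound_id: s for s in self.actives}
        out.update({s.compound_id: s for s in self.inactives})
        return out

    @property
    def activities(self) -> dict:
        out = {s.compound_id: "active" for s in self.actives}
        out.update({s.compound_id: "inactive" for s in self.inactives})
        return out


def make_planted_dataset(
    n_active: int = 10,
    n_inactive: int = 20,
    k: int = 5,
    n_decoys: int = 3,
    n_conformers: int = 2,
    seed: int = 0,
    bin_step: float = 1.0,
    alphabet=DEFAULT_ALPHABET,
    box: float = 10.0,
    tolerance: float = 0.0,
    planted: Pharmacophore | None = None,
    id_prefix: str = "",
    max_tries: int = 200,
) -> PlantedDataset:
    """Generate a planted-model dataset.

    Parameters
    ----------
    n_active, n_inactive : compound counts.
    k : number of features in the planted pharmacophore (≥ 4).
    n_decoys : random extra features added to every conformer.
    n_conformers : conformers per compound (all stereoisomer index 0).
    planted : reuse an existing planted pharmacophore (for held-out
        test sets sharing the model of a training set); a fresh one is
        drawn when None.
    max_tries : rejection-sampling budget per generated object; a
        ``RuntimeError`` is raised when exhausted.

    The planted pharmacophore is redrawn until its hash is stable under
    rigid motion; every active conformer is verified to contain the
    planted hash and every inactive conformer verified (exhaustively
    over all k-subsets) not to.
    """
    if k < 4:
        raise ValueError("planted pharmacophore needs at least 4 features")
    rng = _rng(seed)

    if planted is None:
        for _ in range(max_tries):
            cand = random_pharmacophore(
                k, alphabet=alphabet, box=box, seed=rng, bin_step=bin_step
            )
            if _hash_stable(cand, tolerance, rng):
                planted = cand
                break
        else:
            raise RuntimeError("could not draw a stable planted pharmacophore")
    target = pharm_hash(planted, tolerance)

    def _active_conformer() -> Pharmacophore:
        for _ in range(max_tries):
            core = random_rigid_transform(planted, rng, max_shift=box)
            decoys = random_pharmacophore(
                n_decoys, alphabet=alphabet, box=box, seed=rng, bin_step=bin_step
            )
            centre = core.coords.mean(axis=0) - np.array([box / 2] * 3)
            decoys = rigid_transform(decoys, translation=centre)
            feats = list(core.features) + list(decoys.features)
            order = rng.permutation(len(feats))
            p = Pharmacophore((feats[i] for i in order), bin_step=bin_step)
            core_idx = tuple(sorted(np.argsort(order)[: len(core)]))
            if pharm_hash(p.subset(core_idx), tolerance) == target:
                return p
        raise RuntimeError("rejection budget exhausted for active conformer")

    def _inactive_conformer() -> Pharmacophore:
        for _ in range(max_tries):
            p = random_pharmacophore(
                k + n_decoys, alphabet=alphabet, box=box, seed=rng, bin_step=bin_step
            )
            if not _contains_hash(p, k, target, tolerance):
                return p
        raise RuntimeError("rejection budget exhausted for inactive conformer")

    actives, inactives = [], []
    for i in range(n_active):
        cps = ConformerPharmSet(f"{id_prefix}act{i:03d}")
        for ci in range(n_conformers):
            cps.add(0, ci, _active_conformer())
        actives.append(cps)
    for i in range(n_inactive):
        cps = ConformerPharmSet(f"{id_prefix}inact{i:03d}")
        for ci in range(n_conformers):
            cps.add(0, ci, _inactive_conformer())
        inactives.append(cps)

    return PlantedDataset(
        planted=planted,
        planted_hash=target,
        actives=actives,
        inactives=inactives,
        seed=int(seed) if not isinstance(seed, np.random.Generator) else -1,
    )
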