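"""Three-stage screening of pharmacophore models against conformer sets.

A model matches a candidate conformer pharmacophore when

1. the model's hashed triplet fingerprint is a subset of the
   candidate's (Bloom-filter prefilter — false positives possible,
   false negatives impossible);
2. the model's complete labelled graph embeds into the candidate's
   (VF2 subgraph isomorphism on feature labels and binned distances);
3. some embedding induces a candidate sub-pharmacophore whose 3D
   pharmacophore hash equals the model hash, confirming identical
   stereoconfiguration.

All embeddings are enumerated because two embeddings with the same
graph signature can differ in stereo; matching stops at the first
hash-identical one.  A compound is reported at most once per model no
matter how many of its stereoisomers or conformers match.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import networkx as nx

from .features import Pharmacophore
from .signatures import (
    PharmFingerprint,
    bin_distance,
    pharm_fingerprint,
    pharm_hash,
)

__all__ = [
    "PharmModel",
    "ScreenHit",
    "ScreenResult",
    "fp_prefilter",
    "find_embeddings",
    "match_pharmacophore",
    "screen_dataset",
]


@dataclass
class PharmModel:
    """A selected pharmacophore model ready for screening.

    Carries representative coordinates (any witness instance is valid
    because all witnesses share the hash), the model hash and
    fingerprint, and the training-set confusion statistics recorded at
    selection time.
    """

    model_id: str
    pharmacophore: Pharmacophore
    hash: str
    fingerprint: PharmFingerprint
    tolerance: float = 0.0
    strategy: str | None = None
    training_set_id: str | None = None
    iteration: int | None = None
    stats: dict | None = None

    @property
    def n_features(self) -> int:
        return len(self.pharmacophore)

    @classmethod
    def from_pharmacophore(
        cls,
        pharmacophore: Pharmacophore,
        model_id: str = "model",
        tolerance: float = 0.0,
        n_bits: int = 2048,
        **kw,
    ) -> "PharmModel":
        """Build a model from bare coordinates, computing hash and bits."""
        return cls(
            model_id=model_id,
            pharmacophore=pharmacophore,
            hash=pharm_hash(pharmacophore, tolerance),
            fingerprint=pharm_fingerprint(pharmacophore, n_bits, tolerance),
            tolerance=tolerance,
            **kw,
        )

    def to_dict(self) -> dict:
        d = {
            "model_id": self.model_id,
            "strategy": self.strategy,
            "training_set_id": self.training_set_id,
            "bin_step": self.pharmacophore.bin_step,
            "tolerance": self.tolerance,
            "hash": self.hash,
            "features": [
                {"label": f.label, "x": f.x, "y": f.y, "z": f.z}
                for f in self.pharmacophore
            ],
            "stats": self.stats,
            "iteration": self.iteration,
            "n_bits": self.fingerprint.n_bits,
        }
        return d

    def to_json(self, path=None) -> str:
        s = json.dumps(self.to_dict(), indent=1, sort_keys=True)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(s + "\n")
        return s

    @classmethod
    def from_dict(cls, d: dict) -> "PharmModel":
        p = Pharmacophore.from_dict(
            {"bin_step": d["bin_step"], "features": d["features"]}
        )
        m = cls.from_pharmacophore(
            p,
            model_id=d["model_id"],
            tolerance=float(d.get("tolerance", 0.0)),
            n_bits=int(d.get("n_bits", 2048)),
            strategy=d.get("strategy"),
            training_set_id=d.get("training_set_id"),
            iteration=d.get("iteration"),
            stats=d.get("stats"),
        )
        stored = d.get("hash")
        if stored is not None and stored != m.hash:
            raise ValueError(
                f"stored hash of model {m.model_id!r} does not match its "
                "coordinates; file corrupted or produced with other settings"
            )
        return m

    @classmethod
    def from_json(cls, source) -> "PharmModel":
        text = str(source)
        if not text.lstrip().startswith("{"):
            with open(text) as fh:
                text = fh.read()
        return cls.from_dict(json.loads(text))


@dataclass(frozen=True)
class ScreenHit:
    """One matched compound: which member matched and how."""

    compound_id: str
    model_id: str
    stereo_idx: int
    conf_idx: int
    feature_indices: tuple


def fp_prefilter(query: PharmFingerprint, candidate: PharmFingerprint) -> bool:
    """Bloom-filter test: pass iff query bits ⊆ candidate bits.

    Never rejects a true match (every triplet of a sub-pharmacophore is
    a triplet of its parent), but may pass candidates that later fail
    embedding or hash comparison.
    """
    return query.issubset(candidate)


def _complete_graph(p: Pharmacophore) -> nx.Graph:
    g = nx.Graph()
    for i, f in enumerate(p.features):
        g.add_node(i, label=f.label)
    dm = p.distance_matrix()
    for i in range(len(p)):
        for j in range(i + 1, len(p)):
            g.add_edge(i, j, bin=bin_distance(float(dm[i, j]), p.bin_step))
    return g


def find_embeddings(
    model: Pharmacophore, candidate: Pharmacophore
) -> list[tuple]:
    """All injective label- and binned-distance-preserving embeddings.

    Both pharmacophores are complete graphs, so VF2 induced-subgraph
    isomorphism enforces equality of every pairwise binned distance
    between mapped features.  Each embedding is a tuple ``t`` with
    ``t[i]`` the candidate feature index matched to model feature ``i``;
    an empty list means no embedding exists.
    """
    if model.bin_step != candidate.bin_step:
        raise ValueError("model and candidate must share one bin_step")
    if len(model) > len(candidate):
        return []
    gm = nx.algorithms.isomorphism.GraphMatcher(
        _complete_graph(candidate),
        _complete_graph(model),
        node_match=lambda a, b: a["label"] == b["label"],
        edge_match=lambda a, b: a["bin"] == b["bin"],
    )
    out = []
    for mapping in gm.subgraph_isomorphisms_iter():
        inv = {mi: ci for ci, mi in mapping.items()}
        out.append(tuple(inv[i] for i in range(len(model))))
    return sorted(set(out))


def match_pharmacophore(
    model: PharmModel,
    candidate: Pharmacophore,
    candidate_fp: PharmFingerprint | None = None,
):
    """Full three-stage match of one model against one pharmacophore.

    Returns ``(matched, witness)`` where ``witness`` is the tuple of
    candidate feature indices of the first hash-identical embedding, or
    None.  ``candidate_fp`` may be supplied to reuse a precomputed
    fingerprint across models.
    """
    if candidate_fp is None:
        candidate_fp = pharm_fingerprint(
            candidate, model.fingerprint.n_bits, model.tolerance
        )
    if not fp_prefilter(model.fingerprint, candidate_fp):
        return False, None
    for emb in find_embeddings(model.pharmacophore, candidate):
        sub = candidate.subset(emb)
        if pharm_hash(sub, model.tolerance) == model.hash:
            return True, emb
    return False, None


@dataclass
class ScreenResult:
    """Hits per model plus the de-duplicated consensus over models."""

    hits: dict = field(default_factory=dict)  # model_id -> {compound_id: ScreenHit}

    def compounds(self, model_id: str) -> set:
        return set(self.hits.get(model_id, ()))

    @property
    def consensus(self) -> dict:
        """compound_id -> number of models that matched it (union)."""
        counts: dict = {}
        for per_model in self.hits.values():
            for cid in per_model:
                counts[cid] = counts.get(cid, 0) + 1
        return counts

    def to_tsv(self, path=None, detailed: bool = False) -> str:
        lines = (
            ["model_id\tcompound_id\tstereo_idx\tconf_idx\tfeature_indices"]
            if detailed
            else ["model_id\tcompound_id"]
        )
        for model_id in sorted(self.hits):
            for cid in sorted(self.hits[model_id]):
                h = self.hits[model_id][cid]
                if detailed:
                    idx = ",".join(map(str, h.feature_indices))
                    lines.append(
                        f"{model_id}\t{cid}\t{h.stereo_idx}\t{h.conf_idx}\t{idx}"
                    )
                else:
                    lines.append(f"{model_id}\t{cid}")
        s = "\n".join(lines) + "\n"
        if path is not None:
            with open(path, "w") as fh:
                fh.write(s)
        return s

    def consensus_tsv(self, path=None) -> str:
        lines = ["compound_id\tn_models_matched"]
        for cid, n in sorted(self.consensus.items()):
            lines.append(f"{cid}\t{n}")
        s = "\n".join(lines) + "\n"
        if path is not None:
            with open(path, "w") as fh:
                fh.write(s)
        return s


def screen_dataset(
    models: Sequence[PharmModel],
    db: Iterable,
) -> ScreenResult:
    """Screen every model against every compound's conformer set.

    ``db`` is an iterable of :class:`~pharmsig.prep.ConformerPharmSet`
    (or a mapping of compound_id to one).  A compound is a hit for a
    model iff any of its stereoisomer/conformer pharmacophores matches;
    the consensus is the union of per-model hit lists.
    """
    if hasattr(db, "values"):
        db = list(db.values())
    else:
        db = list(db)
    if not models:
        return ScreenResult()
    n_bits = {m.fingerprint.n_bits for m in models}
    if len(n_bits) > 1:
        raise ValueError("all models must share one fingerprint length")
    n_bits = n_bits.pop()
    tolerances = {m.tolerance for m in models}

    result = ScreenResult({m.model_id: {} for m in models})
    for cps in db:
        # fingerprint each member once; reuse across models
        member_fps = [
            pharm_fingerprint(p, n_bits, min(tolerances)) for _, _, p in cps.members
        ]
        for m in models:
            for (si, ci, p), fp in zip(cps.members, member_fps):
                matched, emb = match_pharmacophore(m, p, candidate_fp=fp)
                if matched:
                    result.hits[m.model_id][cps.compound_id] = ScreenHit(
                        cps.compound_id, m.model_id, si, ci, emb
                    )
                    break  # one hit per compound per model
    return result
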