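"""Common-pharmacophore model building from active/inactive compound sets.

Training sets are designed with Butina sphere-exclusion clustering of
2D pharmacophore fingerprints under one of two strategies:

* **Strategy I** assumes a single binding mode: actives and inactives
  are clustered separately and the centroid of every cluster with at
  least five members enters one diverse training set.
* **Strategy II** assumes multiple binding modes: actives and inactives
  are clustered jointly; every cluster with at least five actives
  yields its own training set of five sampled actives, up to five
  sampled cluster inactives, plus the centroids of the inactive-only
  clustering, de-duplicated.

Model building is iterative.  All distinct 4-point sub-pharmacophore
hashes of the training compounds (over every stereoisomer and
conformer, de-duplicated per compound) are scored by their occurrence
in actives (TP) and inactives (FP).  Hashes passing the strategy's
criterion — F0.5 ≥ 0.8 for strategy I; F2 = 1, falling back to
recall = 1, for strategy II; at most 100 models with ties at the cap
kept — are grown by one feature within the conformer of each witness
instance, and the cycle repeats.  When an iteration selects nothing
(or nothing can grow), the previous iteration's selection is final.
Models whose features occupy three or fewer distinct coordinates are
dropped as too promiscuous.

The user-facing surface follows the fit/results idiom:
:class:`LigandPharmacophoreModel` holds the prepared data and
configuration, its :meth:`~LigandPharmacophoreModel.fit` runs the
search and returns a :class:`LigandPharmacophoreResults` carrying the
selected models, their training statistics, a summary table, and
screening/validation helpers.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .features import Pharmacophore
from .metrics import ValidationReport, confusion_metrics, validate
from .prep import (
    CompoundRecord,
    ConformerPharmSet,
    load_feature_definitions,
    pharm2d_fingerprints,
    prepare_dataset,
    read_compound_table,
)
from .screening import PharmModel, ScreenResult, screen_dataset
from .signatures import pharm_fingerprint, pharm_hash

logger = logging.getLogger(__name__)

__all__ = [
    "Cluster",
    "TrainingSet",
    "HashStats",
    "cluster_compounds",
    "make_training_set_strategy1",
    "make_training_sets_strategy2",
    "compound_hash_index",
    "score_hashes",
    "select_models",
    "grow_models",
    "build_models",
    "postprocess_models",
    "LigandPharmacophoreModel",
    "LigandPharmacophoreResults",
]

_EPS = 1e-12


# --------------------------------------------------------------- clustering


@dataclass(frozen=True)
class Cluster:
    members: tuple  # compound ids, centroid first
    centroid: str


def _tanimoto(a, b) -> float:
    if isinstance(a, (set, frozenset)):
        if not a and not b:
            return 1.0
        return len(a & b) / len(a | b)
    from rdkit import DataStructs

    return DataStructs.TanimotoSimilarity(a, b)


def cluster_compounds(fingerprints: Mapping[str, object], cutoff: float) -> list:
    """Butina sphere-exclusion clustering at a Tanimoto-distance cutoff.

    ``fingerprints`` maps compound_id to either an RDKit bit vector or a
    plain set of on-bit indices (the synthetic route).  The first member
    of each returned :class:`Cluster` is its centroid.  Larger cutoffs
    merge more compounds and yield fewer clusters.
    """
    if not 0 < cutoff < 1:
        raise ValueError("cutoff must lie in (0, 1)")
    ids = sorted(fingerprints)
    if not ids:
        return []
    from rdkit.ML.Cluster import Butina

    fps = [fingerprints[i] for i in ids]
    dists = []
    for i in range(1, len(fps)):
        for j in range(i):
            dists.append(1.0 - _tanimoto(fps[i], fps[j]))
    raw = Butina.ClusterData(dists, len(fps), cutoff, isDistData=True)
    clusters = []
    for tup in raw:
        members = tuple(ids[i] for i in tup)
        clusters.append(Cluster(members=members, centroid=members[0]))
    clusters.sort(key=lambda c: (-len(c.members), c.centroid))
    return clusters


# ------------------------------------------------------------ training sets


@dataclass
class TrainingSet:
    """Compound ids selected for one model-building run."""

    set_id: str
    actives: tuple
    inactives: tuple
    strategy: str  # "I" or "II"
    cutoff: float

    def __post_init__(self):
        if set(self.actives) & set(self.inactives):
            raise ValueError("active and inactive training ids must be disjoint")

    @property
    def ids(self) -> set:
        return set(self.actives) | set(self.inactives)


def make_training_set_strategy1(
    active_fps: Mapping[str, object],
    inactive_fps: Mapping[str, object],
    cutoff: float,
    min_cluster_size: int = 5,
) -> tuple:
    """Single diverse training set from separate active/inactive clustering.

    The centroid of every cluster with at least ``min_cluster_size``
    members enters the training set; all remaining compounds form the
    external test set.  Returns ``(TrainingSet, test_ids)``.
    """
    tr_act = [
        c.centroid
        for c in cluster_compounds(active_fps, cutoff)
        if len(c.members) >= min_cluster_size
    ]
    if not tr_act:
        raise ValueError(
            "training set empty: no active cluster reaches "
            f"{min_cluster_size} compounds at cutoff {cutoff}"
        )
    tr_inact = [
        c.centroid
        for c in cluster_compounds(inactive_fps, cutoff)
        if len(c.members) >= min_cluster_size
    ]
    ts = TrainingSet(
        set_id=f"I-c{cutoff:g}",
        actives=tuple(tr_act),
        inactives=tuple(tr_inact),
        strategy="I",
        cutoff=cutoff,
    )
    test = sorted((set(active_fps) | set(inactive_fps)) - ts.ids)
    return ts, test


def make_training_sets_strategy2(
    active_fps: Mapping[str, object],
    inactive_fps: Mapping[str, object],
    cutoff: float,
    seed: int = 0,
    per_cluster: int = 5,
    min_cluster_size: int = 5,
) -> list:
    """One training set per joint cluster holding ≥ 5 active compounds.

    Actives and inactives are clustered jointly; from each qualifying
    cluster ``per_cluster`` actives and up to ``per_cluster`` inactives
    are sampled (all available when fewer).  The centroids of the
    clusters of the inactive-only clustering (size ≥ ``min_cluster_size``,
    as in strategy I) are added to every set, and duplicate inactives
    removed.  Deterministic for a fixed ``seed``.
    """
    rng = np.random.default_rng(seed)
    all_fps = dict(active_fps)
    all_fps.update(inactive_fps)
    joint = cluster_compounds(all_fps, cutoff)
    centroid_inactives = [
        c.centroid
        for c in cluster_compounds(inactive_fps, cutoff)
        if len(c.members) >= min_cluster_size
    ]
    sets = []
    for c in joint:
        act = sorted(m for m in c.members if m in active_fps)
        if len(act) < per_cluster:
            continue
        inact = sorted(m for m in c.members if m in inactive_fps)
        sel_act = sorted(rng.choice(act, size=per_cluster, replace=False))
        if len(inact) > per_cluster:
            sel_inact = list(rng.choice(inact, size=per_cluster, replace=False))
        else:
            sel_inact = list(inact)
        merged = []
        for cid in sel_inact + centroid_inactives:
            if cid not in merged:
                merged.append(cid)
        sets.append(
            TrainingSet(
                set_id=f"II-c{cutoff:g}-{len(sets)}",
                actives=tuple(sel_act),
                inactives=tuple(merged),
                strategy="II",
                cutoff=cutoff,
            )
        )
    if not sets:
        logger.warning(
            "strategy II found no cluster with %d actives at cutoff %g",
            per_cluster, cutoff,
        )
    return sets


# ------------------------------------------------------- hash scoring


@dataclass
class HashStats:
    """Occurrence of one sub-pharmacophore hash over training compounds.

    Counts are per compound — a hash found in many conformers or
    stereoisomers of the same parent counts once.
    """

    hash: str
    tp: int
    fp: int
    p: int
    n: int

    def __post_init__(self):
        if not 0 <= self.tp <= self.p or not 0 <= self.fp <= self.n:
            raise ValueError("inconsistent confusion counts")

    @property
    def recall(self):
        return self.tp / self.p if self.p else None

    @property
    def precision(self):
        return self.tp / (self.tp + self.fp) if (self.tp + self.fp) else None

    @property
    def f05(self):
        m = confusion_metrics(self.tp, self.fp, self.p, self.n)
        return m["f05"]

    @property
    def f2(self):
        m = confusion_metrics(self.tp, self.fp, self.p, self.n)
        return m["f2"]

    def to_dict(self) -> dict:
        return {
            "TP": self.tp, "FP": self.fp, "P": self.p, "N": self.n,
            "precision": self.precision, "recall": self.recall,
            "F05": self.f05, "F2": self.f2,
        }


def compound_hash_index(
    db: Mapping[str, ConformerPharmSet] | Iterable,
    k: int = 4,
    tolerance: float = 0.0,
) -> dict:
    """Distinct k-point sub-pharmacophore hashes per compound.

    Enumerates every k-feature subset of every stereoisomer/conformer
    pharmacophore of each compound; hashes are de-duplicated at the
    compound level but every witness instance ``(stereo_idx, conf_idx,
    feature indices)`` is retained so later growth is complete.

    Returns ``{compound_id: {hash: [witness, ...]}}``.
    """
    import itertools

    if k < 4:
        raise ValueError("pharmacophore hashes need at least 4 points")
    if hasattr(db, "values"):
        sets = list(db.values())
    else:
        sets = list(db)
    index: dict = {}
    for cps in sets:
        per = index.setdefault(cps.compound_id, {})
        for si, ci, p in cps.members:
            if len(p) < k:
                continue
            for idx in itertools.combinations(range(len(p)), k):
                h = pharm_hash(p.subset(idx), tolerance)
                per.setdefault(h, []).append((si, ci, idx))
    return index


def score_hashes(
    index: Mapping[str, Mapping[str, list]],
    actives: Iterable[str],
    inactives: Iterable[str],
) -> dict:
    """Confusion statistics of every hash present in the indexed compounds."""
    actives, inactives = set(actives), set(inactives)
    p, n = len(actives), len(inactives)
    tp: dict = {}
    fp: dict = {}
    for cid, hashes in index.items():
        bucket = tp if cid in actives else fp if cid in inactives else None
        if bucket is None:
            continue
        for h in hashes:
            bucket[h] = bucket.get(h, 0) + 1
    return {
        h: HashStats(h, tp.get(h, 0), fp.get(h, 0), p, n)
        for h in set(tp) | set(fp)
    }


def select_models(
    stats: Iterable[HashStats],
    strategy: str,
    max_models: int = 100,
    f05_threshold: float = 0.8,
) -> list:
    """Apply the per-strategy selection criterion with a tie-tolerant cap.

    Strategy I keeps hashes with F0.5 ≥ 0.8; strategy II keeps hashes
    with F2 = 1 and, when none exists, falls back to recall = 1.  When
    more than ``max_models`` qualify, hashes are ranked by the
    strategy's criterion and every hash whose criterion equals that of
    the 100th-ranked model is kept (ties expand the cap).  Returned
    sorted by criterion descending, then hash for determinism.
    """
    stats = list(stats)
    if strategy == "I":
        sel = [s for s in stats if s.f05 is not None and s.f05 >= f05_threshold - _EPS]
        crit = lambda s: s.f05
    elif strategy == "II":
        sel = [s for s in stats if s.f2 is not None and s.f2 >= 1.0 - _EPS]
        if not sel:
            sel = [
                s for s in stats
                if s.recall is not None and s.recall >= 1.0 - _EPS
            ]
        crit = lambda s: s.f2
    else:
        raise ValueError("strategy must be 'I' or 'II'")
    sel.sort(key=lambda s: (-crit(s), s.hash))
    if len(sel) > max_models:
        threshold = crit(sel[max_models - 1])
        sel = [s for s in sel if crit(s) >= threshold - _EPS]
    return sel


def grow_models(
    selected_hashes: Iterable[str],
    index: Mapping[str, Mapping[str, list]],
    db: Mapping[str, ConformerPharmSet] | Iterable,
    tolerance: float = 0.0,
) -> dict:
    """Extend every witness of the selected hashes by one feature.

    Growth stays within the witness's own conformer: for each witness
    instance, every superset adding one more feature of that conformer
    is hashed.  The child index has the same structure as the parent
    (per-compound hash de-duplication, all witnesses kept).
    """
    selected = set(selected_hashes)
    if hasattr(db, "values"):
        members = {cps.compound_id: cps.member_map() for cps in db.values()}
    else:
        members = {cps.compound_id: cps.member_map() for cps in db}
    child: dict = {}
    for cid, hashes in index.items():
        per = None
        seen_witness = set()
        for h in hashes:
            if h not in selected:
                continue
            for si, ci, idx in hashes[h]:
                p = members[cid][(si, ci)]
                have = set(idx)
                for j in range(len(p)):
                    if j in have:
                        continue
                    new_idx = tuple(sorted(have | {j}))
                    wit = (si, ci, new_idx)
                    if wit in seen_witness:
                        continue  # reachable from several parents
                    seen_witness.add(wit)
                    if per is None:
                        per = child.setdefault(cid, {})
                    hnew = pharm_hash(p.subset(new_idx), tolerance)
                    per.setdefault(hnew, []).append(wit)
    return child


def postprocess_models(models: Sequence[PharmModel]) -> list:
    """Drop models whose features occupy three or fewer distinct points.

    Coincident features (one fragment carrying several labels) can let
    a many-feature model collapse onto a line or triangle of actual
    positions; such models are too simplistic and promiscuous.
    """
    kept = []
    for m in models:
        points = {(f.x, f.y, f.z) for f in m.pharmacophore}
        if len(points) > 3:
            kept.append(m)
    return kept


def _materialize(
    selected: Sequence[HashStats],
    index: Mapping[str, Mapping[str, list]],
    db_members: Mapping[str, Mapping],
    training_set: TrainingSet,
    k: int,
    tolerance: float,
    n_bits: int,
) -> list:
    """Turn selected hashes into concrete PharmModel objects.

    Representative coordinates come from the first witness instance in
    a fixed iteration order (sorted compound id, then member order);
    any witness is valid since all share the hash.
    """
    models = []
    for rank, s in enumerate(selected):
        rep = None
        for cid in sorted(index):
            if s.hash in index[cid]:
                si, ci, idx = sorted(index[cid][s.hash])[0]
                rep = db_members[cid][(si, ci)].subset(idx)
                break
        if rep is None:  # selected hash must have a witness
            raise RuntimeError(f"no witness recorded for hash {s.hash}")
        models.append(
            PharmModel(
                model_id=f"{training_set.set_id}.k{k}.{s.hash[:12]}",
                pharmacophore=rep,
                hash=s.hash,
                fingerprint=pharm_fingerprint(rep, n_bits, tolerance),
                tolerance=tolerance,
                strategy=training_set.strategy,
                training_set_id=training_set.set_id,
                iteration=k,
                stats=s.to_dict(),
            )
        )
    return models


def build_models(
    training_set: TrainingSet,
    db: Mapping[str, ConformerPharmSet] | Iterable,
    tolerance: float = 0.0,
    max_models: int = 100,
    n_bits: int = 2048,
    f05_threshold: float = 0.8,
) -> tuple:
    """Iterative 4→k-point common-pharmacophore search for one training set.

    Runs index → score → select → grow from 4-point seeds upward until
    an iteration selects nothing or nothing can grow, then returns the
    last non-empty selection (post-processed) together with a per-
    iteration log of candidate/selected counts.

    Returns ``(models, log)``; ``models`` is empty (with a warning)
    when nothing qualifies at the 4-point stage.
    """
    if not training_set.actives or not training_set.inactives:
        raise ValueError("training set needs both active and inactive compounds")
    if hasattr(db, "values"):
        sets = {cid: db[cid] for cid in training_set.ids}
    else:
        by_id = {cps.compound_id: cps for cps in db}
        sets = {cid: by_id[cid] for cid in training_set.ids}
    db_members = {cid: cps.member_map() for cid, cps in sets.items()}

    k = 4
    index = compound_hash_index(sets, k=4, tolerance=tolerance)
    final = None  # (k, selected, index)
    log = []
    while True:
        stats = score_hashes(index, training_set.actives, training_set.inactives)
        selected = select_models(
            stats.values(), training_set.strategy, max_models=max_models,
            f05_threshold=f05_threshold,
        )
        log.append(
            {"k": k, "hashes": len(stats), "selected": len(selected)}
        )
        if not selected:
            break
        final = (k, selected, index)
        child = grow_models(
            [s.hash for s in selected], index, sets, tolerance=tolerance
        )
        if not child:
            break
        index = child
        k += 1

    if final is None:
        logger.warning(
            "no 4-point pharmacophore satisfied the selection criterion for %s",
            training_set.set_id,
        )
        return [], log
    k, selected, index = final
    models = _materialize(
        selected, index, db_members, training_set, k, tolerance, n_bits
    )
    return postprocess_models(models), log


# ------------------------------------------------ fit/results user surface


class LigandPharmacophoreModel:
    """Ligand-based common-pharmacophore model specification.

    Holds prepared conformer pharmacophores, activity labels and the
    configuration of the search (strategy, clustering cutoff, distance
    bin step, planarity tolerance); :meth:`fit` runs training-set design
    and the iterative model search and returns a
    :class:`LigandPharmacophoreResults`.

    Parameters
    ----------
    conformer_sets : mapping of compound_id to ConformerPharmSet
    activities : mapping of compound_id to "active"/"inactive"
    strategy : "I" (single binding mode, one diverse training set) or
        "II" (multiple binding modes, one training set per cluster).
    cluster_cutoff : Tanimoto-distance threshold for Butina clustering
        (the study grid is 0.3/0.4/0.5).
    tolerance : planarity tolerance in degrees for stereo signs
        (0 by default; 5 and 10 are the usual alternatives).
    fingerprints : per-compound 2D fingerprints for clustering.  When
        None, the 3D triplet fingerprint of each compound's first
        conformer is used as a similarity stand-in so fully synthetic
        datasets can run the identical pipeline.
    """

    def __init__(
        self,
        conformer_sets: Mapping[str, ConformerPharmSet],
        activities: Mapping[str, str],
        strategy: str = "I",
        cluster_cutoff: float = 0.4,
        tolerance: float = 0.0,
        fingerprints: Mapping[str, object] | None = None,
        max_models: int = 100,
        n_bits: int = 2048,
    ):
        if strategy not in ("I", "II"):
            raise ValueError("strategy must be 'I' or 'II'")
        missing = set(conformer_sets) - set(activities)
        if missing:
            raise ValueError(f"no activity label for {sorted(missing)[:5]}...")
        self.conformer_sets = dict(conformer_sets)
        self.activities = {
            cid: str(activities[cid]).lower() for cid in conformer_sets
        }
        self.strategy = strategy
        self.cluster_cutoff = cluster_cutoff
        self.tolerance = tolerance
        self.max_models = max_models
        self.n_bits = n_bits
        if fingerprints is None:
            fingerprints = {
                cid: pharm_fingerprint(cps.members[0][2], n_bits).bits
                for cid, cps in conformer_sets.items()
            }
            fingerprints = {cid: set(b) for cid, b in fingerprints.items()}
        self.fingerprints = dict(fingerprints)

    # -------------------------------------------------------- constructors

    @classmethod
    def from_dataframe(
        cls,
        df: pd.DataFrame,
        strategy: str = "I",
        cluster_cutoff: float = 0.4,
        bin_step: float = 1.0,
        tolerance: float = 0.0,
        max_conf: int = 100,
        energy_window: float = 50.0,
        seed: int = 42,
        feature_defs=None,
        **kw,
    ) -> "LigandPharmacophoreModel":
        """Build from a table with columns smiles/compound_id/activity.

        Runs the full ligand-preparation pipeline (stereoisomer
        enumeration, conformer generation, feature perception) and
        computes 2D pharmacophore fingerprints for clustering.
        """
        cols = {c.lower(): c for c in df.columns}
        records = [
            CompoundRecord(
                str(row[cols.get("compound_id", cols.get("id"))]),
                str(row[cols["smiles"]]),
                str(row[cols["activity"]]).lower(),
            )
            for _, row in df.iterrows()
        ]
        if feature_defs is None:
            feature_defs = load_feature_definitions()
        sets, skipped = prepare_dataset(
            records,
            feature_defs=feature_defs,
            bin_step=bin_step,
            max_conf=max_conf,
            energy_window=energy_window,
            seed=seed,
        )
        if skipped:
            logger.warning("%d compounds skipped during preparation", len(skipped))
        fps = pharm2d_fingerprints([r for r in records if r.compound_id in sets])
        activities = {r.compound_id: r.activity for r in records}
        return cls(
            sets,
            activities,
            strategy=strategy,
            cluster_cutoff=cluster_cutoff,
            tolerance=tolerance,
            fingerprints=fps,
            **kw,
        )

    @classmethod
    def from_table(cls, path, **kw) -> "LigandPharmacophoreModel":
        """Build from a delimited text file (see ``read_compound_table``)."""
        records = read_compound_table(path)
        df = pd.DataFrame(
            {
                "smiles": [r.smiles for r in records],
                "compound_id": [r.compound_id for r in records],
                "activity": [r.activity for r in records],
            }
        )
        return cls.from_dataframe(df, **kw)

    # ---------------------------------------------------------------- fit

    def _design_training_sets(self, seed: int):
        active_fps = {
            c: f for c, f in self.fingerprints.items()
            if self.activities.get(c) == "active"
        }
        inactive_fps = {
            c: f for c, f in self.fingerprints.items()
            if self.activities.get(c) == "inactive"
        }
        if self.strategy == "I":
            ts, _test = make_training_set_strategy1(
                active_fps, inactive_fps, self.cluster_cutoff
            )
            return [ts]
        return make_training_sets_strategy2(
            active_fps, inactive_fps, self.cluster_cutoff, seed=seed
        )

    def fit(
        self,
        seed: int = 0,
        training_sets: Sequence[TrainingSet] | None = None,
    ) -> "LigandPharmacophoreResults":
        """Design training sets (unless given) and run the model search.

        ``seed`` controls strategy II's random sampling of cluster
        members; identical inputs and seed give identical results.
        """
        if training_sets is None:
            training_sets = self._design_training_sets(seed)
        all_models = []
        logs = {}
        for ts in training_sets:
            models, log = build_models(
                ts,
                self.conformer_sets,
                tolerance=self.tolerance,
                max_models=self.max_models,
                n_bits=self.n_bits,
            )
            all_models.extend(models)
            logs[ts.set_id] = log
        return LigandPharmacophoreResults(
            model=self,
            models=all_models,
            training_sets=list(training_sets),
            logs=logs,
        )


@dataclass
class LigandPharmacophoreResults:
    """Outcome of a common-pharmacophore search.

    Attributes
    ----------
    models : list of PharmModel, across all training sets.
    training_sets : the designed training sets.
    logs : per-set iteration logs (candidate and selected hash counts).
    """

    model: LigandPharmacophoreModel
    models: list
    training_sets: list
    logs: dict = field(default_factory=dict)

    def summary(self) -> pd.DataFrame:
        """One row per selected model with its training statistics."""
        rows = []
        for m in self.models:
            st = m.stats or {}
            rows.append(
                {
                    "model_id": m.model_id,
                    "training_set": m.training_set_id,
                    "strategy": m.strategy,
                    "n_features": m.n_features,
                    "hash": m.hash,
                    "TP": st.get("TP"),
                    "FP": st.get("FP"),
                    "P": st.get("P"),
                    "N": st.get("N"),
                    "precision": st.get("precision"),
                    "recall": st.get("recall"),
                    "F05": st.get("F05"),
                    "F2": st.get("F2"),
                }
            )
        return pd.DataFrame(rows)

    def test_ids(self, training_set_id: str) -> list:
        """External test compounds: everything outside that training set."""
        ts = next(t for t in self.training_sets if t.set_id == training_set_id)
        return sorted(set(self.model.conformer_sets) - ts.ids)

    def screen(self, db=None) -> ScreenResult:
        """Screen all selected models against ``db`` (default: fit data)."""
        if db is None:
            db = self.model.conformer_sets
        return screen_dataset(self.models, db)

    def validate(
        self, db=None, activities=None
    ) -> list:
        """External validation reports (per model plus consensus).

        By default each model is evaluated on the fit compounds outside
        its own training set; a separate labelled ``db`` may be given.
        """
        if db is not None:
            return validate(self.models, db, activities or self.model.activities)
        reports = []
        union: set = set()
        act_all = self.model.activities
        result = self.screen(self.model.conformer_sets)
        for m in self.models:
            ts = next(
                t for t in self.training_sets if t.set_id == m.training_set_id
            )
            test = set(self.model.conformer_sets) - ts.ids
            hits = result.compounds(m.model_id) & test
            union |= hits
            actives = {c for c in test if act_all[c] == "active"}
            inactives = {c for c in test if act_all[c] == "inactive"}
            reports.append(
                ValidationReport.from_counts(
                    m.model_id,
                    tp=len(hits & actives),
                    fp=len(hits & inactives),
                    p=len(actives),
                    n=len(inactives),
                )
            )
        # consensus over the union of per-model test hits, scored on all
        # compounds outside the intersection of training sets
        trained = set()
        for t in self.training_sets:
            trained |= t.ids
        pool = set(self.model.conformer_sets) - trained
        if pool:
            actives = {c for c in pool if act_all[c] == "active"}
            inactives = {c for c in pool if act_all[c] == "inactive"}
            hits = union & pool
            reports.append(
                ValidationReport.from_counts(
                    "consensus",
                    tp=len(hits & actives),
                    fp=len(hits & inactives),
                    p=len(actives),
                    n=len(inactives),
                )
            )
        return reports

    def save(self, directory) -> None:
        """Write one JSON per model plus a summary TSV into ``directory``."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        for m in self.models:
            m.to_json(directory / f"{m.model_id}.json")
        self.summary().to_csv(directory / "summary.tsv", sep="\t", index=False)
        with open(directory / "iterations.log", "w") as fh:
            for set_id, log in self.logs.items():
                for entry in log:
                    fh.write(
                        f"{set_id}\tk={entry['k']}\thashes={entry['hashes']}\t"
                        f"selected={entry['selected']}\n"
                    )

    def __repr__(self):
        return (
            f"<LigandPharmacophoreResults: {len(self.models)} models from "
            f"{len(self.training_sets)} training set(s)>"
        )


def load_models(directory) -> list:
    """Load every model JSON in a directory."""
    directory = Path(directory)
    return [
        PharmModel.from_json(p)
        for p in sorted(directory.glob("*.json"))
    ]
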