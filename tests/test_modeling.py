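"""Training-set design, hash scoring, selection rules and model growth."""

import math

import numpy as np
import pytest

from pharmsig import (
    HashStats,
    LigandPharmacophoreModel,
    PharmModel,
    Pharmacophore,
    TrainingSet,
    build_models,
    cluster_compounds,
    make_training_set_strategy1,
    make_training_sets_strategy2,
    postprocess_models,
    select_models,
)
from pharmsig.modeling import (
    compound_hash_index,
    grow_models,
    load_models,
    score_hashes,
)
from pharmsig.prep import ConformerPharmSet
from pharmsig.synthetic import make_planted_dataset, random_pharmacophore

# ------------------------------------------------------------ clustering


def _orthogonal_fps(n):
    return {f"c{i}": {i * 10 + j for j in range(5)} for i in range(n)}


def test_identical_fingerprints_single_cluster():
    fps = {f"c{i}": {1, 2, 3} for i in range(6)}
    clusters = cluster_compounds(fps, 0.4)
    assert len(clusters) == 1
    assert set(clusters[0].members) == set(fps)


def test_orthogonal_fingerprints_singletons():
    clusters = cluster_compounds(_orthogonal_fps(5), 0.3)
    assert len(clusters) == 5
    assert all(len(c.members) == 1 for c in clusters)


def test_larger_cutoff_never_increases_cluster_count():
    rng = np.random.default_rng(2)
    fps = {
        f"c{i}": set(rng.choice(100, size=25, replace=False)) for i in range(40)
    }
    counts = [len(cluster_compounds(fps, c)) for c in (0.3, 0.5, 0.7, 0.9)]
    assert all(a >= b for a, b in zip(counts, counts[1:]))


def test_empty_input_empty_clustering():
    assert cluster_compounds({}, 0.4) == []


def test_cutoff_domain():
    with pytest.raises(ValueError):
        cluster_compounds(_orthogonal_fps(2), 0.0)


# -------------------------------------------------------- training sets


def _clustered_fps(sizes, prefix, start=0):
    """Fingerprint families: members of one family are near-identical."""
    fps = {}
    for f, size in enumerate(sizes):
        base = {start + f * 50 + j for j in range(20)}
        for m in range(size):
            fps[f"{prefix}{f}_{m}"] = base | {start + f * 50 + 30 + m % 3}
    return fps


def test_strategy1_min_cluster_size_rule():
    act = _clustered_fps([7, 6, 2], "a")
    inact = _clustered_fps([8, 3], "i", start=1000)
    ts, test = make_training_set_strategy1(act, inact, cutoff=0.4)
    assert len(ts.actives) == 2  # clusters of 7 and 6; the pair is too small
    assert len(ts.inactives) == 1
    # training and test partition the dataset
    assert ts.ids | set(test) == set(act) | set(inact)
    assert not ts.ids & set(test)


def test_strategy1_boundary_cluster_of_five():
    act = _clustered_fps([5], "a")
    inact = _clustered_fps([5], "i", start=1000)
    ts, _ = make_training_set_strategy1(act, inact, cutoff=0.4)
    assert len(ts.actives) == 1


def test_strategy1_no_qualifying_active_cluster_is_error():
    act = _clustered_fps([3, 2], "a")
    inact = _clustered_fps([6], "i", start=1000)
    with pytest.raises(ValueError, match="training set empty"):
        make_training_set_strategy1(act, inact, cutoff=0.4)


def test_strategy2_cluster_rules():
    # one joint family with 9 actives and 2 inactives, one with 4 actives
    act = _clustered_fps([9], "a")
    act.update(_clustered_fps([4], "b", start=500))
    inact = {f"i{m}": {1000 + j for j in range(20)} | {1030 + m % 3}
             for m in range(2)}
    # make the 2 inactives co-cluster with the 9-active family
    for m, cid in enumerate(["i0", "i1"]):
        inact[cid] = {0 * 50 + j for j in range(20)} | {35 + m}
    sets = make_training_sets_strategy2(act, inact, cutoff=0.4, seed=5)
    assert len(sets) == 1  # the 4-active family is ignored
    ts = sets[0]
    assert len(ts.actives) == 5
    assert ts.strategy == "II"
    # both available cluster inactives kept (fewer than 5), deduplicated
    assert set(ts.inactives) >= {"i0", "i1"}
    assert len(ts.inactives) == len(set(ts.inactives))


def test_strategy2_deterministic_given_seed():
    act = _clustered_fps([9, 7], "a")
    inact = _clustered_fps([6], "i", start=1000)
    s1 = make_training_sets_strategy2(act, inact, cutoff=0.4, seed=3)
    s2 = make_training_sets_strategy2(act, inact, cutoff=0.4, seed=3)
    assert [t.actives for t in s1] == [t.actives for t in s2]
    assert [t.inactives for t in s1] == [t.inactives for t in s2]


def test_training_set_disjointness_enforced():
    with pytest.raises(ValueError):
        TrainingSet("x", ("a",), ("a",), "I", 0.4)


# ------------------------------------------------------------- indexing


def _single(cid, p):
    cps = ConformerPharmSet(cid)
    cps.add(0, 0, p)
    return cps


def test_hash_index_counts():
    p4 = random_pharmacophore(4, seed=1)
    p6 = random_pharmacophore(6, seed=2)
    idx = compound_hash_index([_single("c4", p4), _single("c6", p6)], k=4)
    assert len(idx["c4"]) == 1
    assert len(idx["c6"]) <= math.comb(6, 4)


def test_duplicate_conformers_collapse():
    from pharmsig.synthetic import random_rigid_transform

    p = random_pharmacophore(5, seed=3)
    cps = ConformerPharmSet("c")
    cps.add(0, 0, p)
    cps.add(0, 1, random_rigid_transform(p, seed=4))
    idx = compound_hash_index([cps], k=4)
    single = compound_hash_index([_single("c", p)], k=4)
    assert set(idx["c"]) == set(single["c"])


# ------------------------------------------------------ scoring/selection


def _stats(**kw):
    defaults = dict(hash="h", tp=0, fp=0, p=5, n=10)
    defaults.update(kw)
    return HashStats(**defaults)


def test_score_hashes_counts_compounds_not_conformers():
    p = random_pharmacophore(4, seed=6)
    cps = ConformerPharmSet("a0")
    cps.add(0, 0, p)
    cps.add(0, 1, p)
    idx = compound_hash_index([cps], k=4)
    stats = score_hashes(idx, actives=["a0"], inactives=[])
    (s,) = stats.values()
    assert s.tp == 1


def test_perfect_hash_metrics():
    s = _stats(tp=5, fp=0)
    assert s.recall == 1 and s.precision == 1 and s.f2 == 1


def test_f05_hand_computed_value():
    s = _stats(tp=4, fp=1)
    assert s.precision == pytest.approx(0.8)
    assert s.recall == pytest.approx(0.8)
    assert s.f05 == pytest.approx(0.8)


def test_selection_strategy1_threshold():
    stats = [
        _stats(hash="a", tp=5, fp=0),       # F0.5 = 1
        _stats(hash="b", tp=4, fp=1),       # F0.5 = 0.8
        _stats(hash="c", tp=4, fp=2),       # F0.5 < 0.8
    ]
    sel = select_models(stats, "I")
    assert [s.hash for s in sel] == ["a", "b"]


def test_selection_strategy2_f2_then_recall_fallback():
    perfect = [_stats(hash="p", tp=5, fp=0)]
    assert [s.hash for s in select_models(perfect, "II")] == ["p"]
    fallback = [
        _stats(hash="r1", tp=5, fp=3),  # recall 1, F2 < 1
        _stats(hash="r2", tp=5, fp=1),
        _stats(hash="x", tp=4, fp=0),   # recall < 1
    ]
    sel = select_models(fallback, "II")
    assert {s.hash for s in sel} == {"r1", "r2"}


def test_selection_cap_keeps_ties_at_rank_100():
    tied = [_stats(hash=f"h{i:03d}", tp=4, fp=1) for i in range(150)]
    sel = select_models(tied, "I", max_models=100)
    assert len(sel) == 150  # all share the criterion value of the 100th
    mixed = tied + [_stats(hash="top", tp=5, fp=0)]
    sel = select_models(mixed, "I", max_models=100)
    assert len(sel) == 151 and sel[0].hash == "top"


def test_selection_cap_cuts_strictly_worse_models():
    stats = [_stats(hash=f"g{i:03d}", tp=5, fp=0) for i in range(100)]
    stats += [_stats(hash=f"w{i:03d}", tp=4, fp=1) for i in range(30)]
    sel = select_models(stats, "I", max_models=100)
    assert len(sel) == 100
    assert all(s.hash.startswith("g") for s in sel)


# ------------------------------------------------------------- growth


def test_growth_containment_and_combinatorics():
    p = random_pharmacophore(6, seed=9)
    cps = _single("c", p)
    idx = compound_hash_index([cps], k=4)
    all_hashes = list(idx["c"])
    child = grow_models(all_hashes, idx, [cps])
    for h, wits in child["c"].items():
        for _, _, indices in wits:
            assert len(indices) == 5
    # a witness in a conformer with exactly k features has no children
    p4 = random_pharmacophore(4, seed=10)
    cps4 = _single("c4", p4)
    idx4 = compound_hash_index([cps4], k=4)
    assert grow_models(list(idx4["c4"]), idx4, [cps4]) == {}


# ----------------------------------------------------------- postprocess


def test_postprocess_drops_coordinate_poor_models():
    pts = [(0.0, 0.0, 0.0), (3.0, 0.0, 0.0), (0.0, 3.0, 0.0)]
    feats = [("A", *pts[0]), ("H", *pts[0]), ("a", *pts[1]),
             ("H", *pts[1]), ("D", *pts[2]), ("A", *pts[2])]
    poor = PharmModel.from_pharmacophore(Pharmacophore(feats), model_id="poor")
    rich = PharmModel.from_pharmacophore(
        random_pharmacophore(4, seed=12), model_id="rich"
    )
    assert postprocess_models([poor, rich]) == [rich]
    assert postprocess_models([]) == []


# ------------------------------------------------------------ build loop


def _training_set(ds, strategy="II"):
    return TrainingSet(
        "ts",
        tuple(s.compound_id for s in ds.actives),
        tuple(s.compound_id for s in ds.inactives),
        strategy,
        0.4,
    )


def test_build_models_recovers_planted_hash(planted):
    models, log = build_models(_training_set(planted), planted.conformer_sets)
    assert any(m.hash == planted.planted_hash for m in models)
    assert all(m.n_features == 5 for m in models)
    # the loop stopped because the 6-point iteration selected nothing
    assert log[-1]["selected"] == 0 and log[-2]["k"] == 5


def test_build_models_monotone_containment(planted):
    """Every final model contains a previously selected sub-model."""
    ts = _training_set(planted)
    models, _ = build_models(ts, planted.conformer_sets)
    idx4 = compound_hash_index(
        {c: planted.conformer_sets[c] for c in ts.ids}, k=4
    )
    stats4 = score_hashes(idx4, ts.actives, ts.inactives)
    selected4 = {s.hash for s in select_models(stats4.values(), "II")}
    import itertools

    from pharmsig import pharm_hash

    for m in models:
        subs = {
            pharm_hash(m.pharmacophore.subset(c))
            for c in itertools.combinations(range(m.n_features), 4)
        }
        assert subs & selected4


def test_build_models_empty_when_no_common_pharmacophore():
    rng = np.random.default_rng(77)
    db = {}
    for i in range(6):
        cid = f"c{i}"
        db[cid] = _single(cid, random_pharmacophore(6, seed=rng))
    ts = TrainingSet("x", ("c0", "c1", "c2"), ("c3", "c4", "c5"), "II", 0.4)
    models, _ = build_models(ts, db)
    assert models == []


def test_selected_models_satisfy_criterion_on_training_set(planted):
    models, _ = build_models(_training_set(planted), planted.conformer_sets)
    for m in models:
        assert m.stats["F2"] == pytest.approx(1.0)


# ------------------------------------------------- fit/results interface


def test_fit_results_surface(tmp_path, planted):
    spec = LigandPharmacophoreModel(
        planted.conformer_sets, planted.activities, strategy="II"
    )
    results = spec.fit(seed=0, training_sets=[_training_set(planted)])
    assert any(m.hash == planted.planted_hash for m in results.models)
    df = results.summary()
    assert {"model_id", "n_features", "F2", "recall"} <= set(df.columns)
    assert (df["F2"] == 1.0).all()

    results.save(tmp_path)
    loaded = load_models(tmp_path)
    assert {m.hash for m in loaded} == {m.hash for m in results.models}
    # determinism: identical inputs + seed give byte-identical model files
    again = spec.fit(seed=0, training_sets=[_training_set(planted)])
    d2 = tmp_path / "again"
    again.save(d2)
    for f in sorted(tmp_path.glob("*.json")):
        assert (d2 / f.name).read_text() == f.read_text()


def test_fit_validates_on_held_out_compounds(planted):
    spec = LigandPharmacophoreModel(
        planted.conformer_sets, planted.activities, strategy="II"
    )
    train = TrainingSet(
        "ts",
        tuple(s.compound_id for s in planted.actives[:5]),
        tuple(s.compound_id for s in planted.inactives[:10]),
        "II",
        0.4,
    )
    results = spec.fit(training_sets=[train])
    reports = results.validate()
    by_id = {r.model_id: r for r in reports}
    planted_models = [m for m in results.models if m.hash == planted.planted_hash]
    assert planted_models
    r = by_id[planted_models[0].model_id]
    assert r.recall == 1.0 and r.fpr == 0.0
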