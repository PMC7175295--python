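"""Minimum depth, root counts and interaction depths vs a brute-force oracle.

The oracle walks trees recursively, recomputing node depths from path
lengths (it never reads the stored ``depth`` field), and enumerates
maximal subtrees by checking the full ancestor path of every node, so it
shares no code path with the implementation.
"""

import numpy as np
import pandas as pd
import pytest

import biopanml as bp
from biopanml.model import ForestModel

FEATURES = [f"r{i}" for i in range(5)]


# ---------------------------------------------------------------------------
# oracle


def oracle_tree_min_depths(tree):
    by_id = {n["id"]: n for n in tree}
    depths = {}

    def walk(nid, depth):
        node = by_id[nid]
        if node["feature"] is None:
            return
        depths.setdefault(node["feature"], []).append(depth)
        walk(node["left"], depth + 1)
        walk(node["right"], depth + 1)

    walk(0, 0)
    return {f: min(ds) for f, ds in depths.items()}


def oracle_min_depth_table(model):
    per_tree = [oracle_tree_min_depths(t) for t in model.trees]
    out = {}
    for f in range(len(model.feature_names)):
        vals = [d[f] for d in per_tree if f in d]
        out[model.feature_names[f]] = {
            "mean": np.mean(vals) if vals else np.nan,
            "containing": len(vals),
        }
    return out


def oracle_root_counts(model):
    counts = dict.fromkeys(range(len(model.feature_names)), 0)
    for tree in model.trees:
        root = next(n for n in tree if n["id"] == 0)
        if root["feature"] is not None:
            counts[root["feature"]] += 1
    return counts


def oracle_interactions(model):
    obs = {}
    for tree in model.trees:
        by_id = {n["id"]: n for n in tree}

        def subtree_nodes(nid, rel):
            node = by_id[nid]
            yield node, rel
            if node["feature"] is not None:
                yield from subtree_nodes(node["left"], rel + 1)
                yield from subtree_nodes(node["right"], rel + 1)

        def walk(nid, ancestors):
            node = by_id[nid]
            if node["feature"] is None:
                return
            u = node["feature"]
            if u not in ancestors:
                best = {}
                for sub, rel in subtree_nodes(nid, 0):
                    if sub["feature"] is not None and rel >= 1:
                        v = sub["feature"]
                        if v not in best or rel < best[v]:
                            best[v] = rel
                for v, d in best.items():
                    obs.setdefault((u, v), []).append(d)
            walk(node["left"], ancestors + [u])
            walk(node["right"], ancestors + [u])

        walk(0, [])
    return {k: (np.mean(v), len(v)) for k, v in obs.items()}


# ---------------------------------------------------------------------------
# random forests with controlled shape


def random_tree(rng, max_depth=5, n_features=5):
    nodes = []
    counter = [0]

    def grow(depth):
        nid = counter[0]
        counter[0] += 1
        make_leaf = depth >= max_depth or (depth > 0 and rng.random() < 0.3)
        if make_leaf:
            nodes.append({"id": nid, "depth": depth, "feature": None,
                          "threshold": None, "left": None, "right": None,
                          "leaf_class": int(rng.integers(2))})
            return nid
        feature = int(rng.integers(n_features))
        node = {"id": nid, "depth": depth, "feature": feature,
                "threshold": float(rng.normal()), "left": None, "right": None,
                "leaf_class": None}
        nodes.append(node)
        node["left"] = grow(depth + 1)
        node["right"] = grow(depth + 1)
        return nid

    grow(0)
    return sorted(nodes, key=lambda n: n["id"])


def random_forest(rng, n_trees=8, max_depth=5):
    model = ForestModel(params={"ntree": n_trees}, feature_names=FEATURES,
                        trees=[random_tree(rng, max_depth)
                               for _ in range(n_trees)])
    model.validate()
    return model


def manual_model(trees):
    model = ForestModel(params={}, feature_names=FEATURES, trees=trees)
    model.validate()
    return model


def leaf(nid, depth, cls=0):
    return {"id": nid, "depth": depth, "feature": None, "threshold": None,
            "left": None, "right": None, "leaf_class": cls}


def split(nid, depth, feature, left, right):
    return {"id": nid, "depth": depth, "feature": feature, "threshold": 0.0,
            "left": left, "right": right, "leaf_class": None}


class TestMinimumDepths:
    def test_root_variable_has_depth_zero(self):
        tree = [split(0, 0, 3, 1, 2), leaf(1, 1), leaf(2, 1)]
        summary = bp.minimum_depths(manual_model([tree]))
        assert summary.table.loc["r3", "mean_min_depth"] == 0.0
        assert summary.table.loc["r3", "root_count"] == 1

    def test_first_occurrence_wins(self):
        # r3 at root, r1 at both depth-1 children -> r1 min depth 1
        tree = [split(0, 0, 3, 1, 2),
                split(1, 1, 1, 3, 4), split(2, 1, 1, 5, 6),
                leaf(3, 2), leaf(4, 2), leaf(5, 2), leaf(6, 2)]
        summary = bp.minimum_depths(manual_model([tree]))
        assert summary.table.loc["r1", "mean_min_depth"] == 1.0
        assert summary.table.loc["r1", "n_trees_containing"] == 1

    def test_absent_variable_excluded_from_mean(self):
        tree = [split(0, 0, 0, 1, 2), leaf(1, 1), leaf(2, 1)]
        summary = bp.minimum_depths(manual_model([tree]))
        assert np.isnan(summary.table.loc["r4", "mean_min_depth"])

    def test_fill_strategy_penalizes_absent_variables(self):
        tree = [split(0, 0, 0, 1, 2), leaf(1, 1), leaf(2, 1)]
        summary = bp.minimum_depths(manual_model([tree]), fill="max_plus_one")
        assert summary.table.loc["r4", "mean_min_depth"] == 2.0  # max depth 1 + 1

    def test_agrees_with_oracle_on_random_forests(self, rng):
        for _ in range(50):
            model = random_forest(rng)
            summary = bp.minimum_depths(model)
            oracle = oracle_min_depth_table(model)
            for name in FEATURES:
                got = summary.table.loc[name]
                want = oracle[name]
                if np.isnan(want["mean"]):
                    assert np.isnan(got["mean_min_depth"])
                else:
                    assert got["mean_min_depth"] == want["mean"]
                assert got["n_trees_containing"] == want["containing"]

    def test_mean_zero_iff_roots_every_containing_tree(self, rng):
        for _ in range(20):
            model = random_forest(rng)
            table = bp.minimum_depths(model).table
            for name in FEATURES:
                row = table.loc[name]
                if row["n_trees_containing"] == 0:
                    continue
                assert (row["mean_min_depth"] == 0.0) == (
                    row["root_count"] == row["n_trees_containing"])


class TestRootCounts:
    def test_identical_trees_concentrate_counts(self):
        tree = [split(0, 0, 4, 1, 2), leaf(1, 1), leaf(2, 1)]
        model = manual_model([tree] * 7)
        counts = bp.root_counts(model)
        assert counts["r4"] == 7

    def test_counts_conserve_ntree(self, rng):
        for _ in range(20):
            model = random_forest(rng)
            assert bp.root_counts(model).sum() == model.n_trees

    def test_agrees_with_oracle(self, rng):
        for _ in range(30):
            model = random_forest(rng)
            got = bp.root_counts(model)
            want = oracle_root_counts(model)
            assert {FEATURES[i]: c for i, c in want.items()} == got.to_dict()


class TestInteractions:
    def test_child_split_scores_conditional_depth_one(self):
        tree = [split(0, 0, 2, 1, 2), split(1, 1, 0, 3, 4),
                leaf(2, 1), leaf(3, 2), leaf(4, 2)]
        inter = bp.interaction_depths(manual_model([tree]))
        row = inter.set_index(["root_variable", "child_variable"]).loc[
            ("r2", "r0")]
        assert row["mean_conditional_depth"] == 1.0
        assert row["occurrences"] == 1

    def test_unobserved_pairs_absent(self):
        tree = [split(0, 0, 2, 1, 2), leaf(1, 1), leaf(2, 1)]
        inter = bp.interaction_depths(manual_model([tree]))
        assert len(inter) == 0  # single split: no pair ever observed

    def test_conditional_depths_at_least_one(self, rng):
        for _ in range(10):
            inter = bp.interaction_depths(random_forest(rng))
            if len(inter):
                assert (inter["mean_conditional_depth"] >= 1.0).all()

    def test_agrees_with_oracle_on_random_forests(self, rng):
        for _ in range(50):
            model = random_forest(rng)
            got = bp.interaction_depths(model)
            want = oracle_interactions(model)
            got_map = {(r.root_variable, r.child_variable):
                       (r.mean_conditional_depth, r.occurrences)
                       for r in got.itertuples()}
            want_map = {(FEATURES[u], FEATURES[v]): (m, c)
                        for (u, v), (m, c) in want.items()}
            assert set(got_map) == set(want_map)
            for key in want_map:
                assert got_map[key][0] == pytest.approx(want_map[key][0])
                assert got_map[key][1] == want_map[key][1]


class TestOnTrainedForests:
    def test_dominant_selection_round_attains_lowest_mean_depth(self):
        # the round carrying all selection signal should win the
        # importance ranking in at least 8 of 10 seeded campaigns
        wins = 0
        for seed in range(10):
            cfg = bp.dominant_round_config(
                4, n_clonotypes=400, binder_fraction=0.2, seed=seed,
                read_depth=(8000,) * 5)
            truth = bp.simulate_repertoire(cfg)
            counts = bp.simulate_panning(truth, cfg)
            ds = bp.truth_tr_dataset(truth, counts)
            train, _ = bp.split_dataset(ds, 0.75, seed=seed)
            model = bp.train_rf(train, mtry=4, ntree=100, seed=seed)
            table = bp.minimum_depths(model).table
            if table["mean_min_depth"].idxmin() == "r4":
                wins += 1
        assert wins >= 8

    def test_oracle_agreement_on_trained_forest(self, truth_labeled_dataset):
        ds = truth_labeled_dataset(seed=9, n=60, depth=500)
        model = bp.train_rf(ds, mtry=2, ntree=8, seed=1)
        summary = bp.minimum_depths(model)
        oracle = oracle_min_depth_table(model)
        for name in FEATURES:
            want = oracle[name]["mean"]
            got = summary.table.loc[name, "mean_min_depth"]
            assert (np.isnan(want) and np.isnan(got)) or got == want

    def test_plot_artifact_written(self, truth_labeled_dataset, tmp_path):
        from biopanml.introspect import plot_min_depth_distribution

        ds = truth_labeled_dataset(seed=10, n=60, depth=500)
        model = bp.train_rf(ds, mtry=2, ntree=5, seed=1)
        out = tmp_path / "depth.png"
        plot_min_depth_distribution(bp.minimum_depths(model), out)
        assert out.stat().st_size > 0
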