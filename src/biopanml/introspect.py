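"""Structure-based variable importance for random forests.

Minimum depth: within one tree, a variable's minimum depth is the depth
of its first (shallowest) splitting node, the root being depth 0. Its
mean over the forest ranks variables — the smaller, the more important —
and the number of trees rooted on a variable is a companion statistic.

Interactions: a *maximal subtree* of variable u is a subtree rooted at a
u-split none of whose ancestors split on u. The conditional depth of
variable v in that subtree (subtree root = 0, so a v-split at a direct
child scores 1) measures how tightly v follows u; its mean over all
maximal u-subtrees in the forest ranks the ordered pair (u, v).

All statistics are computed from the neutral node-list tree encoding of
:class:`~biopanml.model.ForestModel`, so they are independent of the
library that grew the forest.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .model import ForestModel

__all__ = [
    "DepthSummary",
    "minimum_depths",
    "root_counts",
    "interaction_depths",
    "plot_min_depth_distribution",
]


def _children(tree: list[dict]) -> dict[int, dict]:
    return {n["id"]: n for n in tree}


def _tree_min_depths(tree: list[dict], tree_index: int) -> dict[int, int]:
    """First-occurrence depth per split variable in one tree (BFS order)."""
    by_id = _children(tree)
    if 0 not in by_id:
        raise ValueError(f"tree {tree_index}: missing root node")
    depths: dict[int, int] = {}
    frontier = [0]
    while frontier:
        nxt = []
        for nid in frontier:
            node = by_id.get(nid)
            if node is None:
                raise ValueError(f"tree {tree_index}: dangling child id {nid}")
            if node["feature"] is not None:
                f = node["feature"]
                if f not in depths or node["depth"] < depths[f]:
                    depths[f] = node["depth"]
                nxt.extend([node["left"], node["right"]])
        frontier = nxt
    return depths


@dataclass
class DepthSummary:
    """Per-variable minimum-depth statistics over a forest.

    ``per_tree`` is an (n_trees x n_variables) frame of per-tree minimum
    depths, NaN where a tree never splits on the variable. ``table``
    aggregates: mean minimum depth, count of trees rooted on the
    variable, and count of trees containing it.
    """

    per_tree: pd.DataFrame
    table: pd.DataFrame
    fill: Optional[str] = None


def minimum_depths(model: ForestModel, fill: Optional[str] = None) -> DepthSummary:
    """Minimum-depth summary for every feature of a forest.

    ``fill=None`` (default) averages each variable only over the trees
    that contain it. ``fill="max_plus_one"`` substitutes, per tree, one
    more than that tree's maximum node depth for absent variables before
    averaging, penalizing rarely used variables.
    """
    if fill not in (None, "max_plus_one"):
        raise ValueError(f"unknown fill strategy {fill!r}")
    names = model.feature_names
    n_feat = len(names)
    rows = np.full((model.n_trees, n_feat), np.nan)
    roots = np.zeros(n_feat, dtype=int)
    for t, tree in enumerate(model.trees):
        depths = _tree_min_depths(tree, t)
        for f, d in depths.items():
            rows[t, f] = d
        root_feature = _children(tree)[0]["feature"]
        if root_feature is not None:
            roots[root_feature] += 1
        if fill == "max_plus_one":
            tree_max = max(n["depth"] for n in tree)
            absent = np.isnan(rows[t])
            rows[t, absent] = tree_max + 1

    per_tree = pd.DataFrame(rows, columns=names)
    table = pd.DataFrame({
        "variable": names,
        "mean_min_depth": per_tree.mean(axis=0, skipna=True).to_numpy(),
        "root_count": roots,
        "n_trees_containing": (~np.isnan(rows)).sum(axis=0)
        if fill is None else
        np.array([sum(f in _tree_min_depths(tr, t)
                      for t, tr in enumerate(model.trees))
                  for f in range(n_feat)]),
    }).set_index("variable")
    return DepthSummary(per_tree=per_tree, table=table, fill=fill)


def root_counts(model: ForestModel) -> pd.Series:
    """Trees whose root splits on each variable; sums to the tree count."""
    counts = pd.Series(0, index=model.feature_names, dtype=int, name="root_count")
    for t, tree in enumerate(model.trees):
        root = _children(tree).get(0)
        if root is None:
            raise ValueError(f"tree {t}: missing root node")
        if root["feature"] is not None:
            counts.iloc[root["feature"]] += 1
    return counts


def _subtree_min_depths(by_id: dict[int, dict], root_id: int) -> dict[int, int]:
    """Min depth per variable strictly below the subtree root (root = 0).

    The root's own split is excluded so that self-pairs (u, u) score the
    *second* occurrence of u, keeping all conditional depths >= 1.
    """
    base = by_id[root_id]["depth"]
    out: dict[int, int] = {}
    stack = [root_id]
    while stack:
        node = by_id[stack.pop()]
        if node["feature"] is not None:
            rel = node["depth"] - base
            f = node["feature"]
            if rel >= 1 and (f not in out or rel < out[f]):
                out[f] = rel
            stack.extend([node["left"], node["right"]])
    return out


def interaction_depths(model: ForestModel) -> pd.DataFrame:
    """Mean conditional depth for every observed ordered variable pair.

    For each maximal u-subtree the minimal relative depth of every other
    variable v found inside (>= 1 by construction, since the subtree root
    itself splits u) contributes one observation to the pair (u, v).
    Pairs never observed are absent from the result, which is sorted by
    mean conditional depth ascending (ties by occurrence count
    descending, then pair name).
    """
    names = model.feature_names
    sums: dict[tuple[int, int], float] = {}
    counts: dict[tuple[int, int], int] = {}
    for tree in model.trees:
        by_id = _children(tree)
        # DFS carrying the set of ancestor split variables
        stack: list[tuple[int, frozenset[int]]] = [(0, frozenset())]
        while stack:
            nid, ancestors = stack.pop()
            node = by_id[nid]
            if node["feature"] is None:
                continue
            u = node["feature"]
            if u not in ancestors:
                # maximal u-subtree rooted here
                rel = _subtree_min_depths(by_id, nid)
                for v, d in rel.items():
                    if d >= 1:
                        key = (u, v)
                        sums[key] = sums.get(key, 0.0) + d
                        counts[key] = counts.get(key, 0) + 1
            child_anc = ancestors | {u}
            stack.append((node["left"], child_anc))
            stack.append((node["right"], child_anc))
    rows = [{
        "root_variable": names[u],
        "child_variable": names[v],
        "mean_conditional_depth": sums[(u, v)] / counts[(u, v)],
        "occurrences": counts[(u, v)],
    } for (u, v) in sums]
    df = pd.DataFrame(rows, columns=["root_variable", "child_variable",
                                     "mean_conditional_depth", "occurrences"])
    if len(df):
        df = df.sort_values(
            ["mean_conditional_depth", "occurrences",
             "root_variable", "child_variable"],
            ascending=[True, False, True, True]).reset_index(drop=True)
    return df


def plot_min_depth_distribution(summary: DepthSummary, path: str | Path) -> None:
    """Stacked-bar distribution of per-tree minimum depths per variable."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    per_tree = summary.per_tree
    variables = list(per_tree.columns)
    max_depth = int(np.nanmax(per_tree.to_numpy())) if per_tree.size else 0
    fig, ax = plt.subplots(figsize=(7, 4))
    bottom = np.zeros(len(variables))
    cmap = plt.get_cmap("viridis", max_depth + 1)
    for d in range(max_depth + 1):
        frac = [(per_tree[v] == d).sum() for v in variables]
        ax.bar(variables, frac, bottom=bottom, color=cmap(d), label=str(d))
        bottom += np.array(frac, dtype=float)
    means = summary.table["mean_min_depth"].reindex(variables)
    for i, v in enumerate(variables):
        ax.text(i, bottom[i] + 0.5, f"{means[v]:.2f}", ha="center", fontsize=8)
    ax.set_xlabel("predictor variable (panning round abundance)")
    ax.set_ylabel("trees")
    ax.legend(title="min depth", fontsize=7, ncol=2)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
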