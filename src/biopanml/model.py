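"""Classifier benchmarking, random-forest training, tuning and prediction.

The response is binary antigen reactivity (AR/NR) and the predictors are
the five per-round clonal abundances, so every model here is a small
tabular classifier. A roster of standard algorithms is benchmarked with
repeated stratified k-fold cross-validation on accuracy and Cohen's
kappa; the random forest is then tuned over (training sampling ratio,
mtry, ntree), trained, and used to emit per-clonotype predictions with a
tree-vote confidence.

The forest itself is fit with scikit-learn, but every fitted forest is
exported to a neutral node-list encoding (split variable, threshold,
children, depth, leaf class per node) that the introspection module and
the JSON serialization consume; predictions and vote confidences are
computed from that encoding, with ties broken conservatively toward NR.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.discriminant_analysis import (
    LinearDiscriminantAnalysis,
    QuadraticDiscriminantAnalysis,
)
from sklearn.ensemble import AdaBoostClassifier, RandomForestClassifier
from sklearn.model_selection import RepeatedStratifiedKFold
from sklearn.naive_bayes import GaussianNB
from sklearn.svm import SVC

from .clonotypes import round_columns
from .dataset import TRDataset, split_dataset

__all__ = [
    "cohen_kappa",
    "CVBenchmarkResult",
    "benchmark_classifiers",
    "RFTuningGrid",
    "ForestModel",
    "train_rf",
    "tune_rf",
    "EvalMetrics",
    "evaluate",
    "predict_confidence",
    "DEFAULT_ALGORITHMS",
]

logger = logging.getLogger(__name__)

# Benchmark roster: names follow the field's shorthand. RDA (regularized
# discriminant analysis) is realized as shrinkage QDA, the closest
# scikit-learn estimator. Library defaults throughout - no manual tuning
# during benchmarking.
DEFAULT_ALGORITHMS: dict[str, Callable[[int], object]] = {
    "RF": lambda seed: RandomForestClassifier(random_state=seed),
    "RDA": lambda seed: QuadraticDiscriminantAnalysis(reg_param=0.5),
    "LDA": lambda seed: LinearDiscriminantAnalysis(),
    "SVM": lambda seed: SVC(random_state=seed),
    "NB": lambda seed: GaussianNB(),
    "ADA": lambda seed: AdaBoostClassifier(random_state=seed),
}


def cohen_kappa(confusion) -> float:
    """Cohen's kappa from a square confusion matrix.

    kappa = (p_o - p_e) / (1 - p_e), with observed agreement p_o the
    normalized trace and expected agreement p_e from the products of the
    row/column marginals. Returns 1.0 in the degenerate p_e = 1 case
    (all mass in one cell, perfect agreement).
    """
    m = np.asarray(confusion, dtype=float)
    if m.ndim != 2 or m.shape[0] != m.shape[1]:
        raise ValueError("confusion matrix must be square")
    n = m.sum()
    if n <= 0:
        raise ValueError("empty confusion matrix")
    po = np.trace(m) / n
    pe = float((m.sum(axis=1) * m.sum(axis=0)).sum()) / n**2
    if np.isclose(pe, 1.0):
        return 1.0
    return float((po - pe) / (1.0 - pe))


# ---------------------------------------------------------------------------
# benchmarking


@dataclass
class CVBenchmarkResult:
    """Per-algorithm accuracy/kappa values across repeats x folds."""

    results: dict[str, pd.DataFrame]  # columns: repeat, fold, accuracy, kappa
    repeats: int
    folds: int

    def summary(self) -> pd.DataFrame:
        rows = []
        for name, df in self.results.items():
            rows.append({
                "algorithm": name,
                "n_models": len(df),
                "mean_accuracy": df["accuracy"].mean(),
                "mean_kappa": df["kappa"].mean(),
                "max_accuracy": df["accuracy"].max(),
                "max_kappa": df["kappa"].max(),
            })
        return pd.DataFrame(rows)


def benchmark_classifiers(
    ds: TRDataset,
    algorithms: Optional[dict[str, Callable[[int], object]]] = None,
    repeats: int = 5,
    folds: int = 10,
    seed: int = 0,
) -> CVBenchmarkResult:
    """Repeated stratified k-fold benchmark on accuracy and Cohen's kappa.

    Each algorithm is fit ``repeats * folds`` times (default 5 x 10 = 50
    models): per repetition the rows are partitioned into ``folds`` folds,
    each model trains on all but one fold and is scored on the held-out
    fold. Estimators use library defaults. Algorithms whose constructor
    or fit fails are skipped with a log message.
    """
    X, y = ds.X, ds.y
    if len(np.unique(y)) < 2:
        raise ValueError("benchmark requires both AR and NR rows")
    algorithms = algorithms or DEFAULT_ALGORITHMS

    cv = RepeatedStratifiedKFold(n_splits=folds, n_repeats=repeats,
                                 random_state=seed)
    splits = list(cv.split(X, y))
    results: dict[str, pd.DataFrame] = {}
    for name, factory in algorithms.items():
        rows = []
        try:
            for k, (tr, te) in enumerate(splits):
                est = factory(seed)
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    est.fit(X[tr], y[tr])
                    pred = est.predict(X[te])
                conf = _confusion(y[te], pred)
                rows.append({
                    "repeat": k // folds,
                    "fold": k % folds,
                    "accuracy": (conf[0, 0] + conf[1, 1]) / conf.sum(),
                    "kappa": cohen_kappa(conf),
                })
        except Exception as exc:  # estimator unavailable or degenerate
            logger.warning("skipping algorithm %s: %s", name, exc)
            continue
        results[name] = pd.DataFrame(rows)
    return CVBenchmarkResult(results=results, repeats=repeats, folds=folds)


def _confusion(y_true: np.ndarray, y_pred: np.ndarray) -> np.ndarray:
    """2x2 confusion with AR (True) as the positive class.

    Layout: rows = truth (AR, NR), columns = prediction (AR, NR).
    """
    y_true = np.asarray(y_true, dtype=bool)
    y_pred = np.asarray(y_pred, dtype=bool)
    tp = int(np.sum(y_true & y_pred))
    fn = int(np.sum(y_true & ~y_pred))
    fp = int(np.sum(~y_true & y_pred))
    tn = int(np.sum(~y_true & ~y_pred))
    return np.array([[tp, fn], [fp, tn]])


# ---------------------------------------------------------------------------
# the forest


@dataclass
class ForestModel:
    """A trained random forest with a fully inspectable tree encoding.

    ``trees`` holds one node list per tree. Each node is a dict with keys
    ``id``, ``depth``, ``feature`` (feature index, or None at leaves),
    ``threshold`` (split point, None at leaves), ``left``/``right``
    (child ids, None at leaves) and ``leaf_class`` (0 = NR, 1 = AR at
    leaves, else None). Node 0 is the root at depth 0.
    """

    params: dict
    feature_names: list[str]
    trees: list[list[dict]]
    training_meta: dict = field(default_factory=dict)
    estimator: Optional[RandomForestClassifier] = None

    @property
    def n_trees(self) -> int:
        return len(self.trees)

    def validate(self) -> None:
        for t, nodes in enumerate(self.trees):
            by_id = {n["id"]: n for n in nodes}
            if 0 not in by_id or by_id[0]["depth"] != 0:
                raise ValueError(f"tree {t}: missing root at depth 0")
            for node in nodes:
                internal = node["feature"] is not None
                has_children = node["left"] is not None and node["right"] is not None
                if internal != has_children:
                    raise ValueError(f"tree {t}: node {node['id']} must have "
                                     "exactly 2 children iff it splits")
                if has_children:
                    for child in (node["left"], node["right"]):
                        if by_id[child]["depth"] != node["depth"] + 1:
                            raise ValueError(
                                f"tree {t}: child depth inconsistent at node "
                                f"{node['id']}")

    def to_json(self, path: str | Path) -> None:
        payload = {
            "params": self.params,
            "feature_names": self.feature_names,
            "training_meta": self.training_meta,
            "trees": self.trees,
        }
        Path(path).write_text(json.dumps(payload) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "ForestModel":
        payload = json.loads(Path(path).read_text())
        model = cls(
            params=payload["params"],
            feature_names=payload["feature_names"],
            trees=payload["trees"],
            training_meta=payload.get("training_meta", {}),
            estimator=None,
        )
        model.validate()
        return model


def _export_trees(rf: RandomForestClassifier) -> list[list[dict]]:
    """Export sklearn trees to the neutral node-list encoding."""
    classes = list(rf.classes_)
    ar_index = classes.index(True) if True in classes else None
    forests = []
    for est in rf.estimators_:
        t = est.tree_
        nodes: list[dict] = []
        stack = [(0, 0)]  # (node id, depth)
        while stack:
            nid, depth = stack.pop()
            left, right = int(t.children_left[nid]), int(t.children_right[nid])
            is_leaf = left == -1
            if is_leaf:
                counts = t.value[nid][0]
                best = int(np.argmax(counts))  # argmax tie -> first class
                leaf_class = 1 if (ar_index is not None and best == ar_index) else 0
                nodes.append({"id": nid, "depth": depth, "feature": None,
                              "threshold": None, "left": None, "right": None,
                              "leaf_class": leaf_class})
            else:
                nodes.append({"id": nid, "depth": depth,
                              "feature": int(t.feature[nid]),
                              "threshold": float(t.threshold[nid]),
                              "left": left, "right": right, "leaf_class": None})
                stack.append((left, depth + 1))
                stack.append((right, depth + 1))
        nodes.sort(key=lambda n: n["id"])
        forests.append(nodes)
    return forests


def train_rf(
    train: TRDataset,
    mtry: Optional[int] = None,
    ntree: int = 500,
    seed: int = 0,
    sampling_ratio: Optional[float] = None,
) -> ForestModel:
    """Grow a random forest on a TR training set.

    ``ntree`` trees are each grown on a bootstrap sample of the training
    rows with ``mtry`` candidate features considered per split (default:
    sqrt of the feature count). ``sampling_ratio`` is recorded as
    metadata when the caller already subsampled the data.
    """
    X, y = train.X, train.y
    n_features = X.shape[1]
    if mtry is not None and not 1 <= mtry <= n_features:
        raise ValueError(f"mtry must lie in [1, {n_features}], got {mtry}")
    if ntree < 1:
        raise ValueError("ntree must be >= 1")
    if len(np.unique(y)) < 2:
        raise ValueError("training set must contain both AR and NR rows")

    rf = RandomForestClassifier(
        n_estimators=ntree,
        max_features=mtry if mtry is not None else "sqrt",
        bootstrap=True,
        random_state=seed,
        n_jobs=1,
    )
    rf.fit(X, y)
    model = ForestModel(
        params={"sampling_ratio": sampling_ratio, "mtry": mtry,
                "ntree": ntree, "seed": seed},
        feature_names=train.feature_names,
        trees=_export_trees(rf),
        training_meta={"n_train": len(train), "chain": train.chain,
                       "n_positive": int(y.sum())},
        estimator=rf,
    )
    model.validate()
    return model


def _tree_vote(nodes: list[dict], x: np.ndarray) -> int:
    by_id = {n["id"]: n for n in nodes}
    node = by_id[0]
    while node["feature"] is not None:
        node = by_id[node["left"] if x[node["feature"]] <= node["threshold"]
                     else node["right"]]
    return node["leaf_class"]


def forest_votes(model: ForestModel, X: np.ndarray) -> np.ndarray:
    """Fraction of trees voting AR for each row, computed from the
    neutral tree encoding."""
    X = np.asarray(X, dtype=float)
    votes = np.zeros(len(X))
    for nodes in model.trees:
        by_id = {n["id"]: n for n in nodes}
        for i, x in enumerate(X):
            node = by_id[0]
            while node["feature"] is not None:
                node = by_id[node["left"]
                             if x[node["feature"]] <= node["threshold"]
                             else node["right"]]
            votes[i] += node["leaf_class"]
    return votes / model.n_trees


@dataclass
class EvalMetrics:
    """Confusion counts and derived rates, AR as the positive class."""

    tp: int
    fn: int
    fp: int
    tn: int

    @property
    def n(self) -> int:
        return self.tp + self.fn + self.fp + self.tn

    @property
    def accuracy(self) -> float:
        return (self.tp + self.tn) / self.n

    @property
    def sensitivity(self) -> float:
        pos = self.tp + self.fn
        return self.tp / pos if pos else float("nan")

    @property
    def specificity(self) -> float:
        neg = self.tn + self.fp
        return self.tn / neg if neg else float("nan")

    @property
    def confusion(self) -> np.ndarray:
        return np.array([[self.tp, self.fn], [self.fp, self.tn]])


def _predict_bool(model: ForestModel, X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    ar_frac = forest_votes(model, X)
    # strict majority: an exact tie is called NR (conservative)
    pred = ar_frac > 0.5
    confidence = np.where(pred, ar_frac, 1.0 - ar_frac)
    return pred, confidence


def evaluate(model: ForestModel, validation: TRDataset) -> EvalMetrics:
    """Majority-vote predictions on a validation set, scored as a 2x2
    confusion with accuracy, sensitivity (AR recall) and specificity."""
    if len(validation) == 0:
        raise ValueError("validation set is empty")
    pred, _ = _predict_bool(model, validation.X)
    conf = _confusion(validation.y, pred)
    return EvalMetrics(tp=int(conf[0, 0]), fn=int(conf[0, 1]),
                       fp=int(conf[1, 0]), tn=int(conf[1, 1]))


def predict_confidence(model: ForestModel, table: pd.DataFrame) -> pd.DataFrame:
    """Confidence-scored predictions for every clonotype in a table.

    The table must carry the model's feature columns (``r0..rR``).
    Confidence is the winning vote fraction, so it is always >= 0.5 for
    a binary majority vote. Returns a DataFrame with columns ``cdr3_aa``,
    ``label`` ("AR"/"NR"), ``confidence`` and, when present in the input,
    ``full_sequence_available``.
    """
    missing = [c for c in model.feature_names if c not in table.columns]
    if missing:
        raise ValueError(f"table lacks model feature columns {missing}")
    X = table[model.feature_names].to_numpy(dtype=float)
    pred, confidence = _predict_bool(model, X)
    out = pd.DataFrame({
        "cdr3_aa": table["cdr3_aa"].to_numpy(),
        "label": np.where(pred, "AR", "NR"),
        "confidence": confidence,
    })
    if "full_sequence_available" in table.columns:
        out["full_sequence_available"] = table["full_sequence_available"].to_numpy()
    return out


# ---------------------------------------------------------------------------
# tuning


@dataclass
class RFTuningGrid:
    """Grid over sampling ratio, mtry and ntree with replicate splits."""

    sampling_ratios: Sequence[float] = (0.55, 0.65, 0.75)
    mtry_values: Sequence[int] = (2, 3, 4, 5)
    ntree_values: Sequence[int] = (100, 500)
    replicates: int = 10
    optimize_for: str = "accuracy"

    def __post_init__(self) -> None:
        if not (self.sampling_ratios and self.mtry_values and self.ntree_values):
            raise ValueError("all grid axes must be non-empty")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        if self.optimize_for not in ("accuracy", "sensitivity", "specificity"):
            raise ValueError(f"unknown metric {self.optimize_for!r}")
        if any(not 0 < r < 1 for r in self.sampling_ratios):
            raise ValueError("sampling ratios must lie in (0, 1)")

    @property
    def combinations(self) -> list[tuple[float, int, int]]:
        return [(r, m, t) for r in self.sampling_ratios
                for m in self.mtry_values for t in self.ntree_values]


def tune_rf(ds: TRDataset, grid: RFTuningGrid, seed: int = 0
            ) -> tuple[dict, pd.DataFrame]:
    """Evaluate every grid combination on fresh random splits.

    For each (sampling ratio, mtry, ntree) cell, ``grid.replicates``
    models are trained on independent without-replacement samples of the
    data and scored on the complements. The best cell maximizes the mean
    of ``grid.optimize_for``; the full results table (one row per model)
    is returned so the argmax is recomputable.
    """
    n_features = ds.X.shape[1]
    if any(m > n_features for m in grid.mtry_values):
        raise ValueError(f"mtry values must be <= {n_features} features")

    combos = grid.combinations
    child_seeds = np.random.SeedSequence(seed).generate_state(
        len(combos) * grid.replicates) % (2**31)
    rows = []
    k = 0
    for ratio, mtry, ntree in combos:
        for rep in range(grid.replicates):
            s = int(child_seeds[k]); k += 1
            train, val = split_dataset(ds, ratio, seed=s)
            model = train_rf(train, mtry=mtry, ntree=ntree, seed=s,
                             sampling_ratio=ratio)
            metrics = evaluate(model, val)
            rows.append({
                "sampling_ratio": ratio, "mtry": mtry, "ntree": ntree,
                "replicate": rep, "accuracy": metrics.accuracy,
                "sensitivity": metrics.sensitivity,
                "specificity": metrics.specificity,
            })
    table = pd.DataFrame(rows)
    means = (table.groupby(["sampling_ratio", "mtry", "ntree"], sort=False)
             [grid.optimize_for].mean())
    best_key = means.idxmax()  # ties -> first cell in grid order
    best = {"sampling_ratio": best_key[0], "mtry": int(best_key[1]),
            "ntree": int(best_key[2]),
            f"mean_{grid.optimize_for}": float(means.loc[best_key])}
    return best, table
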