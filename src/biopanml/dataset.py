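"""Join reactivity calls to abundance trajectories: the TR
(trajectory-reactivity) data set.

One row per unique CDR3 clonotype of one chain; predictors are the
clonotype's abundance in each phagemid DNA set (rounds 0..R), and the
response is the AR/NR label inherited from the ELISA calls of the clones
that carry the clonotype. A clonotype can appear in several clones with
conflicting calls (light chains especially are shared across pairings);
by default any AR call makes the clonotype AR.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.model_selection import train_test_split

from .clonotypes import round_columns
from .elisa import ReactivityCall

__all__ = ["TRDataset", "build_tr_dataset", "split_dataset",
           "read_tr_tsv", "write_tr_tsv"]

logger = logging.getLogger(__name__)


@dataclass
class TRDataset:
    """Labeled feature table for one chain.

    ``df`` columns: ``cdr3_aa``, abundance features ``r0..rR``, and a
    boolean ``label`` (True = AR). ``unmatched`` lists call CDR3s absent
    from the clonotype table (reported, never silently dropped).
    """

    df: pd.DataFrame
    chain: str
    unmatched: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if "cdr3_aa" not in self.df.columns or "label" not in self.df.columns:
            raise ValueError("TR dataset requires cdr3_aa and label columns")
        if self.df["cdr3_aa"].duplicated().any():
            dupes = self.df.loc[self.df["cdr3_aa"].duplicated(), "cdr3_aa"]
            raise ValueError(f"duplicate CDR3 rows: {sorted(set(dupes))[:5]}")

    def __len__(self) -> int:
        return len(self.df)

    @property
    def feature_names(self) -> list[str]:
        return round_columns(self.df)

    @property
    def X(self) -> np.ndarray:
        return self.df[self.feature_names].to_numpy(dtype=float)

    @property
    def y(self) -> np.ndarray:
        return self.df["label"].to_numpy(dtype=bool)

    def subset(self, index) -> "TRDataset":
        return TRDataset(self.df.loc[index].reset_index(drop=True), self.chain)


def build_tr_dataset(
    table: pd.DataFrame,
    calls: Sequence[ReactivityCall],
    chain: str,
    rule: str = "any",
    use_frequencies: bool = False,
) -> TRDataset:
    """Label clonotype trajectories with ELISA reactivity.

    Parameters
    ----------
    table
        Clonotype count table (from :func:`collate_clonotypes`) for ``chain``.
    calls
        Reactivity calls; each must carry the CDR3 of the requested chain.
    rule
        ``"any"`` (default): a clonotype is AR if any clone containing it
        was called AR. ``"majority"``: AR iff AR calls are at least as
        many as NR calls among its clones.
    use_frequencies
        Use per-round frequencies ``f0..fR`` instead of raw counts as
        features.

    Clones whose CDR3 is absent from the table are collected in
    ``dataset.unmatched`` and logged.
    """
    if rule not in ("any", "majority"):
        raise ValueError(f"unknown label rule {rule!r}")
    if "chain" in table.columns and len(table):
        chains = set(table["chain"].unique())
        if chains != {chain}:
            raise ValueError(f"clonotype table is for chains {sorted(chains)}, "
                             f"requested {chain!r}")

    attr = "hcdr3_aa" if chain == "H" else "lcdr3_aa"
    votes: dict[str, list[bool]] = {}
    for call in calls:
        cdr3 = getattr(call, attr)
        if cdr3 is None:
            raise ValueError(
                f"call for clone {call.clone_id!r} carries no {chain}CDR3")
        votes.setdefault(cdr3, []).append(call.label == "AR")

    rcols = round_columns(table)
    feat_cols = [f"f{c[1:]}" for c in rcols] if use_frequencies else rcols
    indexed = table.set_index("cdr3_aa")

    rows, unmatched = [], []
    for cdr3 in sorted(votes):
        if cdr3 not in indexed.index:
            unmatched.append(cdr3)
            continue
        ar_votes = votes[cdr3]
        if rule == "any":
            label = any(ar_votes)
        else:
            label = sum(ar_votes) >= len(ar_votes) - sum(ar_votes)
        row = {"cdr3_aa": cdr3, "label": label}
        for rcol, fcol in zip(rcols, feat_cols):
            row[rcol] = indexed.at[cdr3, fcol]
        rows.append(row)

    if unmatched:
        logger.warning("%d call CDR3(s) not present in the clonotype table "
                       "(first few: %s)", len(unmatched), unmatched[:5])
    df = pd.DataFrame(rows, columns=["cdr3_aa", *rcols, "label"])
    return TRDataset(df, chain, unmatched=unmatched)


def split_dataset(
    ds: TRDataset,
    train_fraction: float,
    seed: int = 0,
    stratify: bool = False,
) -> tuple[TRDataset, TRDataset]:
    """Partition into train/validation without replacement.

    The train size is ``floor(train_fraction * n)``; the validation set is
    the complement, so the split is disjoint and exhaustive. Unstratified
    by default; ``stratify=True`` balances the label proportions.
    """
    if not 0.0 < train_fraction < 1.0:
        raise ValueError("train_fraction must lie strictly in (0, 1)")
    n = len(ds)
    n_train = int(np.floor(train_fraction * n))
    if n_train < 1 or n - n_train < 1:
        raise ValueError(
            f"degenerate split: {n_train} train / {n - n_train} validation rows")
    idx = np.arange(n)
    strat = ds.y if stratify else None
    train_idx, val_idx = train_test_split(
        idx, train_size=n_train, random_state=seed, shuffle=True, stratify=strat)
    return ds.subset(np.sort(train_idx)), ds.subset(np.sort(val_idx))


def write_tr_tsv(ds: TRDataset, path: str | Path) -> None:
    out = ds.df.copy()
    out["label"] = np.where(out["label"], "AR", "NR")
    out.to_csv(path, sep="\t", index=False)


def read_tr_tsv(path: str | Path, chain: str) -> TRDataset:
    df = pd.read_csv(path, sep="\t")
    df["label"] = df["label"].astype(str).str.upper().eq("AR")
    return TRDataset(df, chain)
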