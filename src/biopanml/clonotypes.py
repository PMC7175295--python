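"""Clonotype collation across panning rounds and Shannon-entropy diversity.

A clonotype is the set of reads sharing one CDR3 amino-acid sequence.
CDR3s extracted per round are collated into a rounds-by-clonotype count
table; a clonotype is valid only if its read count reaches 2 in at least
one round, which suppresses singleton sequencing artifacts. Diversity per
round is Shannon entropy over clonotype frequencies (natural log), which
falls as panning enriches a library.
"""

from __future__ import annotations

from collections import Counter
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "collate_clonotypes",
    "shannon_entropy",
    "entropy_profile",
    "round_columns",
    "read_clonotype_tsv",
    "write_clonotype_tsv",
]


def round_columns(table: pd.DataFrame) -> list[str]:
    """Count columns r0, r1, ... in round order."""
    cols = [c for c in table.columns if c.startswith("r") and c[1:].isdigit()]
    return sorted(cols, key=lambda c: int(c[1:]))


def _normalize_items(items: Iterable, chain: str) -> list[str]:
    out = []
    for item in items:
        if isinstance(item, tuple):
            cdr3, item_chain = item
            if item_chain != chain:
                raise ValueError(
                    f"mixed chains: expected {chain!r}, got {item_chain!r} "
                    f"for CDR3 {cdr3!r}")
            out.append(cdr3)
        else:
            out.append(item)
    return out


def collate_clonotypes(
    per_round_cdr3s: Sequence[Iterable[str]],
    chain: str = "H",
    min_count: int = 2,
) -> pd.DataFrame:
    """Collate per-round CDR3 multisets into a clonotype count table.

    Parameters
    ----------
    per_round_cdr3s
        One iterable of CDR3 strings per round (round 0 first). Items may
        also be ``(cdr3, chain)`` tuples; a chain other than ``chain``
        raises ValueError.
    min_count
        Validity rule: a clonotype is retained only if its count reaches
        ``min_count`` in at least one round (default 2).

    Returns
    -------
    DataFrame with columns ``cdr3_aa``, ``chain``, per-round counts
    ``r0..rR`` and per-round frequencies ``f0..fR`` over retained rows
    (NaN for rounds with zero total). Rows are sorted by total count
    descending, ties broken lexicographically by sequence.
    """
    counters = [Counter(_normalize_items(items, chain)) for items in per_round_cdr3s]
    all_cdr3s = sorted(set().union(*[c.keys() for c in counters]) if counters else [])
    n_rounds = len(counters)

    table = pd.DataFrame({"cdr3_aa": all_cdr3s, "chain": chain})
    for r, counter in enumerate(counters):
        table[f"r{r}"] = [counter.get(c, 0) for c in all_cdr3s]

    rcols = [f"r{r}" for r in range(n_rounds)]
    if all_cdr3s:
        keep = table[rcols].max(axis=1) >= min_count
        table = table[keep]
        total = table[rcols].sum(axis=1)
        order = pd.DataFrame({"total": -total, "cdr3_aa": table["cdr3_aa"]})
        table = table.loc[order.sort_values(["total", "cdr3_aa"]).index]
        table = table.reset_index(drop=True)

    for r in range(n_rounds):
        col_total = table[f"r{r}"].sum() if len(table) else 0
        table[f"f{r}"] = (table[f"r{r}"] / col_total) if col_total > 0 else np.nan
    return table


def shannon_entropy(counts, base: Optional[float] = None) -> float:
    """Shannon entropy of a clonotype count vector.

    H = -sum p_i log p_i over positive-count clonotypes, with
    p_i = count_i / total. Natural log (nats) by default; pass
    ``base=2`` for bits. An all-zero or empty vector raises ValueError.
    """
    arr = np.asarray(counts, dtype=float)
    if arr.size == 0:
        raise ValueError("entropy of an empty count vector is undefined")
    if (arr < 0).any():
        raise ValueError("counts must be non-negative")
    if arr.sum() <= 0:
        raise ValueError("entropy undefined when all counts are zero")
    return float(stats.entropy(arr[arr > 0], base=base))


def entropy_profile(table: pd.DataFrame, base: Optional[float] = None) -> pd.Series:
    """Per-round Shannon entropy of a clonotype table.

    Rounds whose count column sums to zero are reported as NaN
    (undefined), not zero.
    """
    if len(table) == 0:
        raise ValueError("entropy profile of an empty clonotype table is undefined")
    rcols = round_columns(table)
    values = {}
    for col in rcols:
        counts = table[col].to_numpy()
        values[col] = shannon_entropy(counts, base=base) if counts.sum() > 0 else np.nan
    return pd.Series(values, name="shannon_entropy")


def write_clonotype_tsv(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, sep="\t", index=False, float_format="%.8g")


def read_clonotype_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
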