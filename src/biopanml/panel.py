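"""Confidence-ranked AR/NR clonotype panels and clone-pairing structure.

After prediction, the highest-confidence AR clonotypes of each chain are
selected for gene synthesis (optionally restricted to clonotypes whose
full V-gene sequence could be recovered), and a small NR panel serves as
the negative control. The pairing report summarizes a set of validated
scFv clones: unique heavy/light CDR3s, unique H/L pairs, and light
chains promiscuously shared across several heavy partners.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import pandas as pd

__all__ = ["Panel", "PairingReport", "select_panel", "pairing_report",
           "read_clones_tsv"]

logger = logging.getLogger(__name__)


@dataclass
class Panel:
    """A confidence-sorted panel of clonotypes of one label and chain."""

    chain: str
    label: str
    entries: pd.DataFrame  # cdr3_aa, confidence[, full_sequence_available]

    def __len__(self) -> int:
        return len(self.entries)

    def to_tsv(self, path: str | Path) -> None:
        self.entries.to_csv(path, sep="\t", index=False)


def select_panel(
    predictions: pd.DataFrame,
    label: str,
    n: int,
    min_confidence: float = 0.9,
    require_available: bool = False,
    chain: str = "H",
) -> Panel:
    """Top-n clonotypes of one predicted label by confidence.

    Eligible predictions carry the requested ``label``, confidence
    strictly above ``min_confidence``, and (when ``require_available``)
    a true ``full_sequence_available`` flag. Sorting is by confidence
    descending with lexicographic CDR3 tie-break, so selection is
    deterministic. Fewer than ``n`` qualifying entries yield a shorter
    panel with a logged warning.
    """
    if label not in ("AR", "NR"):
        raise ValueError(f"label must be 'AR' or 'NR', got {label!r}")
    if n < 1:
        raise ValueError("panel size must be >= 1")
    pool = predictions[(predictions["label"] == label)
                       & (predictions["confidence"] > min_confidence)]
    if require_available:
        if "full_sequence_available" not in pool.columns:
            raise ValueError("predictions lack a full_sequence_available column")
        pool = pool[pool["full_sequence_available"].astype(bool)]
    pool = pool.drop_duplicates(subset="cdr3_aa")
    pool = pool.sort_values(["confidence", "cdr3_aa"],
                            ascending=[False, True]).head(n)
    if len(pool) < n:
        logger.warning("panel %s/%s: only %d of %d requested clonotypes "
                       "qualify at confidence > %g", chain, label, len(pool),
                       n, min_confidence)
    cols = ["cdr3_aa", "confidence"]
    if "full_sequence_available" in pool.columns:
        cols.append("full_sequence_available")
    return Panel(chain=chain, label=label,
                 entries=pool[cols].reset_index(drop=True))


@dataclass
class PairingReport:
    """Uniqueness and light-chain-redundancy summary of scFv clones."""

    n_clones: int
    n_unique_scfv: int
    n_unique_hcdr3: int
    n_unique_lcdr3: int
    promiscuous_lcdr3: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "n_clones": self.n_clones,
            "n_unique_scfv": self.n_unique_scfv,
            "n_unique_hcdr3": self.n_unique_hcdr3,
            "n_unique_lcdr3": self.n_unique_lcdr3,
            "promiscuous_lcdr3": list(self.promiscuous_lcdr3),
        }


def pairing_report(
    clones: Iterable[tuple[str, str, str]] | pd.DataFrame,
) -> PairingReport:
    """Summarize H/L pairing structure of a clone list.

    ``clones`` is an iterable of ``(clone_id, hcdr3_aa, lcdr3_aa)`` or a
    DataFrame with those columns. A unique scFv is a unique (HCDR3,
    LCDR3) pair; a promiscuous LCDR3 is one paired with at least two
    distinct HCDR3s. Identity is exact amino-acid identity.
    """
    if isinstance(clones, pd.DataFrame):
        triples = list(clones[["clone_id", "hcdr3_aa", "lcdr3_aa"]]
                       .itertuples(index=False, name=None))
    else:
        triples = list(clones)

    pairs = {(h, l) for _, h, l in triples}
    hset = {h for _, h, _ in triples}
    lset = {l for _, _, l in triples}
    partners: dict[str, set[str]] = {}
    for _, h, l in triples:
        partners.setdefault(l, set()).add(h)
    promiscuous = sorted(l for l, hs in partners.items() if len(hs) >= 2)
    return PairingReport(
        n_clones=len(triples),
        n_unique_scfv=len(pairs),
        n_unique_hcdr3=len(hset),
        n_unique_lcdr3=len(lset),
        promiscuous_lcdr3=promiscuous,
    )


def read_clones_tsv(path: str | Path) -> pd.DataFrame:
    """Read a clone table with columns clone_id, hcdr3_aa, lcdr3_aa."""
    df = pd.read_csv(path, sep="\t")
    required = {"clone_id", "hcdr3_aa", "lcdr3_aa"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"clone table missing columns {sorted(missing)}")
    return df
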