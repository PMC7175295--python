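"""Phage-ELISA relative absorbances and antigen-reactivity calls.

Each retrieved phage clone is assayed in three well types: antigen-coated,
anti-tag-antibody-coated (capturing total displayed phage, used as the
normalizer), and blocked-only (background). Two normalized readouts are
formed per clone:

    A = mean(antigen wells) / mean(anti-tag wells)
    B = mean(blocked wells) / mean(anti-tag wells)

A clone is called antigen-reactive (AR) when its A strictly exceeds the
batch background threshold mean(B) + 3·SD(B), with the sample (n-1)
standard deviation taken across the clones of the batch.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ELISARecord",
    "ReactivityCall",
    "relative_absorbances",
    "call_reactive",
    "records_to_frame",
    "frame_to_records",
    "read_elisa_tsv",
    "write_calls_tsv",
    "read_calls_tsv",
]


@dataclass
class ELISARecord:
    """Replicate absorbances for one clone on the three well types."""

    clone_id: str
    hcdr3_aa: Optional[str]
    lcdr3_aa: Optional[str]
    antigen_abs: list[float]
    anti_tag_abs: list[float]
    blocked_abs: list[float]

    def __post_init__(self) -> None:
        for name in ("antigen_abs", "anti_tag_abs", "blocked_abs"):
            vals = getattr(self, name)
            if len(vals) == 0:
                raise ValueError(f"clone {self.clone_id!r}: empty {name}")
            if any(v < 0 for v in vals):
                raise ValueError(f"clone {self.clone_id!r}: negative {name}")


@dataclass
class ReactivityCall:
    """AR/NR call for one clone, with the threshold that produced it."""

    clone_id: str
    rel_abs_a: float
    rel_abs_b: float
    label: str  # "AR" or "NR"
    threshold_used: float
    hcdr3_aa: Optional[str] = None
    lcdr3_aa: Optional[str] = None


def relative_absorbances(rec: ELISARecord) -> tuple[float, float]:
    """Relative Absorbance A (antigen) and B (blocked), anti-tag-normalized.

    Raises ValueError when the anti-tag mean is zero: without displayed
    phage signal the clone is uninterpretable.
    """
    tag = float(np.mean(rec.anti_tag_abs))
    if tag <= 0:
        raise ValueError(
            f"clone {rec.clone_id!r}: anti-tag mean is zero, ratios undefined")
    a = float(np.mean(rec.antigen_abs)) / tag
    b = float(np.mean(rec.blocked_abs)) / tag
    return a, b


def call_reactive(records: Sequence[ELISARecord], n_sd: float = 3.0
                  ) -> list[ReactivityCall]:
    """Call AR/NR for a batch of clones against the +3·SD background band.

    The threshold mean(B) + ``n_sd``·SD(B) is computed once across the
    batch (sample SD, ddof=1) and recorded on every call; a clone is AR
    iff its A strictly exceeds it. At least two records are required for
    the SD to be defined.
    """
    if len(records) < 2:
        raise ValueError("need at least 2 records to define the SD of B")
    ab = [relative_absorbances(rec) for rec in records]
    bs = np.array([b for _, b in ab])
    threshold = float(bs.mean() + n_sd * bs.std(ddof=1))
    calls = []
    for rec, (a, b) in zip(records, ab):
        calls.append(ReactivityCall(
            clone_id=rec.clone_id,
            rel_abs_a=a,
            rel_abs_b=b,
            label="AR" if a > threshold else "NR",
            threshold_used=threshold,
            hcdr3_aa=rec.hcdr3_aa,
            lcdr3_aa=rec.lcdr3_aa,
        ))
    return calls


# ---------------------------------------------------------------------------
# TSV round-trip (replicates stored comma-joined in one column)


def records_to_frame(records: Sequence[ELISARecord]) -> pd.DataFrame:
    return pd.DataFrame({
        "clone_id": [r.clone_id for r in records],
        "hcdr3_aa": [r.hcdr3_aa or "" for r in records],
        "lcdr3_aa": [r.lcdr3_aa or "" for r in records],
        "antigen_abs": [",".join(f"{v:.6g}" for v in r.antigen_abs) for r in records],
        "anti_tag_abs": [",".join(f"{v:.6g}" for v in r.anti_tag_abs) for r in records],
        "blocked_abs": [",".join(f"{v:.6g}" for v in r.blocked_abs) for r in records],
    })


def frame_to_records(df: pd.DataFrame) -> list[ELISARecord]:
    records = []
    for row in df.itertuples():
        records.append(ELISARecord(
            clone_id=str(row.clone_id),
            hcdr3_aa=str(row.hcdr3_aa) or None,
            lcdr3_aa=str(row.lcdr3_aa) or None,
            antigen_abs=[float(v) for v in str(row.antigen_abs).split(",")],
            anti_tag_abs=[float(v) for v in str(row.anti_tag_abs).split(",")],
            blocked_abs=[float(v) for v in str(row.blocked_abs).split(",")],
        ))
    return records


def read_elisa_tsv(path: str | Path) -> list[ELISARecord]:
    return frame_to_records(pd.read_csv(path, sep="\t", keep_default_na=False))


def write_calls_tsv(calls: Sequence[ReactivityCall], path: str | Path) -> None:
    pd.DataFrame({
        "clone_id": [c.clone_id for c in calls],
        "hcdr3_aa": [c.hcdr3_aa or "" for c in calls],
        "lcdr3_aa": [c.lcdr3_aa or "" for c in calls],
        "rel_abs_a": [c.rel_abs_a for c in calls],
        "rel_abs_b": [c.rel_abs_b for c in calls],
        "label": [c.label for c in calls],
        "threshold_used": [c.threshold_used for c in calls],
    }).to_csv(path, sep="\t", index=False)


def read_calls_tsv(path: str | Path) -> list[ReactivityCall]:
    df = pd.read_csv(path, sep="\t", keep_default_na=False)
    return [
        ReactivityCall(
            clone_id=str(r.clone_id),
            rel_abs_a=float(r.rel_abs_a),
            rel_abs_b=float(r.rel_abs_b),
            label=str(r.label),
            threshold_used=float(r.threshold_used),
            hcdr3_aa=str(r.hcdr3_aa) or None,
            lcdr3_aa=str(r.lcdr3_aa) or None,
        )
        for r in df.itertuples()
    ]
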