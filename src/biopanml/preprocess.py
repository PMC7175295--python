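"""Amplicon read pre-processing for CDR3 clonotype extraction.

Reads come from short amplicons spanning the 3' end of framework region 3
(FR3), the full CDR3, and the 5' end of FR4 of an antibody chain. The
pipeline applied to each (merged) read is:

1. mean-Phred quality filter,
2. locate both library-construction primers (3' primer as its reverse
   complement, exact match first, then a Hamming scan),
3. frame check on the inter-primer span,
4. translate and excise the CDR3 between conserved anchor motifs
   (Cys context on the 5' side, the FR4 ``WG.G``/``FG.G`` motif on
   the 3' side).

A read failing step *k* is charged to that step only, so the rejection
statistics partition the input.
"""

from __future__ import annotations

import gzip
import json
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Optional

import numpy as np
from Bio.Seq import Seq

__all__ = [
    "ReadRecord",
    "FilterConfig",
    "RejectionStats",
    "default_filter_config",
    "merge_pairs",
    "extract_cdr3",
    "filter_and_extract",
    "read_fastq",
    "write_fastq",
    "HEAVY_PRIMER_5P",
    "HEAVY_PRIMER_3P",
    "LIGHT_PRIMER_5P",
    "LIGHT_PRIMER_3P",
]

# Primers hybridizing to FR3/FR4 of the chicken V genes used to amplify the
# CDR3-spanning fragment. The 3' primer is stored in primer orientation; on
# the sequenced top strand it appears as its reverse complement.
HEAVY_PRIMER_5P = "GGCTGCAGCTGAACAACCTCAGGGCTG"
HEAVY_PRIMER_3P = "GGAGGAGACGATGACTTCGGTCCCGTGG"
LIGHT_PRIMER_5P = "CCCTTCACGATTCTCCGGTGCC"
LIGHT_PRIMER_3P = "CTGACCTAGGACGGTCAGGG"

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

_VALID_BASES = frozenset("ACGTN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class ReadRecord:
    """A single sequencing read: identifier, bases, per-base Phred scores."""

    id: str
    bases: str
    quals: list[int]

    def __post_init__(self) -> None:
        if len(self.bases) != len(self.quals):
            raise ValueError(
                f"read {self.id!r}: {len(self.bases)} bases but "
                f"{len(self.quals)} quality values"
            )
        if not set(self.bases) <= _VALID_BASES:
            bad = sorted(set(self.bases) - _VALID_BASES)
            raise ValueError(f"read {self.id!r}: invalid bases {bad}")

    def __len__(self) -> int:
        return len(self.bases)

    @property
    def mean_phred(self) -> float:
        return float(np.mean(self.quals)) if self.quals else 0.0


@dataclass
class FilterConfig:
    """Thresholds and motifs for the four-step read filter.

    ``cdr3_anchor_5p``/``cdr3_anchor_3p`` are amino-acid regular
    expressions; the CDR3 is the translated segment strictly between the
    first 5' anchor match and the first 3' anchor match after it.
    """

    chain: str
    primer_5p: str
    primer_3p: str
    min_mean_phred: float = 20.0
    max_primer_mismatches: int = 1
    cdr3_anchor_5p: str = "YYC"
    cdr3_anchor_3p: str = "WG.G"
    min_cdr3_len: int = 4
    max_cdr3_len: int = 40

    def __post_init__(self) -> None:
        if self.chain not in ("H", "L"):
            raise ValueError(f"chain must be 'H' or 'L', got {self.chain!r}")
        if not self.primer_5p or not self.primer_3p:
            raise ValueError("primers must be non-empty")
        if not self.cdr3_anchor_5p or not self.cdr3_anchor_3p:
            raise ValueError("CDR3 anchor motifs must be non-empty")
        if self.max_primer_mismatches < 0:
            raise ValueError("max_primer_mismatches must be >= 0")


def default_filter_config(chain: str, **overrides) -> FilterConfig:
    """Chain-appropriate default filter settings.

    Heavy chains use the ``WG.G`` FR4 anchor, light chains ``FG.G``.
    """
    if chain == "H":
        cfg = dict(chain="H", primer_5p=HEAVY_PRIMER_5P, primer_3p=HEAVY_PRIMER_3P,
                   cdr3_anchor_3p="WG.G")
    elif chain == "L":
        cfg = dict(chain="L", primer_5p=LIGHT_PRIMER_5P, primer_3p=LIGHT_PRIMER_3P,
                   cdr3_anchor_3p="FG.G")
    else:
        raise ValueError(f"chain must be 'H' or 'L', got {chain!r}")
    cfg.update(overrides)
    return FilterConfig(**cfg)


@dataclass
class RejectionStats:
    """Per-reason read rejection counts; reasons partition the input."""

    low_quality: int = 0
    missing_primer: int = 0
    out_of_frame: int = 0
    no_cdr3: int = 0
    passed: int = 0

    @property
    def total(self) -> int:
        return (self.low_quality + self.missing_primer + self.out_of_frame
                + self.no_cdr3 + self.passed)

    def to_dict(self) -> dict:
        return {
            "low_quality": self.low_quality,
            "missing_primer": self.missing_primer,
            "out_of_frame": self.out_of_frame,
            "no_cdr3": self.no_cdr3,
            "passed": self.passed,
            "total": self.total,
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n")


# ---------------------------------------------------------------------------
# pair merging


def merge_pairs(
    r1: ReadRecord,
    r2: ReadRecord,
    min_overlap: int = 10,
    max_mismatch_frac: float = 0.1,
) -> Optional[ReadRecord]:
    """Merge a read pair by its best ungapped 3' overlap.

    ``r2`` is given in sequencing orientation and reverse-complemented
    internally. Candidate overlaps of length >= ``min_overlap`` are scored
    by mismatch fraction; the lowest-fraction overlap wins (longest on
    ties). At disagreeing positions the higher-quality base is kept.
    Returns ``None`` when no overlap qualifies.
    """
    if min_overlap < 1:
        raise ValueError("min_overlap must be >= 1")
    b2 = reverse_complement(r2.bases)
    q2 = list(reversed(r2.quals))
    n1, n2 = len(r1), len(r2)

    best_o, best_frac = None, None
    for o in range(min(n1, n2), min_overlap - 1, -1):
        tail = r1.bases[n1 - o:]
        head = b2[:o]
        mism = sum(a != b for a, b in zip(tail, head))
        frac = mism / o
        if frac <= max_mismatch_frac and (best_frac is None or frac < best_frac):
            best_o, best_frac = o, frac
    if best_o is None:
        return None

    o = best_o
    cons_bases: list[str] = []
    cons_quals: list[int] = []
    for i in range(o):
        a, qa = r1.bases[n1 - o + i], r1.quals[n1 - o + i]
        b, qb = b2[i], q2[i]
        if a == b:
            cons_bases.append(a)
            cons_quals.append(max(qa, qb))
        elif qb > qa:
            cons_bases.append(b)
            cons_quals.append(qb)
        else:  # ties go to the forward read
            cons_bases.append(a)
            cons_quals.append(qa)
    merged_bases = r1.bases[: n1 - o] + "".join(cons_bases) + b2[o:]
    merged_quals = r1.quals[: n1 - o] + cons_quals + q2[o:]
    return ReadRecord(id=r1.id, bases=merged_bases, quals=merged_quals)


# ---------------------------------------------------------------------------
# primer location and CDR3 extraction


def _find_with_mismatches(haystack: str, needle: str, max_mm: int, start: int = 0
                          ) -> int:
    """Leftmost position of ``needle`` in ``haystack`` allowing up to
    ``max_mm`` substitutions; exact search first. Returns -1 if absent."""
    pos = haystack.find(needle, start)
    if pos != -1 or max_mm == 0:
        return pos
    k = len(needle)
    for i in range(start, len(haystack) - k + 1):
        mm = 0
        window = haystack[i : i + k]
        for a, b in zip(window, needle):
            if a != b:
                mm += 1
                if mm > max_mm:
                    break
        else:
            return i
    return -1


def _locate_primers(bases: str, config: FilterConfig) -> Optional[tuple[int, int]]:
    """0-based half-open inter-primer interval, or None if either primer
    is absent."""
    p5 = config.primer_5p
    p3rc = reverse_complement(config.primer_3p)
    i5 = _find_with_mismatches(bases, p5, config.max_primer_mismatches)
    if i5 == -1:
        return None
    start = i5 + len(p5)
    i3 = _find_with_mismatches(bases, p3rc, config.max_primer_mismatches, start)
    if i3 == -1:
        return None
    return start, i3


def _extract_from_region(region_nt: str, config: FilterConfig) -> Optional[str]:
    """Translate an in-frame inter-primer region and excise the CDR3."""
    if len(region_nt) % 3 != 0 or not region_nt:
        return None
    if "N" in region_nt:
        return None
    aa = str(Seq(region_nt).translate())
    m5 = re.search(config.cdr3_anchor_5p, aa)
    if m5 is None:
        return None
    m3 = re.search(config.cdr3_anchor_3p, aa[m5.end():])
    if m3 is None:
        return None
    cdr3 = aa[m5.end() : m5.end() + m3.start()]
    if "*" in cdr3:
        return None
    if not (config.min_cdr3_len <= len(cdr3) <= config.max_cdr3_len):
        return None
    return cdr3


def extract_cdr3(read: ReadRecord, config: FilterConfig) -> Optional[str]:
    """Extract the CDR3 amino-acid sequence from one read.

    The translation frame is anchored at the end of the 5' primer (the
    amplicon design places the primer flush with a codon boundary).
    Returns ``None`` when the primers or anchors cannot be located, a stop
    codon falls inside the CDR3, or its length is out of bounds.
    """
    loc = _locate_primers(read.bases, config)
    if loc is None:
        return None
    start, end = loc
    return _extract_from_region(read.bases[start:end], config)


def filter_and_extract(
    reads: Iterable[ReadRecord], config: FilterConfig
) -> tuple[list[str], RejectionStats]:
    """Apply the four filters in order and extract one CDR3 per passing read.

    Filter order: (1) mean Phred below threshold, (2) missing primer,
    (3) inter-primer span out of frame, (4) no identifiable CDR3.
    """
    stats = RejectionStats()
    cdr3s: list[str] = []
    for read in reads:
        if read.mean_phred < config.min_mean_phred:
            stats.low_quality += 1
            continue
        loc = _locate_primers(read.bases, config)
        if loc is None:
            stats.missing_primer += 1
            continue
        start, end = loc
        if (end - start) % 3 != 0 or end == start:
            stats.out_of_frame += 1
            continue
        cdr3 = _extract_from_region(read.bases[start:end], config)
        if cdr3 is None:
            stats.no_cdr3 += 1
            continue
        stats.passed += 1
        cdr3s.append(cdr3)
    return cdr3s, stats


# ---------------------------------------------------------------------------
# FASTQ I/O (gz-transparent)


def _open_text(path: str | Path, mode: str = "rt"):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


def read_fastq(path: str | Path) -> Iterator[ReadRecord]:
    """Iterate ReadRecords from a (possibly gzipped) FASTQ file."""
    from Bio import SeqIO

    with _open_text(path) as handle:
        for i, rec in enumerate(SeqIO.parse(handle, "fastq")):
            try:
                yield ReadRecord(
                    id=rec.id,
                    bases=str(rec.seq).upper(),
                    quals=list(rec.letter_annotations["phred_quality"]),
                )
            except ValueError as exc:
                raise ValueError(f"malformed FASTQ record #{i} in {path}: {exc}")


def write_fastq(records: Iterable[ReadRecord], path: str | Path) -> None:
    """Write 4-line FASTQ (Sanger Phred+33)."""
    with _open_text(path, "wt") as out:
        for rec in records:
            qual = "".join(chr(q + 33) for q in rec.quals)
            out.write(f"@{rec.id}\n{rec.bases}\n+\n{qual}\n")
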