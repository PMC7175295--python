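"""Synthetic bio-panning data with the statistical structure the analysis assumes.

A phage-display campaign is emulated in four pieces:

* a **repertoire** of CDR3 clonotypes for one antibody chain, a small
  fraction of which are true antigen binders with stochastically larger
  capture strengths;
* **panning trajectories**: per-round clonotype frequencies evolve by
  exponential selection tilting ``p_i' ∝ p_i · s_i^{w_r}`` (capture
  strength ``s_i``, wash-stringency exponent ``w_r``), and sequencing is a
  multinomial draw of the configured read depth from those frequencies;
* **amplicon reads**: each counted clonotype copy becomes a read laid out
  as 5' primer + FR3 tail + CDR3 codons + FR4 head + reverse-complemented
  3' primer, with uniform synonymous-codon choice, per-base substitution
  errors, and synthetic Phred strings;
* **ELISA readings**: absorbance triplets on antigen-coated, anti-tag and
  blocked wells, with binders drawing the antigen well from a high-mean
  law and non-binders from the blocked-well law.

All randomness flows from ``SimulationConfig.seed``; identical seeds
reproduce byte-identical outputs.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from Bio.Data import CodonTable

from .elisa import ELISARecord
from .preprocess import ReadRecord, reverse_complement, write_fastq

__all__ = [
    "SimulationConfig",
    "SimulationTruth",
    "dominant_round_config",
    "simulate_repertoire",
    "simulate_paired_repertoire",
    "simulate_panning",
    "simulate_reads",
    "simulate_elisa",
    "write_truth_tsv",
    "read_truth_tsv",
    "write_elisa_tsv",
]

AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"

# amino acid -> synonymous codons, standard genetic code
_CODONS: dict[str, list[str]] = {}
for codon, aa in CodonTable.unambiguous_dna_by_id[1].forward_table.items():
    _CODONS.setdefault(aa, []).append(codon)
for aa in _CODONS:
    _CODONS[aa].sort()

# Constant framework context flanking the CDR3 in simulated amplicons. The
# FR3 tail ends in the conserved Tyr-Tyr-Cys anchor; the FR4 head starts
# with the chain-specific Trp/Phe-Gly-X-Gly motif.
FR3_TAIL = {"H": "SAVYYC", "L": "DSAYYC"}
FR4_HEAD = {"H": "WGHGTE", "L": "FGAGTT"}
ANCHOR_3P = {"H": "WG.G", "L": "FG.G"}


def _junction_unambiguous(cdr3: str, chain: str) -> bool:
    """True when the first 3' anchor match in cdr3+FR4 is the real one.

    A CDR3 that itself completes a Trp/Phe-Gly-X-Gly motif (internally or
    across the FR4 junction) would be truncated at extraction time, so the
    generator only emits junction-unambiguous sequences.
    """
    m = re.search(ANCHOR_3P[chain], cdr3 + FR4_HEAD[chain])
    return m is not None and m.start() == len(cdr3)


class ConfigurationError(ValueError):
    """Raised for invalid simulation configuration."""


@dataclass
class SimulationConfig:
    """Study-condition parameters for one simulated panning campaign.

    Defaults mirror the emulated campaign: five phagemid DNA sets (round 0
    before panning, rounds 1-4 after each panning round) with wash
    stringencies proportional to the 1/3/3/5 wash schedule, and a
    positive-clone fraction of 0.23 (the validated hit rate of the
    retrieved clones). The exponent scale (0.1 per wash) is set so that
    four rounds enrich binders strongly but not to fixation - the final
    pool still contains non-binders, as a real campaign's does.
    """

    n_clonotypes: int = 2000
    binder_fraction: float = 0.23
    affinity_law: dict = field(default_factory=lambda: {
        "name": "lognormal", "sigma": 0.5,
        "binder_scale": 10.0, "nonbinder_scale": 1.0,
    })
    wash_stringency: tuple[float, ...] = (0.0, 0.1, 0.3, 0.3, 0.5)
    read_depth: tuple[int, ...] = (20000, 20000, 20000, 20000, 20000)
    cdr3_length_law: dict = field(default_factory=lambda: {
        "name": "uniform_int", "low": 8, "high": 18,
    })
    read_error_rate: float = 0.001
    seed: int = 0
    chain: str = "H"

    def __post_init__(self) -> None:
        if self.n_clonotypes < 1:
            raise ConfigurationError("n_clonotypes must be positive")
        if not 0.0 <= self.binder_fraction <= 1.0:
            raise ConfigurationError("binder_fraction must lie in [0, 1]")
        if len(self.wash_stringency) != len(self.read_depth):
            raise ConfigurationError(
                "wash_stringency and read_depth must have equal length")
        if any(w < 0 for w in self.wash_stringency):
            raise ConfigurationError("wash exponents must be >= 0")
        if any(d < 0 for d in self.read_depth):
            raise ConfigurationError("read depths must be >= 0")
        if not 0.0 <= self.read_error_rate <= 1.0:
            raise ConfigurationError("read_error_rate must lie in [0, 1]")
        if self.chain not in ("H", "L"):
            raise ConfigurationError("chain must be 'H' or 'L'")
        _validate_law(self.affinity_law, {"lognormal", "gamma"})
        _validate_law(self.cdr3_length_law, {"uniform_int", "constant"})

    @property
    def n_rounds(self) -> int:
        return len(self.read_depth)


def _validate_law(law: dict, allowed: set[str]) -> None:
    if not isinstance(law, dict) or "name" not in law:
        raise ConfigurationError(f"distribution spec must be a dict with a "
                                 f"'name' key, got {law!r}")
    if law["name"] not in allowed:
        raise ConfigurationError(
            f"unknown distribution {law['name']!r}; expected one of {sorted(allowed)}")


def dominant_round_config(dominant_round: int = 4, strong: float = 3.0,
                          weak: float = 0.0, **overrides) -> SimulationConfig:
    """Config in which one round carries essentially all selection signal.

    Every wash exponent is ``weak`` except ``dominant_round``, which gets
    ``strong``; abundance at and after that round is then the only
    informative feature, which recovery tests for minimum-depth importance
    rely on. The last round is the cleanest choice because no later round
    can inherit its signal.
    """
    base = SimulationConfig(**overrides)
    if not 1 <= dominant_round < base.n_rounds:
        raise ConfigurationError("dominant_round must be a panning round >= 1")
    wash = [weak] * base.n_rounds
    wash[0] = 0.0
    wash[dominant_round] = strong
    return replace(base, wash_stringency=tuple(wash))


@dataclass
class SimulationTruth:
    """Ground truth per simulated clonotype.

    ``table`` columns: chain, cdr3_aa, is_binder, capture_strength,
    initial_frequency. Initial frequencies sum to 1 within each chain.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"chain", "cdr3_aa", "is_binder", "capture_strength",
                    "initial_frequency"}
        missing = required - set(self.table.columns)
        if missing:
            raise ValueError(f"truth table missing columns {sorted(missing)}")
        if (self.table["capture_strength"] <= 0).any():
            raise ValueError("capture strengths must be positive")
        for chain, sub in self.table.groupby("chain"):
            if not np.isclose(sub["initial_frequency"].sum(), 1.0):
                raise ValueError(f"initial frequencies for chain {chain} "
                                 "must sum to 1")

    def __len__(self) -> int:
        return len(self.table)

    def for_chain(self, chain: str) -> pd.DataFrame:
        sub = self.table[self.table["chain"] == chain]
        if sub.empty:
            raise ValueError(f"no clonotypes for chain {chain!r}")
        return sub.reset_index(drop=True)

    @property
    def chains(self) -> list[str]:
        return sorted(self.table["chain"].unique())


def _rng(seed: int, stream: int) -> np.random.Generator:
    # distinct deterministic substream per operation
    return np.random.default_rng([seed, stream])


def _draw_capture_strengths(law: dict, is_binder: np.ndarray,
                            rng: np.random.Generator) -> np.ndarray:
    n = len(is_binder)
    scale = np.where(is_binder, law.get("binder_scale", 10.0),
                     law.get("nonbinder_scale", 1.0))
    if law["name"] == "lognormal":
        sigma = law.get("sigma", 0.5)
        return scale * np.exp(sigma * rng.standard_normal(n))
    if law["name"] == "gamma":
        shape = law.get("shape", 2.0)
        return scale * rng.gamma(shape, 1.0 / shape, size=n)
    raise ConfigurationError(f"unknown affinity law {law['name']!r}")


def _draw_cdr3_lengths(law: dict, n: int, rng: np.random.Generator) -> np.ndarray:
    if law["name"] == "uniform_int":
        low, high = int(law.get("low", 8)), int(law.get("high", 18))
        if low < 1 or high < low:
            raise ConfigurationError("invalid uniform_int length bounds")
        return rng.integers(low, high + 1, size=n)
    if law["name"] == "constant":
        value = int(law.get("value", 12))
        if value < 1:
            raise ConfigurationError("constant CDR3 length must be >= 1")
        return np.full(n, value)
    raise ConfigurationError(f"unknown CDR3 length law {law['name']!r}")


def _simulate_chain(config: SimulationConfig, chain: str,
                    is_binder: Optional[np.ndarray] = None) -> pd.DataFrame:
    rng = _rng(config.seed, 1 if chain == "H" else 2)
    n = config.n_clonotypes
    if is_binder is None:
        is_binder = rng.random(n) < config.binder_fraction
    else:
        is_binder = np.asarray(is_binder, dtype=bool)
        rng.random(n)  # keep downstream draws aligned with the unpaired path

    lengths = _draw_cdr3_lengths(config.cdr3_length_law, n, rng)
    alphabet = np.array(list(AA_ALPHABET))
    seen: set[str] = set()
    cdr3s: list[str] = []
    for length in lengths:
        while True:
            seq = "".join(rng.choice(alphabet, size=int(length)))
            if seq not in seen and _junction_unambiguous(seq, chain):
                seen.add(seq)
                cdr3s.append(seq)
                break

    strengths = _draw_capture_strengths(config.affinity_law, is_binder, rng)
    # heavy-tailed clone sizes, normalized to frequencies
    raw = rng.lognormal(mean=0.0, sigma=1.2, size=n)
    freqs = raw / raw.sum()
    return pd.DataFrame({
        "chain": chain,
        "cdr3_aa": cdr3s,
        "is_binder": is_binder,
        "capture_strength": strengths,
        "initial_frequency": freqs,
    })


def simulate_repertoire(config: SimulationConfig) -> SimulationTruth:
    """Draw a repertoire of unique CDR3 clonotypes with ground-truth labels.

    Binder status is Bernoulli(``binder_fraction``); binders draw capture
    strengths from the binder-scaled branch of ``affinity_law`` and are
    therefore stochastically stronger than non-binders.
    """
    return SimulationTruth(_simulate_chain(config, config.chain))


def simulate_paired_repertoire(config: SimulationConfig
                               ) -> tuple[SimulationTruth, SimulationTruth]:
    """Heavy- and light-chain repertoires with aligned binder status.

    Clonotype ``i`` of the H repertoire pairs with clonotype ``i`` of the
    L repertoire (one scFv clone per index), sharing one binder flag, so
    clone-level reactivity is consistent across chains.
    """
    h = _simulate_chain(replace(config, chain="H"), "H")
    l = _simulate_chain(replace(config, chain="L"), "L",
                        is_binder=h["is_binder"].to_numpy())
    return SimulationTruth(h), SimulationTruth(l)


def simulate_panning(truth: SimulationTruth, config: SimulationConfig,
                     chain: Optional[str] = None) -> pd.DataFrame:
    """Selection-weighted resampling over panning rounds.

    Round 0 counts are Multinomial(depth_0, initial frequencies). For each
    later round the frequency vector is tilted, ``p_i' ∝ p_i · s_i^{w_r}``,
    and counts are a fresh multinomial draw at that round's depth. Counts
    per round sum exactly to the configured depth.
    """
    chain = chain or config.chain
    sub = truth.for_chain(chain)
    rng = _rng(config.seed, 11 if chain == "H" else 12)
    p = sub["initial_frequency"].to_numpy(dtype=float).copy()
    p = p / p.sum()
    s = sub["capture_strength"].to_numpy(dtype=float)

    out = pd.DataFrame({"cdr3_aa": sub["cdr3_aa"], "chain": chain})
    for r in range(config.n_rounds):
        if r > 0:
            w = config.wash_stringency[r]
            p = p * s ** w
            p = p / p.sum()
        out[f"r{r}"] = rng.multinomial(config.read_depth[r], p)
    return out


def expected_frequencies(truth: SimulationTruth, config: SimulationConfig,
                         chain: Optional[str] = None) -> pd.DataFrame:
    """Deterministic per-round frequency expectations (no sequencing noise)."""
    chain = chain or config.chain
    sub = truth.for_chain(chain)
    p = sub["initial_frequency"].to_numpy(dtype=float).copy()
    p /= p.sum()
    s = sub["capture_strength"].to_numpy(dtype=float)
    out = pd.DataFrame({"cdr3_aa": sub["cdr3_aa"]})
    for r in range(config.n_rounds):
        if r > 0:
            p = p * s ** config.wash_stringency[r]
            p /= p.sum()
        out[f"p{r}"] = p
    return out


def truth_tr_dataset(truth: SimulationTruth, counts: pd.DataFrame,
                     chain: Optional[str] = None):
    """Oracle-labeled TR dataset: ground-truth binder status as response.

    Bypasses clone retrieval and ELISA, labeling every simulated
    clonotype's abundance trajectory with its true binder flag - the
    full-information dataset used in parameter-recovery studies.
    """
    from .dataset import TRDataset

    chain = chain or str(counts["chain"].iloc[0])
    sub = truth.for_chain(chain)
    merged = counts.merge(sub[["cdr3_aa", "is_binder"]], on="cdr3_aa")
    rcols = [c for c in counts.columns if c.startswith("r") and c[1:].isdigit()]
    df = merged[["cdr3_aa", *rcols]].copy()
    df["label"] = merged["is_binder"].to_numpy(dtype=bool)
    return TRDataset(df, chain)


# ---------------------------------------------------------------------------
# amplicon reads


def _encode_aa(aa_seq: str, rng: np.random.Generator) -> str:
    codons = []
    for aa in aa_seq:
        if aa not in _CODONS:
            raise ValueError(f"cannot reverse-translate residue {aa!r}")
        choices = _CODONS[aa]
        codons.append(choices[rng.integers(len(choices))])
    return "".join(codons)


_BASES = np.array(list("ACGT"))
_BASE_INDEX = {b: i for i, b in enumerate("ACGT")}


def simulate_reads(
    truth: SimulationTruth,
    counts: pd.DataFrame,
    config: SimulationConfig,
    chain: Optional[str] = None,
    primers: Optional[tuple[str, str]] = None,
    baseline_phred: int = 38,
    low_qual_rate: float = 0.02,
) -> dict[int, list[ReadRecord]]:
    """Expand per-round clonotype counts into error-bearing amplicon reads.

    Each read is ``primer_5p + FR3-tail codons + CDR3 codons + FR4-head
    codons + revcomp(primer_3p)``; synonymous codons are chosen uniformly
    per read. Substitution errors hit every base independently at
    ``read_error_rate``; Phred strings are a constant high baseline with
    rare low-quality positions. Read multiplicities equal the requested
    counts before errors are applied.
    """
    from . import preprocess as pp

    chain = chain or config.chain
    if primers is None:
        primers = ((pp.HEAVY_PRIMER_5P, pp.HEAVY_PRIMER_3P) if chain == "H"
                   else (pp.LIGHT_PRIMER_5P, pp.LIGHT_PRIMER_3P))
    p5, p3 = primers
    p3rc = reverse_complement(p3)
    fr3, fr4 = FR3_TAIL[chain], FR4_HEAD[chain]

    sub = truth.for_chain(chain)
    cdr3_of = sub["cdr3_aa"].to_list()
    count_cols = [c for c in counts.columns if c.startswith("r") and c[1:].isdigit()]
    counts = counts.set_index("cdr3_aa")

    rng = _rng(config.seed, 21 if chain == "H" else 22)
    per_round: dict[int, list[ReadRecord]] = {}
    for col in count_cols:
        rnum = int(col[1:])
        reads: list[ReadRecord] = []
        for ci, cdr3 in enumerate(cdr3_of):
            c = int(counts.at[cdr3, col]) if cdr3 in counts.index else 0
            for copy in range(c):
                insert = _encode_aa(fr3 + cdr3 + fr4, rng)
                bases = list(p5 + insert + p3rc)
                n = len(bases)
                # substitution errors
                if config.read_error_rate > 0:
                    errs = np.flatnonzero(rng.random(n) < config.read_error_rate)
                    for pos in errs:
                        orig = bases[pos]
                        alt = _BASES[(_BASE_INDEX[orig] + rng.integers(1, 4)) % 4]
                        bases[pos] = str(alt)
                quals = np.full(n, baseline_phred, dtype=int)
                low = np.flatnonzero(rng.random(n) < low_qual_rate)
                if low.size:
                    quals[low] = rng.integers(3, 15, size=low.size)
                reads.append(ReadRecord(
                    id=f"{chain}_r{rnum}_c{ci}_{copy}",
                    bases="".join(bases),
                    quals=quals.tolist(),
                ))
        per_round[rnum] = reads
    return per_round


def write_reads_fastq(per_round: dict[int, list[ReadRecord]], outdir: str | Path,
                      prefix: str = "round") -> dict[int, Path]:
    """Write one FASTQ per round, named ``<prefix><r>.fastq``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}
    for rnum, reads in sorted(per_round.items()):
        path = outdir / f"{prefix}{rnum}.fastq"
        write_fastq(reads, path)
        paths[rnum] = path
    return paths


# ---------------------------------------------------------------------------
# ELISA


def simulate_elisa(
    clones: Sequence[tuple[str, Optional[str], Optional[str]]],
    truth: SimulationTruth,
    noise_sd: float = 0.1,
    seed: int = 0,
    binder_mean: float = 2.0,
    background_mean: float = 0.2,
    anti_tag_mean: float = 1.0,
    n_replicates: int = 3,
) -> list[ELISARecord]:
    """Noisy absorbance triplets for retrieved clones.

    ``clones`` is a list of ``(clone_id, hcdr3_aa, lcdr3_aa)`` (either CDR3
    may be None for single-chain clones). A clone is treated as a binder
    iff every chain present is a true binder in ``truth``. Binder clones
    draw the antigen well around ``binder_mean``; non-binders draw it from
    the blocked-well law around ``background_mean``; anti-tag wells share
    ``anti_tag_mean``. Gaussian noise with ``noise_sd`` on every replicate,
    truncated at zero.
    """
    lookup: dict[tuple[str, str], bool] = {
        (row.chain, row.cdr3_aa): bool(row.is_binder)
        for row in truth.table.itertuples()
    }
    rng = np.random.default_rng([seed, 31])
    records: list[ELISARecord] = []
    for clone_id, h, l in clones:
        statuses = []
        for chain, cdr3 in (("H", h), ("L", l)):
            if cdr3 is None:
                continue
            if (chain, cdr3) not in lookup:
                raise ValueError(
                    f"clone {clone_id!r}: {chain}CDR3 {cdr3!r} not in truth")
            statuses.append(lookup[(chain, cdr3)])
        if not statuses:
            raise ValueError(f"clone {clone_id!r} has no CDR3s")
        is_binder = all(statuses)
        ag_mean = binder_mean if is_binder else background_mean

        def _draw(mean: float) -> list[float]:
            vals = mean + noise_sd * rng.standard_normal(n_replicates)
            return np.clip(vals, 0.0, None).tolist()

        records.append(ELISARecord(
            clone_id=clone_id, hcdr3_aa=h, lcdr3_aa=l,
            antigen_abs=_draw(ag_mean),
            anti_tag_abs=_draw(anti_tag_mean),
            blocked_abs=_draw(background_mean),
        ))
    return records


# ---------------------------------------------------------------------------
# plain-text serialization


def write_truth_tsv(truth: SimulationTruth, path: str | Path) -> None:
    truth.table.to_csv(path, sep="\t", index=False)


def read_truth_tsv(path: str | Path) -> SimulationTruth:
    return SimulationTruth(pd.read_csv(path, sep="\t"))


def write_elisa_tsv(records: Sequence[ELISARecord], path: str | Path) -> None:
    from .elisa import records_to_frame

    records_to_frame(records).to_csv(path, sep="\t", index=False)
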