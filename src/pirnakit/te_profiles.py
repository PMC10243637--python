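"""Per-transposon piRNA profiles: end coverage, strand bias, 1U fraction.

End profiles accumulate the weighted 5' and 3' ends of piRNA reads (>= 23 nt)
on a transposon consensus, normalized to counts per million genome mappers
(CPM). Strand bias is the antisense fraction of the total; transposons with
at least 10% of reads from each strand are eligible for ping-pong linkage;
transposons expressed more than 3-fold higher in whole ovaries than in
embryos are attributed to the somatic compartment and excluded from it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .core import AlignmentRecord, LibraryStats, PIRNA_MIN_LEN, SmallRNARead


@dataclass
class EndProfile:
    """Per-position 5'/3' end coverage of one reference, in CPM."""

    reference: str
    length: int
    five_sense: np.ndarray
    three_sense: np.ndarray
    five_antisense: np.ndarray
    three_antisense: np.ndarray
    sense_total: float = 0.0
    antisense_total: float = 0.0

    @classmethod
    def empty(cls, reference: str, length: int) -> "EndProfile":
        z = lambda: np.zeros(length)
        return cls(reference, length, z(), z(), z(), z())


def build_end_profile(te_alignments: Iterable[AlignmentRecord],
                      library_stats: LibraryStats,
                      reference_length: int | None = None,
                      min_len: int = PIRNA_MIN_LEN) -> EndProfile:
    """Accumulate weighted piRNA end counts on a single consensus.

    Each instance adds ``count * weight`` (scaled to CPM by the library's
    genome-mapper total) at its 5' and 3' end positions on its strand.
    Reads shorter than ``min_len`` contribute nothing.
    """
    alignments = [a for a in te_alignments if a.read.length >= min_len]
    refs = {a.reference for a in alignments}
    if len(refs) > 1:
        raise ValueError(f"alignments span multiple references: {sorted(refs)}")
    name = refs.pop() if refs else "empty"
    if reference_length is None:
        reference_length = max((a.end for a in alignments), default=0)
    scale = 1e6 / library_stats.total_genome_mappers
    prof = EndProfile.empty(name, reference_length)
    for aln in alignments:
        mass = aln.read.count * aln.weight * scale
        if aln.strand == "+":
            prof.five_sense[aln.five_prime] += mass
            prof.three_sense[aln.three_prime] += mass
            prof.sense_total += mass
        else:
            prof.five_antisense[aln.five_prime] += mass
            prof.three_antisense[aln.three_prime] += mass
            prof.antisense_total += mass
    return prof


def strand_bias(profile: EndProfile) -> float | None:
    """Antisense fraction of the total; None when the profile is empty."""
    total = profile.sense_total + profile.antisense_total
    if total == 0:
        return None
    return profile.antisense_total / total


def first_u_fraction(reads: Iterable[SmallRNARead]) -> pd.DataFrame:
    """Per-length fractions of the 5'-most nucleotide, weighted by count.

    Returns a DataFrame indexed by read length with columns A/C/G/T(/N);
    rows sum to 1. The T column is the 1U fraction.
    """
    counts: dict[int, dict[str, float]] = {}
    for read in reads:
        if not read.sequence:
            continue
        by_base = counts.setdefault(read.length, {})
        base = read.sequence[0]
        by_base[base] = by_base.get(base, 0) + read.count
    df = pd.DataFrame(counts).T.fillna(0.0).sort_index()
    for col in "ACGT":
        if col not in df.columns:
            df[col] = 0.0
    df = df[[c for c in ["A", "C", "G", "T", "N"] if c in df.columns]]
    return df.div(df.sum(axis=1), axis=0)


@dataclass
class TESelection:
    """Ranked nonredundant transposon list with a redundancy audit."""

    ranked: list[str]
    kept: list[str]
    absorbed_by: dict[str, str] = field(default_factory=dict)


def select_nonredundant_te(te_counts: pd.Series, te_share: pd.DataFrame,
                           top_n: int = 150,
                           share_threshold: float = 0.5) -> TESelection:
    """Rank transposons by piRNA abundance and drop redundant entries.

    ``te_share`` holds the weighted reads mapping to both of a pair of
    entries. Walking the top-``top_n`` ranking, a lower-ranked entry is
    absorbed by the highest-ranked retained entry with which it shares more
    than ``share_threshold`` of its own weighted reads.
    """
    ranked = list(te_counts.sort_values(ascending=False).index[:top_n])
    kept: list[str] = []
    absorbed: dict[str, str] = {}
    for name in ranked:
        own = te_counts[name]
        absorber = None
        if own > 0:
            for prior in kept:
                shared = 0.0
                if name in te_share.index and prior in te_share.columns:
                    shared = float(te_share.at[name, prior])
                if shared / own > share_threshold:
                    absorber = prior
                    break
        if absorber is None:
            kept.append(name)
        else:
            absorbed[name] = absorber
    return TESelection(ranked=ranked, kept=kept, absorbed_by=absorbed)


def classify_te_compartment(ovary_cpm: float, embryo_cpm: float,
                            fold: float = 3.0,
                            pseudocount: float = 0.1) -> str:
    """"soma_enriched" when ovary expression exceeds fold x embryo.

    A pseudocount guards ratios against zero embryo expression.
    """
    if ovary_cpm > fold * (embryo_cpm + pseudocount):
        return "soma_enriched"
    return "germline"


def both_strand_eligibility(profile: EndProfile, min_frac: float = 0.10) -> bool:
    """True when at least min_frac of reads come from each strand (inclusive)."""
    total = profile.sense_total + profile.antisense_total
    if total == 0:
        return False
    return min(profile.sense_total, profile.antisense_total) / total >= min_frac


def te_summary_table(profiles: Sequence[EndProfile]) -> pd.DataFrame:
    """Per-TE table of totals, strand bias and both-strand eligibility."""
    rows = []
    for prof in profiles:
        rows.append({
            "te": prof.reference,
            "sense_cpm": prof.sense_total,
            "antisense_cpm": prof.antisense_total,
            "strand_bias": strand_bias(prof),
            "both_strands": both_strand_eligibility(prof),
        })
    return pd.DataFrame(rows)
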