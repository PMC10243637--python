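"""Raw small-RNA reads to filtered, collapsed piRNA read sets.

The cloning scheme ligates a 3' adapter carrying a 4-nt UMI
(``5rApp/NNNNAGATCGGAAGAGCACACGTCT``) and a 5' adapter ending in 4 random
nucleotides, so a sequencing read is ``[5'UMI][insert][3'UMI][adapter...]``.
Trimming locates the adapter, removes it and everything downstream, then
strips the UMIs from both ends. Size selection keeps 18-40 nt inserts and
discards the two synthetic size-marker spikes. Reads matching infrastructural
RNAs (rRNA/snoRNA/snRNA/miRNA/tRNA) are removed, with the microRNA-matching
count retained as a normalization denominator.

Mapping here is a brute-force Hamming-distance search intended for toy
references (consensus sequences, synthetic genomes up to a few Mb); real
genome alignments are ingested as SAM/BED produced externally.
"""

from __future__ import annotations

import logging
from typing import Iterable, Mapping, Sequence

import numpy as np
from intervaltree import IntervalTree
from numpy.lib.stride_tricks import sliding_window_view

from .core import (AlignmentRecord, LibraryStats, SmallRNARead, revcomp,
                   VALID_BASES, normalize_sequence)

log = logging.getLogger(__name__)

#: genomic-strand prefix of the 3' cloning adapter (after the 3' UMI)
ADAPTER_3P = "AGATCGGAAGAGCACACGTCT"

#: DNA form of the radio-labelled size-selection spikes
SPIKE_19MER = "CGTACGCGGGTTTAAACGA"
SPIKE_35MER = "CTCATCTTGGTCGTACGCGGAATAGTTTAAACTGT"

#: number of adapter bases used for the exact prefix match
_ADAPTER_SEED = 10


def trim_read(raw: str, adapter3: str = ADAPTER_3P, umi_len: int = 4) -> str | None:
    """Extract the insert from a raw read.

    Scans 5'->3' for an exact match of the first 10 adapter bases (leftmost
    hit wins), removes the adapter and everything downstream, then removes
    ``umi_len`` bases from each end of the remainder. Returns None when no
    adapter is found or the remainder is shorter than ``2 * umi_len``.
    """
    if umi_len < 0:
        raise ValueError("umi_len must be >= 0")
    raw = normalize_sequence(raw)
    if set(raw) - VALID_BASES:
        log.warning("read with non-nucleotide characters rejected: %r", raw[:40])
        return None
    idx = raw.find(adapter3[:_ADAPTER_SEED])
    if idx < 0:
        return None
    remainder = raw[:idx]
    if len(remainder) < 2 * umi_len:
        return None
    return remainder[umi_len: len(remainder) - umi_len]


def size_filter(reads: Iterable[SmallRNARead], min_len: int = 18,
                max_len: int = 40,
                spikes: Sequence[str] = (SPIKE_19MER, SPIKE_35MER),
                stats: LibraryStats | None = None) -> list[SmallRNARead]:
    """Keep reads with min_len <= length <= max_len, dropping spike sequences."""
    spike_set = set(spikes)
    kept = []
    for read in reads:
        if read.sequence in spike_set:
            if stats is not None:
                stats.spike_reads += read.count
            continue
        if min_len <= read.length <= max_len:
            kept.append(read)
    return kept


def _matches_within(read_seq: str, target: str, max_mismatch: int) -> bool:
    """True if read_seq aligns inside target with <= max_mismatch mismatches."""
    L = len(read_seq)
    if L > len(target):
        return False
    read_arr = np.frombuffer(read_seq.encode(), dtype=np.uint8)
    tgt = np.frombuffer(target.encode(), dtype=np.uint8)
    windows = sliding_window_view(tgt, L)
    return bool((windows != read_arr).sum(axis=1).min() <= max_mismatch)


def filter_infrastructural(reads: Iterable[SmallRNARead],
                           annotation_seqs: Mapping[str, Sequence[str]],
                           max_mismatch: int = 1
                           ) -> tuple[list[SmallRNARead], LibraryStats]:
    """Remove reads matching infrastructural RNAs in either orientation.

    ``annotation_seqs`` maps a class name (e.g. ``"miRNA"``, ``"rRNA"``) to
    its sequences. The microRNA-matching read count is recorded in the
    returned :class:`LibraryStats` for normalization.
    """
    stats = LibraryStats()
    reads = list(reads)
    if not any(annotation_seqs.values()):
        log.warning("empty infrastructural annotation set; passing through")
        return reads, stats
    norm = {cls: [normalize_sequence(s) for s in seqs]
            for cls, seqs in annotation_seqs.items()}
    kept = []
    for read in reads:
        hit_class = None
        rc = revcomp(read.sequence)
        for cls, seqs in norm.items():
            for target in seqs:
                if (_matches_within(read.sequence, target, max_mismatch)
                        or _matches_within(rc, target, max_mismatch)):
                    hit_class = cls
                    break
            if hit_class:
                break
        if hit_class is None:
            kept.append(read)
        else:
            stats.removed_by_class[hit_class] = (
                stats.removed_by_class.get(hit_class, 0) + read.count)
            if hit_class.lower() in ("mirna", "microrna"):
                stats.mirna_reads += read.count
    return kept, stats


def map_reads(reads: Iterable[SmallRNARead], references: Mapping[str, str],
              max_mismatch: int = 1, report_mode: str = "all"
              ) -> list[AlignmentRecord]:
    """Brute-force Hamming mapper over both strands of small references.

    report_mode="all" reports every hit with <= max_mismatch mismatches;
    "best_strata" keeps only hits in the lowest observed mismatch stratum.
    ``n_hits`` (and so the 1/n_hits weight) is set per read over the whole
    reference set after stratum selection. Reads containing N are skipped.
    """
    if report_mode not in ("all", "best_strata"):
        raise ValueError(f"unknown report_mode {report_mode!r}")
    encoded = {}
    for name, seq in references.items():
        seq = normalize_sequence(seq)
        if set(seq) - VALID_BASES:
            raise ValueError(f"reference {name!r} has non-ACGTN characters")
        encoded[name] = np.frombuffer(seq.encode(), dtype=np.uint8)

    out: list[AlignmentRecord] = []
    for read in reads:
        if read.has_n:
            continue
        hits = []  # (mismatches, ref, start, strand)
        for strand, seq in (("+", read.sequence), ("-", revcomp(read.sequence))):
            arr = np.frombuffer(seq.encode(), dtype=np.uint8)
            for name, ref in encoded.items():
                if len(arr) > len(ref):
                    continue
                mm = (sliding_window_view(ref, len(arr)) != arr).sum(axis=1)
                for pos in np.nonzero(mm <= max_mismatch)[0]:
                    hits.append((int(mm[pos]), name, int(pos), strand))
        if not hits:
            continue
        if report_mode == "best_strata":
            best = min(h[0] for h in hits)
            hits = [h for h in hits if h[0] == best]
        n = len(hits)
        for mm_count, name, pos, strand in hits:
            out.append(AlignmentRecord(read, name, pos, pos + read.length,
                                       strand, n_hits=n, mismatches=mm_count))
    return out


def remove_trna_flanks(alignments: Iterable[AlignmentRecord],
                       trna_intervals: Iterable[tuple],
                       flank: int = 100) -> list[AlignmentRecord]:
    """Drop all instances of any read with a mapping inside a tRNA +/- flank.

    ``trna_intervals`` holds (chrom, start, end, ...) tuples in genome
    coordinates. The removal is per read: one offending instance discards
    every instance of that read.
    """
    trees: dict[str, IntervalTree] = {}
    for iv in trna_intervals:
        chrom, start, end = iv[0], iv[1], iv[2]
        trees.setdefault(chrom, IntervalTree()).addi(
            max(start - flank, 0), end + flank)
    alignments = list(alignments)
    doomed = {
        aln.read.sequence
        for aln in alignments
        if aln.reference in trees and trees[aln.reference].overlap(aln.start, aln.end)
    }
    return [aln for aln in alignments if aln.read.sequence not in doomed]


def genome_mapper_stats(alignments: Iterable[AlignmentRecord],
                        min_len: int = 1) -> LibraryStats:
    """Totals of genome-mapping reads (each distinct read counted once)."""
    total = 0.0
    unique = 0.0
    seen: set[str] = set()
    for aln in alignments:
        if aln.read.sequence in seen or aln.read.length < min_len:
            continue
        seen.add(aln.read.sequence)
        total += aln.read.count
        if aln.n_hits == 1:
            unique += aln.read.count
    return LibraryStats(total_genome_mappers=total, genome_unique_mappers=unique)
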