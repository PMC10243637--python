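"""Readers/writers for collapsed FASTA, FASTQ, plain FASTA and alignment BED."""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable, Mapping

from Bio import SeqIO

from .core import AlignmentRecord, SmallRNARead, normalize_sequence

log = logging.getLogger(__name__)


def read_fastq(path, min_mean_quality: float = 20.0) -> list[str]:
    """Raw sequences from FASTQ, dropping reads below a mean Phred threshold."""
    out = []
    for rec in SeqIO.parse(str(path), "fastq"):
        quals = rec.letter_annotations.get("phred_quality")
        if quals and sum(quals) / len(quals) < min_mean_quality:
            continue
        out.append(normalize_sequence(str(rec.seq)))
    return out


def collapse(sequences: Iterable[str]) -> list[SmallRNARead]:
    """Collapse identical sequences into reads with multiplicities."""
    counts: dict[str, int] = {}
    for seq in sequences:
        counts[seq] = counts.get(seq, 0) + 1
    return [SmallRNARead(s, c) for s, c in sorted(counts.items())]


def read_collapsed_fasta(path) -> list[SmallRNARead]:
    """Collapsed FASTA with ``>id_count`` headers."""
    reads = []
    for rec in SeqIO.parse(str(path), "fasta"):
        try:
            count = int(rec.id.rsplit("_", 1)[1])
        except (IndexError, ValueError):
            log.warning("header %r has no _count suffix; assuming count 1", rec.id)
            count = 1
        reads.append(SmallRNARead(normalize_sequence(str(rec.seq)), count))
    return reads


def write_collapsed_fasta(reads: Iterable[SmallRNARead], path) -> None:
    with open(path, "w") as fh:
        for i, read in enumerate(reads):
            fh.write(f">r{i}_{read.count}\n{read.sequence}\n")


def read_fasta(path) -> dict[str, str]:
    return {rec.id: normalize_sequence(str(rec.seq))
            for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(sequences: Mapping[str, str], path) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n{seq}\n")


def write_bed_alignments(alignments: Iterable[AlignmentRecord], path) -> None:
    """6-column BED: chrom, start, end, SEQ:COUNT, n_hits, strand."""
    with open(path, "w") as fh:
        for aln in alignments:
            name = f"{aln.read.sequence}:{aln.read.count}"
            fh.write(f"{aln.reference}\t{aln.start}\t{aln.end}\t{name}\t"
                     f"{aln.n_hits}\t{aln.strand}\n")


def read_bed_alignments(path) -> list[AlignmentRecord]:
    """Parse the BED written by :func:`write_bed_alignments`.

    The name column carries ``SEQ:COUNT`` so the BED is self-contained; a bare
    name is accepted with count 1 and a placeholder sequence of matching span.
    """
    out = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track")):
                continue
            chrom, start, end, name, score, strand = line.split()[:6]
            start, end = int(start), int(end)
            if ":" in name:
                seq, count = name.rsplit(":", 1)
                read = SmallRNARead(seq, int(count))
            else:
                read = SmallRNARead("N" * (end - start), 1)
            out.append(AlignmentRecord(read, chrom, start, end, strand,
                                       n_hits=max(int(score), 1)))
    return out


def read_bed_intervals(path) -> list[tuple]:
    """(chrom, start, end[, name[, strand]]) tuples from a BED file."""
    out = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track")):
                continue
            parts = line.split()
            chrom, start, end = parts[0], int(parts[1]), int(parts[2])
            name = parts[3] if len(parts) > 3 else "."
            strand = parts[5] if len(parts) > 5 else "."
            out.append((chrom, start, end, name, strand))
    return out


def write_bed_intervals(intervals: Iterable[tuple], path) -> None:
    with open(path, "w") as fh:
        for iv in intervals:
            chrom, start, end = iv[0], iv[1], iv[2]
            name = iv[3] if len(iv) > 3 else "."
            strand = iv[4] if len(iv) > 4 else "."
            fh.write(f"{chrom}\t{start}\t{end}\t{name}\t0\t{strand}\n")


def ensure_dir(path) -> Path:
    p = Path(path)
    p.mkdir(parents=True, exist_ok=True)
    return p
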