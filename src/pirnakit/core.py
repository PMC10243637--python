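"""Core domain types shared across the pipeline.

A small-RNA library is represented as collapsed reads (distinct sequence plus
an integer multiplicity) and mapping instances carrying fractional weights:
a read hitting the reference n times contributes 1/n per instance, so that
every mapped read distributes exactly one unit of mass over the reference set.
"""

from __future__ import annotations

from dataclasses import dataclass, field

VALID_BASES = frozenset("ACGTN")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

#: reads at least this long count as piRNAs throughout the package
PIRNA_MIN_LEN = 23


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (N maps to N)."""
    return seq.translate(_COMPLEMENT)[::-1]


def normalize_sequence(seq: str) -> str:
    """Uppercase and convert RNA U to DNA T."""
    return seq.upper().replace("U", "T")


@dataclass(frozen=True)
class SmallRNARead:
    """A trimmed, collapsed small-RNA read.

    Parameters
    ----------
    sequence
        DNA string over A/C/G/T/N. Reads containing N are retained here but
        excluded from mapping and k-mer statistics downstream.
    count
        Non-negative integer multiplicity (number of identical raw reads).
    """

    sequence: str
    count: int = 1

    def __post_init__(self) -> None:
        bad = set(self.sequence) - VALID_BASES
        if bad:
            raise ValueError(f"invalid bases in read: {sorted(bad)}")
        if self.count < 0:
            raise ValueError("read count must be non-negative")

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def length(self) -> int:
        return len(self.sequence)

    @property
    def has_n(self) -> bool:
        return "N" in self.sequence

    @property
    def is_pirna(self) -> bool:
        """piRNA definition: mapped reads >= 23 nt."""
        return len(self.sequence) >= PIRNA_MIN_LEN


@dataclass(frozen=True)
class AlignmentRecord:
    """One mapping instance of a read on a reference.

    Coordinates are 0-based half-open on the forward strand of the reference;
    ``n_hits`` is the number of mapping events of this read over the whole
    reference set, so ``weight == 1 / n_hits`` and the weights of all
    instances of one read sum to 1.
    """

    read: SmallRNARead
    reference: str
    start: int
    end: int
    strand: str
    n_hits: int = 1
    mismatches: int = 0

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if self.end - self.start != len(self.read.sequence):
            raise ValueError("alignment span must equal read length (no indels)")
        if self.n_hits < 1:
            raise ValueError("n_hits must be >= 1")

    @property
    def weight(self) -> float:
        return 1.0 / self.n_hits

    @property
    def five_prime(self) -> int:
        """Genomic position of the 5' end (start on +, end-1 on -)."""
        return self.start if self.strand == "+" else self.end - 1

    @property
    def three_prime(self) -> int:
        """Genomic position of the 3' end (end-1 on +, start on -)."""
        return self.end - 1 if self.strand == "+" else self.start


@dataclass
class LibraryStats:
    """Per-library normalization denominators and bookkeeping counts."""

    total_genome_mappers: float = 0.0
    genome_unique_mappers: float = 0.0
    mirna_reads: int = 0
    spike_reads: int = 0
    removed_by_class: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.genome_unique_mappers > self.total_genome_mappers:
            raise ValueError("unique mappers cannot exceed total mappers")
        if min(self.total_genome_mappers, self.genome_unique_mappers,
               self.mirna_reads, self.spike_reads) < 0:
            raise ValueError("library stats must be non-negative")
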