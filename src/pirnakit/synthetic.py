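"""Synthetic genomes, annotations and piRNA pools with known ground truth.

The generator emulates the statistical structure the analyses assume:
piRNA-sized reads (23-29 nt), 5'-1U bias, ping-pong pairs with exact 10-nt
5' overlaps at a controlled fraction, phased read trails with +1 head-to-tail
spacing and a downstream-U preference, per-transposon strand bias, power-law
abundance heterogeneity, and paired ovary/embryo libraries differing by a
somatic compartment (a flamenco-like uni-strand cluster).

Phased regions are built from the reads outward: the precursor sequence is
generated together with its read layout, each junction base drawn
Bernoulli(p_u_downstream), so the realized downstream-U frequency is an
unbiased binomial draw of the configured probability. The genomic segment is
the reverse complement of the precursor when the cluster is antisense.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .core import AlignmentRecord, SmallRNARead, revcomp

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_NON_T = "ACG"


def random_dna(rng: np.random.Generator, length: int) -> str:
    return _BASES[rng.integers(0, 4, size=length)].tobytes().decode()


def random_sequences(rng: np.random.Generator, n: int, lmin: int = 23,
                     lmax: int = 29, p_first_u: float = 0.25) -> list[str]:
    """Distinct random read sequences with a controlled 1U probability.

    The first base is T with probability exactly ``p_first_u`` (else uniform
    over A/C/G); remaining bases are uniform.
    """
    lengths = rng.integers(lmin, lmax + 1, size=n)
    first_u = rng.random(n) < p_first_u
    seqs: list[str] = []
    seen: set[str] = set()
    codes = rng.integers(0, 4, size=(n, lmax))
    non_t = rng.integers(0, 3, size=n)
    for i in range(n):
        body = _BASES[codes[i, 1:lengths[i]]].tobytes().decode()
        head = "T" if first_u[i] else _NON_T[non_t[i]]
        seq = head + body
        while seq in seen:  # collisions are vanishingly rare at 23+ nt
            seq = head + random_dna(rng, lengths[i] - 1)
        seen.add(seq)
        seqs.append(seq)
    return seqs


def powerlaw_counts(rng: np.random.Generator, n: int, total: int,
                    exponent: float = 1.5, max_cpm: float = 500.0
                    ) -> np.ndarray:
    """Integer abundances with a Pareto tail, clipped at ``max_cpm``.

    Counts follow P(C > x) ~ x**(-exponent), scaled to sum roughly to
    ``total``; with the defaults, species at >= 100 CPM carry on the order of
    10% of the pool mass.
    """
    if n == 0:
        return np.zeros(0, dtype=np.int64)
    raw = rng.random(n) ** (-1.0 / exponent)
    cap = max_cpm * 1e-6 * total
    for _ in range(3):
        raw = raw * (total / raw.sum())
        raw = np.minimum(raw, cap)
    counts = np.maximum(np.round(raw).astype(np.int64), 1)
    # distribute any deficit left by clipping/rounding (dense pools whose
    # per-species mean exceeds the cap are topped up evenly)
    deficit = int(total - counts.sum())
    if deficit > 0:
        counts += deficit // n
        counts[:deficit % n] += 1
    return counts


def random_pool(rng: np.random.Generator, n_species: int,
                total: int | None = None, exponent: float = 1.5,
                max_cpm: float = 500.0, p_first_u: float = 0.25,
                lmin: int = 23, lmax: int = 29) -> list[SmallRNARead]:
    """A random piRNA pool with no engineered complementarity.

    With ``total=None`` every species has count 1 (a pool of distinct
    reads); otherwise abundances are power-law with the given tail.
    """
    seqs = random_sequences(rng, n_species, lmin, lmax, p_first_u)
    if total is None:
        return [SmallRNARead(s, 1) for s in seqs]
    counts = powerlaw_counts(rng, n_species, total, exponent, max_cpm)
    return [SmallRNARead(s, int(c)) for s, c in zip(seqs, counts)]


# ---------------------------------------------------------------------------
# phased trails

def phased_precursor(rng: np.random.Generator, n_reads: int,
                     p_u: float = 0.7, p_first_u: float = 0.75,
                     lmin: int = 23, lmax: int = 29
                     ) -> tuple[str, list[tuple[int, int]]]:
    """One phased trail: head-to-tail reads plus a terminal downstream base.

    Returns the precursor sequence (5'->3') and (start, length) intervals.
    Each read's first base doubles as the previous read's +1 downstream base
    and is T with probability ``p_u`` (``p_first_u`` for the trail head); a
    terminal base extends the precursor so the last read also has a +1 base.
    """
    chars: list[str] = []
    intervals: list[tuple[int, int]] = []
    pos = 0
    for i in range(n_reads):
        length = int(rng.integers(lmin, lmax + 1))
        p = p_first_u if i == 0 else p_u
        head = "T" if rng.random() < p else _NON_T[rng.integers(0, 3)]
        chars.append(head + random_dna(rng, length - 1))
        intervals.append((pos, length))
        pos += length
    chars.append("T" if rng.random() < p_u else _NON_T[rng.integers(0, 3)])
    return "".join(chars), intervals


def _phased_segment(rng: np.random.Generator, length: int, p_u: float,
                    p_first_u: float, lmin: int, lmax: int,
                    trail_len: int = 8) -> tuple[str, list[tuple[int, int]]]:
    """Tile a segment of exactly ``length`` bases with phased trails.

    Only reads whose +1 downstream base falls inside the segment are kept;
    the remainder is padded with random sequence.
    """
    parts: list[str] = []
    intervals: list[tuple[int, int]] = []
    pos = 0
    while pos < length:
        seq, ivs = phased_precursor(rng, trail_len, p_u, p_first_u, lmin, lmax)
        for s, l in ivs:
            if pos + s + l < length:
                intervals.append((pos + s, l))
        parts.append(seq)
        pos += len(seq)
    segment = "".join(parts)[:length]
    return segment, intervals


def phased_te_pool(rng: np.random.Generator, n_reads: int, p_u: float = 0.7,
                   p_first_u: float = 0.75, lmin: int = 23, lmax: int = 29,
                   trail_len: int = 8, sense_background: int = 0
                   ) -> tuple[str, list[AlignmentRecord]]:
    """An antisense phased pool on a transposon consensus.

    The consensus is the reverse complement of the simulated precursor, so
    trail reads map antisense with exact +1 3'-5' spacing and the configured
    downstream-U probability. ``sense_background`` adds that many random
    sense reads (needed to score the null ping-pong statistic).
    """
    parts: list[str] = []
    read_ivs: list[tuple[int, int]] = []
    pos = 0
    made = 0
    while made < n_reads:
        k = min(trail_len, n_reads - made)
        seq, ivs = phased_precursor(rng, k, p_u, p_first_u, lmin, lmax)
        read_ivs.extend((pos + s, l) for s, l in ivs)
        parts.append(seq)
        pos += len(seq)
        made += k
    precursor = "".join(parts)
    te = revcomp(precursor)
    L = len(te)
    alignments = []
    for s, l in read_ivs:
        start, end = L - s - l, L - s
        seq = precursor[s:s + l]
        alignments.append(AlignmentRecord(SmallRNARead(seq, 1), "te",
                                          start, end, "-"))
    for _ in range(sense_background):
        l = int(rng.integers(lmin, lmax + 1))
        start = int(rng.integers(0, L - l))
        alignments.append(AlignmentRecord(SmallRNARead(te[start:start + l], 1),
                                          "te", start, start + l, "+"))
    return te, alignments


def pingpong_te_pool(rng: np.random.Generator, te_seq: str, n_pairs: int,
                     lmin: int = 23, lmax: int = 29,
                     pair_count: int = 1) -> list[AlignmentRecord]:
    """Sense/antisense pairs with exact 10-nt 5' overlaps on a consensus."""
    L = len(te_seq)
    alignments = []
    for _ in range(n_pairs):
        l1, l2 = (int(x) for x in rng.integers(lmin, lmax + 1, size=2))
        p = int(rng.integers(max(l2 - 10, 0) + 1, L - l1))
        sense_seq = te_seq[p:p + l1]
        anti_start, anti_end = p + 10 - l2, p + 10
        anti_seq = revcomp(te_seq[anti_start:anti_end])
        alignments.append(AlignmentRecord(SmallRNARead(sense_seq, pair_count),
                                          "te", p, p + l1, "+"))
        alignments.append(AlignmentRecord(SmallRNARead(anti_seq, pair_count),
                                          "te", anti_start, anti_end, "-"))
    return alignments


def random_te_pool(rng: np.random.Generator, te_seq: str, n_reads: int,
                   antisense_fraction: float = 0.5, lmin: int = 23,
                   lmax: int = 29) -> list[AlignmentRecord]:
    """Reads at uniform positions with a configured antisense fraction."""
    L = len(te_seq)
    alignments = []
    for anti in rng.random(n_reads) < antisense_fraction:
        l = int(rng.integers(lmin, lmax + 1))
        start = int(rng.integers(0, L - l))
        seq = te_seq[start:start + l]
        if anti:
            alignments.append(AlignmentRecord(SmallRNARead(revcomp(seq), 1),
                                              "te", start, start + l, "-"))
        else:
            alignments.append(AlignmentRecord(SmallRNARead(seq, 1),
                                              "te", start, start + l, "+"))
    return alignments


# ---------------------------------------------------------------------------
# whole-genome simulation

@dataclass
class SimulationConfig:
    """Study conditions for the synthetic genome and libraries."""

    seed: int = 0
    contig_length: int = 200_000
    cluster_length: int = 20_000
    te_count: int = 4
    te_length: int = 1500
    total_counts: int = 200_000
    somatic_fraction: float = 0.3
    pingpong_fraction: float = 0.0
    p_u_downstream: float = 0.7
    p_first_u: float = 0.75
    abundance_exponent: float = 1.5
    max_cpm: float = 500.0
    pair_cpm: float = 100.0
    pair_spacing: int = 40
    read_len_min: int = 23
    read_len_max: int = 29
    embryo_depth_factor: float = 1.0

    def __post_init__(self) -> None:
        for name in ("somatic_fraction", "pingpong_fraction",
                     "p_u_downstream", "p_first_u"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.somatic_fraction + (1 - self.somatic_fraction) * \
                self.pingpong_fraction > 1:
            raise ValueError("infeasible fraction combination")
        if 2 * self.cluster_length + 10_000 > self.contig_length:
            raise ValueError("clusters do not fit in the contig")
        if not 18 <= self.read_len_min <= self.read_len_max <= 40:
            raise ValueError("read length bounds out of range")


@dataclass
class SyntheticGenome:
    contigs: dict[str, str]
    te_consensus: dict[str, str]
    annotations: dict[str, list[tuple]]
    uni_cluster: tuple[str, int, int]
    dual_cluster: tuple[str, int, int]
    uni_reads: list[tuple[int, int]] = field(repr=False, default_factory=list)
    dual_reads: list[tuple[int, int, str]] = field(repr=False,
                                                   default_factory=list)
    pair_loci: list[int] = field(repr=False, default_factory=list)


def make_genome(config: SimulationConfig) -> SyntheticGenome:
    """Random contig with a uni-strand (somatic) and a dual-strand cluster.

    The uni-strand cluster is built from antisense phased precursors
    (flamenco-like); the dual-strand cluster holds sense and antisense trail
    segments plus a grid of candidate ping-pong pair loci. Gypsy, exon and
    tRNA annotation intervals are emitted consistently with the coordinates.
    """
    rng = np.random.default_rng(config.seed)
    c = config
    chrom = "chr1"
    Lc = c.cluster_length
    uni_start = 20_000
    dual_start = uni_start + Lc + 30_000
    if dual_start + Lc > c.contig_length:
        raise ValueError("cluster insertions exceed contig length")

    pre = random_dna(rng, uni_start)
    uni_seg_pre, uni_ivs = _phased_segment(
        rng, Lc, c.p_u_downstream, c.p_first_u, c.read_len_min, c.read_len_max)
    uni_seg = revcomp(uni_seg_pre)
    # precursor coordinate q -> genomic uni_start + Lc - 1 - q
    uni_reads = [(uni_start + Lc - s - l, uni_start + Lc - s)
                 for s, l in uni_ivs]

    mid = random_dna(rng, dual_start - (uni_start + Lc))
    half = int(0.4 * Lc)
    sense_seg, sense_ivs = _phased_segment(
        rng, half, c.p_u_downstream, c.p_first_u, c.read_len_min, c.read_len_max)
    anti_seg_pre, anti_ivs = _phased_segment(
        rng, half, c.p_u_downstream, c.p_first_u, c.read_len_min, c.read_len_max)
    anti_seg = revcomp(anti_seg_pre)
    pair_len = Lc - 2 * half
    pair_seg = random_dna(rng, pair_len)
    dual_reads = [(dual_start + s, dual_start + s + l, "+")
                  for s, l in sense_ivs]
    anti_base = dual_start + half
    dual_reads += [(anti_base + half - s - l, anti_base + half - s, "-")
                   for s, l in anti_ivs]
    pair_base = dual_start + 2 * half
    margin = c.read_len_max + 1
    pair_loci = list(range(pair_base + margin,
                           pair_base + pair_len - margin, c.pair_spacing))

    tail = random_dna(rng, c.contig_length - (dual_start + Lc))
    contig = pre + uni_seg + mid + sense_seg + anti_seg + pair_seg + tail
    assert len(contig) == c.contig_length

    te_consensus = {f"te{i}": random_dna(rng, c.te_length)
                    for i in range(c.te_count)}

    clusters = [(chrom, uni_start, uni_start + Lc, "uni_cluster", "-"),
                (chrom, dual_start, dual_start + Lc, "dual_cluster", ".")]
    gypsy = []
    for i in range(3):  # antisense insertions inside the uni-strand cluster
        s = uni_start + int(rng.integers(0, Lc - 2000))
        gypsy.append((chrom, s, s + 1500, f"gypsy{i}", "-"))
    gs = int(rng.integers(dual_start + Lc + 5000, c.contig_length - 4000))
    gypsy.append((chrom, gs, gs + 1500, "gypsy_s", "+"))
    exons = [(chrom, 2000, 3200, "exon1", "+"),
             (chrom, 5000, 6500, "exon2", "-")]
    trna = [(chrom, 9000, 9072, "trna1", "+"),
            (chrom, 12_000, 12_072, "trna2", "-")]
    annotations = {"cluster": clusters, "gypsy": gypsy,
                   "exon": exons, "trna": trna}
    return SyntheticGenome(
        contigs={chrom: contig}, te_consensus=te_consensus,
        annotations=annotations,
        uni_cluster=(chrom, uni_start, uni_start + Lc),
        dual_cluster=(chrom, dual_start, dual_start + Lc),
        uni_reads=uni_reads, dual_reads=dual_reads, pair_loci=pair_loci)


@dataclass
class Pool:
    """A simulated library: alignments plus per-read truth labels."""

    alignments: list[AlignmentRecord]
    truth: pd.DataFrame

    @property
    def reads(self) -> list[SmallRNARead]:
        counts: dict[str, int] = {}
        for aln in self.alignments:
            counts[aln.read.sequence] = (counts.get(aln.read.sequence, 0)
                                         + aln.read.count)
        return [SmallRNARead(s, n) for s, n in sorted(counts.items())]

    @property
    def total_counts(self) -> int:
        return sum(a.read.count for a in self.alignments)


def _read_seq(contig: str, start: int, end: int, strand: str) -> str:
    seq = contig[start:end]
    return seq if strand == "+" else revcomp(seq)


def simulate_pool(config: SimulationConfig, genome: SyntheticGenome,
                  rng: np.random.Generator | None = None) -> Pool:
    """Draw the ovarian read pool from the genome's planted layout.

    Somatic mass (``somatic_fraction`` of the total) goes to the uni-strand
    cluster's phased reads; the germline remainder is split between
    ping-pong pair loci (``pingpong_fraction`` of germline counts, members at
    ``pair_cpm``) and the dual-strand cluster's trail reads, both with
    power-law abundances for the trails.
    """
    c = config
    if rng is None:
        rng = np.random.default_rng(c.seed + 1)
    chrom, contig = next(iter(genome.contigs.items()))
    rows = []

    soma_total = int(round(c.somatic_fraction * c.total_counts))
    germ_total = c.total_counts - soma_total
    if soma_total > 0 and genome.uni_reads:
        counts = powerlaw_counts(rng, len(genome.uni_reads), soma_total,
                                 c.abundance_exponent, c.max_cpm)
        for (s, e), n in zip(genome.uni_reads, counts):
            rows.append((s, e, "-", int(n), "soma", "phased"))

    pair_mass = 0
    if c.pingpong_fraction > 0:
        member = max(int(round(c.pair_cpm * 1e-6 * c.total_counts)), 1)
        n_pairs = int(round(c.pingpong_fraction * germ_total / (2 * member)))
        if n_pairs > len(genome.pair_loci):
            raise ValueError(
                f"pingpong_fraction {c.pingpong_fraction} needs {n_pairs} "
                f"pair loci but the genome provides {len(genome.pair_loci)}; "
                "increase cluster_length or lower the fraction")
        loci = rng.choice(len(genome.pair_loci), size=n_pairs, replace=False)
        for i in loci:
            p = genome.pair_loci[int(i)]
            l1, l2 = (int(x) for x in
                      rng.integers(c.read_len_min, c.read_len_max + 1, size=2))
            rows.append((p, p + l1, "+", member, "germline", "pair"))
            rows.append((p + 10 - l2, p + 10, "-", member, "germline", "pair"))
        pair_mass = 2 * member * n_pairs

    trail_total = germ_total - pair_mass
    if trail_total > 0 and genome.dual_reads:
        counts = powerlaw_counts(rng, len(genome.dual_reads), trail_total,
                                 c.abundance_exponent, c.max_cpm)
        for (s, e, strand), n in zip(genome.dual_reads, counts):
            rows.append((s, e, strand, int(n), "germline", "phased"))

    alignments = []
    truth_rows = []
    for start, end, strand, count, compartment, kind in rows:
        seq = _read_seq(contig, start, end, strand)
        if "N" in seq:
            continue
        alignments.append(AlignmentRecord(SmallRNARead(seq, count), chrom,
                                          start, end, strand))
        truth_rows.append({"chrom": chrom, "start": start, "end": end,
                           "strand": strand, "count": count,
                           "compartment": compartment, "kind": kind,
                           "sequence": seq})
    return Pool(alignments, pd.DataFrame(truth_rows))


def make_library_pair(config: SimulationConfig, genome: SyntheticGenome
                      ) -> tuple[Pool, Pool]:
    """Matched ovary and embryo libraries.

    The ovary holds somatic plus germline compartments; the embryo resamples
    the germline compartment alone with Poisson counting noise, emulating a
    0-2 h embryo pool devoid of somatic material.
    """
    rng = np.random.default_rng(config.seed + 2)
    ovary = simulate_pool(config, genome, rng)
    germ = ovary.truth[ovary.truth["compartment"] == "germline"]
    alignments = []
    truth_rows = []
    for row in germ.itertuples():
        n = int(rng.poisson(row.count * config.embryo_depth_factor))
        if n == 0:
            continue
        alignments.append(AlignmentRecord(SmallRNARead(row.sequence, n),
                                          row.chrom, row.start, row.end,
                                          row.strand))
        truth_rows.append({"chrom": row.chrom, "start": row.start,
                           "end": row.end, "strand": row.strand, "count": n,
                           "compartment": "germline", "kind": row.kind,
                           "sequence": row.sequence})
    embryo = Pool(alignments, pd.DataFrame(truth_rows))
    return ovary, embryo
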