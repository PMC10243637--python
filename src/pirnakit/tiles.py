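"""Genomic tile quantification of somatic vs germline piRNA sources.

Two tilings are used: 0.5 kb tiles restricted to uniquely mappable regions
(>= 85% of positions covered by 25mers occurring once in the genome) carry
genome-unique piRNA counts for scatter-style comparisons, and 0.2 kb tiles
carry multimapper-weighted counts to quantify soma-enriched piRNAs. A tile is
"somatic" when its ovarian piRNA output exceeds its embryonic output more
than 10-fold (the embryo contains germline material only). Somatic tiles are
annotated by covering intervals with the priority piRNA cluster >
gypsy antisense/sense > mRNA exon.
"""

from __future__ import annotations

from collections import Counter
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .core import AlignmentRecord, PIRNA_MIN_LEN, revcomp

ANNOTATION_PRIORITY = ("piRNA_cluster", "gypsy_antisense", "gypsy_sense",
                       "mRNA_exon", "other")


def make_tiles(contig_lengths: Mapping[str, int], width: int = 500) -> pd.DataFrame:
    """Partition contigs into fixed-width tiles.

    The last partial tile of a contig is kept when it is at least half the
    width, otherwise dropped. Tiles are disjoint and (up to the dropped
    remainder) exhaustive.
    """
    rows = []
    for chrom, length in contig_lengths.items():
        for start in range(0, length, width):
            end = min(start + width, length)
            if end - start < width and end - start < width / 2:
                continue
            rows.append({"chrom": chrom, "start": start, "end": end})
    return pd.DataFrame(rows, columns=["chrom", "start", "end"])


def unique_position_mask(genome: Mapping[str, str], kmer: int = 25
                         ) -> dict[str, np.ndarray]:
    """Per-contig boolean mask of positions covered by unique 25mers.

    A k-mer start is unique iff the k-mer occurs exactly once in the genome,
    counting an occurrence of its reverse complement as a second occurrence
    (palindromic k-mers are therefore never unique). A position is covered
    when at least one unique k-mer overlaps it.
    """
    counts: Counter[str] = Counter()
    for seq in genome.values():
        for i in range(len(seq) - kmer + 1):
            counts[seq[i:i + kmer]] += 1
    masks = {}
    for chrom, seq in genome.items():
        n = len(seq)
        cover = np.zeros(n + 1, dtype=np.int64)
        for i in range(n - kmer + 1):
            km = seq[i:i + kmer]
            if counts[km] + counts.get(revcomp(km), 0) == 1:
                cover[i] += 1
                cover[i + kmer] -= 1
        masks[chrom] = np.cumsum(cover[:-1]) > 0
    return masks


def compute_mappable_tiles(genome: Mapping[str, str], tile_width: int = 500,
                           kmer: int = 25, min_frac: float = 0.85
                           ) -> pd.DataFrame:
    """Tiles with their unique-mappability fraction and a pass flag.

    Contigs shorter than the k-mer get zero mappability.
    """
    tiles = make_tiles({c: len(s) for c, s in genome.items()}, tile_width)
    masks = unique_position_mask(genome, kmer)
    fracs = []
    for row in tiles.itertuples():
        mask = masks[row.chrom][row.start:row.end]
        fracs.append(float(mask.mean()) if len(mask) else 0.0)
    tiles["mappability"] = fracs
    tiles["mappable"] = tiles["mappability"] >= min_frac
    return tiles


def _assign_mass(alignments: Iterable[AlignmentRecord], tiles: pd.DataFrame,
                 unique_only: bool, min_len: int) -> np.ndarray:
    """Weighted 5'-end mass per tile (single-tile assignment by 5' position)."""
    starts: dict[str, np.ndarray] = {}
    index: dict[str, np.ndarray] = {}
    for chrom, sub in tiles.groupby("chrom", sort=False):
        starts[chrom] = sub["start"].to_numpy()
        index[chrom] = sub.index.to_numpy()
    mass = np.zeros(len(tiles))
    for aln in alignments:
        if aln.read.length < min_len:
            continue
        if unique_only and aln.n_hits != 1:
            continue
        if aln.reference not in starts:
            continue
        pos = aln.five_prime
        s = starts[aln.reference]
        i = np.searchsorted(s, pos, side="right") - 1
        if i < 0:
            continue
        row = index[aln.reference][i]
        if pos >= tiles.at[row, "end"]:
            continue
        w = aln.read.count * (1.0 if unique_only else aln.weight)
        mass[row] += w
    return mass


def _pirna_denominator(alignments: Iterable[AlignmentRecord],
                       unique_only: bool, min_len: int) -> float:
    seen: set[str] = set()
    total = 0.0
    for aln in alignments:
        if aln.read.length < min_len or aln.read.sequence in seen:
            continue
        if unique_only and aln.n_hits != 1:
            continue
        seen.add(aln.read.sequence)
        total += aln.read.count
    return total


def count_unique_tiles(alignments: Sequence[AlignmentRecord],
                       tiles: pd.DataFrame,
                       denominator: float | None = None,
                       min_len: int = PIRNA_MIN_LEN) -> np.ndarray:
    """Genome-unique piRNA counts per tile, per million unique piRNA mappers.

    Reads are assigned to the single tile containing their 5' end.
    """
    mass = _assign_mass(alignments, tiles, unique_only=True, min_len=min_len)
    if denominator is None:
        denominator = _pirna_denominator(alignments, True, min_len)
    return mass * (1e6 / denominator) if denominator else mass


def count_all_mapper_tiles(alignments: Sequence[AlignmentRecord],
                           tiles: pd.DataFrame,
                           denominator: float | None = None,
                           min_len: int = PIRNA_MIN_LEN) -> np.ndarray:
    """Multimapper-weighted piRNA counts per tile, per million piRNA mappers.

    Each mapping instance contributes count/n_hits, distributing multimappers
    evenly across their repeats.
    """
    mass = _assign_mass(alignments, tiles, unique_only=False, min_len=min_len)
    if denominator is None:
        denominator = _pirna_denominator(alignments, False, min_len)
    return mass * (1e6 / denominator) if denominator else mass


def classify_somatic(ovary_counts: np.ndarray, embryo_counts: np.ndarray,
                     fold: float = 10.0, pseudocount: float = 0.1) -> np.ndarray:
    """Somatic flag: ovarian output exceeds fold x (embryonic + pseudocount)."""
    ovary = np.asarray(ovary_counts, dtype=float)
    embryo = np.asarray(embryo_counts, dtype=float)
    return ovary > fold * (embryo + pseudocount)


def _coverage_fraction(tiles: pd.DataFrame, intervals: Sequence[tuple]
                       ) -> np.ndarray:
    """Fraction of each tile covered by the (merged) intervals."""
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for iv in intervals:
        by_chrom.setdefault(iv[0], []).append((int(iv[1]), int(iv[2])))
    merged: dict[str, list[tuple[int, int]]] = {}
    for chrom, ivs in by_chrom.items():
        ivs.sort()
        acc = [list(ivs[0])]
        for s, e in ivs[1:]:
            if s <= acc[-1][1]:
                acc[-1][1] = max(acc[-1][1], e)
            else:
                acc.append([s, e])
        merged[chrom] = [tuple(x) for x in acc]
    fracs = np.zeros(len(tiles))
    for i, row in enumerate(tiles.itertuples()):
        cov = 0
        for s, e in merged.get(row.chrom, ()):
            cov += max(0, min(e, row.end) - max(s, row.start))
        width = row.end - row.start
        fracs[i] = cov / width if width else 0.0
    return fracs


def annotate_tiles(tiles: pd.DataFrame, cluster_intervals: Sequence[tuple],
                   gypsy_intervals: Sequence[tuple],
                   exon_intervals: Sequence[tuple],
                   min_cover: float = 0.5) -> pd.Series:
    """Assign one annotation class per tile.

    A class is eligible when its intervals cover at least ``min_cover`` of the
    tile; conflicts resolve by the priority piRNA_cluster > gypsy antisense/
    sense > mRNA_exon. Gypsy intervals carry strand in field 5 ('-' means the
    insertion is antisense to the tile's piRNA output convention); between the
    two gypsy classes the larger coverage wins, ties going to antisense.
    """
    gypsy_as = [iv for iv in gypsy_intervals if len(iv) > 4 and iv[4] == "-"]
    gypsy_s = [iv for iv in gypsy_intervals if not (len(iv) > 4 and iv[4] == "-")]
    cov = {
        "piRNA_cluster": _coverage_fraction(tiles, cluster_intervals)
        if cluster_intervals else np.zeros(len(tiles)),
        "gypsy_antisense": _coverage_fraction(tiles, gypsy_as)
        if gypsy_as else np.zeros(len(tiles)),
        "gypsy_sense": _coverage_fraction(tiles, gypsy_s)
        if gypsy_s else np.zeros(len(tiles)),
        "mRNA_exon": _coverage_fraction(tiles, exon_intervals)
        if exon_intervals else np.zeros(len(tiles)),
    }
    classes = []
    for i in range(len(tiles)):
        if cov["piRNA_cluster"][i] >= min_cover:
            classes.append("piRNA_cluster")
        elif max(cov["gypsy_antisense"][i], cov["gypsy_sense"][i]) >= min_cover:
            if cov["gypsy_sense"][i] > cov["gypsy_antisense"][i]:
                classes.append("gypsy_sense")
            else:
                classes.append("gypsy_antisense")
        elif cov["mRNA_exon"][i] >= min_cover:
            classes.append("mRNA_exon")
        else:
            classes.append("other")
    return pd.Series(classes, index=tiles.index, name="annotation")


def soma_composition(annotations: pd.Series, somatic: np.ndarray,
                     ovary_counts: np.ndarray) -> dict:
    """Breakdown of somatic piRNA mass by annotation class.

    Returns per-class shares of the somatic mass, the combined
    cluster + gypsy-antisense share, and the somatic share of the total
    ovarian piRNA output.
    """
    somatic = np.asarray(somatic, dtype=bool)
    ovary = np.asarray(ovary_counts, dtype=float)
    soma_mass = ovary[somatic].sum()
    total_mass = ovary.sum()
    shares = {}
    for cls in ANNOTATION_PRIORITY:
        mask = somatic & (annotations.to_numpy() == cls)
        shares[cls] = float(ovary[mask].sum() / soma_mass) if soma_mass else 0.0
    return {
        "class_shares": shares,
        "cluster_plus_gypsy_antisense": shares["piRNA_cluster"]
        + shares["gypsy_antisense"],
        "soma_share_of_ovary": float(soma_mass / total_mass) if total_mass else 0.0,
    }
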