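"""Tile mappability, counting, somatic classification and annotation."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pirnakit.core import AlignmentRecord, SmallRNARead, revcomp
from pirnakit.synthetic import random_dna
from pirnakit.tiles import (annotate_tiles, classify_somatic,
                            compute_mappable_tiles, count_all_mapper_tiles,
                            count_unique_tiles, make_tiles, soma_composition,
                            unique_position_mask)


def _aln(chrom, start, length=25, strand="+", count=1, n_hits=1):
    return AlignmentRecord(SmallRNARead("A" * length, count), chrom, start,
                           start + length, strand, n_hits=n_hits)


class TestMakeTiles:
    def test_partial_tile_rule(self):
        tiles = make_tiles({"a": 1300, "b": 1100}, width=500)
        # 1300 -> 500, 500, 300 (kept, >= half); 1100 -> 500, 500 (100 dropped)
        assert len(tiles[tiles.chrom == "a"]) == 3
        assert len(tiles[tiles.chrom == "b"]) == 2
        assert tiles[tiles.chrom == "a"].iloc[-1].end == 1300

    def test_tiles_disjoint_and_ordered(self):
        tiles = make_tiles({"a": 2600}, width=200)
        assert (tiles.end - tiles.start > 0).all()
        assert (tiles.start.values[1:] >= tiles.end.values[:-1]).all()


def brute_force_unique_mask(genome, kmer=25):
    """Per-position unique coverage by direct string scanning."""
    catalogue = []
    for seq in genome.values():
        catalogue.append(seq)
        catalogue.append(revcomp(seq))
    def occurrences(km):
        n = 0
        for seq in catalogue:
            start = 0
            while True:
                i = seq.find(km, start)
                if i < 0:
                    break
                n += 1
                start = i + 1
        return n
    masks = {}
    for chrom, seq in genome.items():
        mask = np.zeros(len(seq), dtype=bool)
        for i in range(len(seq) - kmer + 1):
            if occurrences(seq[i:i + kmer]) == 1:
                mask[i:i + kmer] = True
        masks[chrom] = mask
    return masks


class TestMappability:
    def test_unique_random_genome_all_pass(self, rng):
        genome = {"c": random_dna(rng, 3000)}
        tiles = compute_mappable_tiles(genome)
        assert tiles.mappable.all()

    def test_long_duplication_fails(self, rng):
        block = random_dna(rng, 600)
        genome = {"c": random_dna(rng, 1000) + block + block
                  + random_dna(rng, 1000)}
        tiles = compute_mappable_tiles(genome)
        dup_tiles = tiles[(tiles.start >= 1000) & (tiles.end <= 2200)]
        assert not dup_tiles.mappable.any()

    def test_matches_position_oracle(self, rng):
        block = random_dna(rng, 100)
        genome = {"c": random_dna(rng, 700) + block + random_dna(rng, 200)
                  + block + random_dna(rng, 500)}
        expected = brute_force_unique_mask(genome)
        actual = unique_position_mask(genome)
        np.testing.assert_array_equal(actual["c"], expected["c"])

    def test_short_contig_zero_mappability(self):
        tiles = compute_mappable_tiles({"tiny": "ACGTACGTACGT" * 30,
                                        "short": "ACGTACGTAC"},
                                       tile_width=10)
        assert (tiles[tiles.chrom == "short"].mappability == 0).all()


class TestTileCounting:
    TILES = make_tiles({"c": 1000}, width=200)

    def test_five_prime_assignment_across_boundary(self):
        # read spans the 200 boundary; its 5' end at 190 puts it in tile 0
        counts = count_unique_tiles([_aln("c", 190)], self.TILES,
                                    denominator=1e6)
        assert counts[0] == 1.0 and counts[1] == 0.0

    def test_minus_strand_five_prime(self):
        # minus-strand 5' end is end-1 = 214: tile 1
        counts = count_unique_tiles([_aln("c", 190, strand="-")], self.TILES,
                                    denominator=1e6)
        assert counts[0] == 0.0 and counts[1] == 1.0

    def test_multimapper_excluded_from_unique(self):
        counts = count_unique_tiles([_aln("c", 10, n_hits=3)], self.TILES,
                                    denominator=1e6)
        assert counts.sum() == 0.0

    def test_empty_library_zero(self):
        assert count_unique_tiles([], self.TILES, denominator=1e6).sum() == 0

    def test_multimapper_weights_distributed(self):
        alns = [_aln("c", p, n_hits=4) for p in (10, 210, 410, 610)]
        counts = count_all_mapper_tiles(alns, self.TILES, denominator=1e6)
        assert list(counts[:4]) == [0.25] * 4

    def test_two_instances_one_tile(self):
        alns = [_aln("c", 10, n_hits=2), _aln("c", 50, n_hits=2)]
        counts = count_all_mapper_tiles(alns, self.TILES, denominator=1e6)
        assert counts[0] == 1.0

    def test_mass_conservation(self, rng):
        reads = []
        for i in range(50):
            n_hits = int(rng.integers(1, 4))
            for _ in range(n_hits):
                reads.append(_aln("c", int(rng.integers(0, 970)),
                                  count=int(rng.integers(1, 5)), n_hits=n_hits))
        counts = count_all_mapper_tiles(reads, self.TILES, denominator=1e6)
        total_reads = sum(a.read.count * a.weight for a in reads)
        assert counts.sum() == pytest.approx(total_reads)

    def test_sub_pirna_reads_ignored(self):
        counts = count_all_mapper_tiles([_aln("c", 10, length=22)],
                                        self.TILES, denominator=1e6)
        assert counts.sum() == 0


class TestClassifySomatic:
    @pytest.mark.parametrize("ovary, embryo, expected", [
        (50.0, 4.0, True),    # 12.2x with pseudocount
        (50.0, 6.0, False),
        (1.5, 0.0, True),     # pseudocount keeps zero-embryo tiles finite
        (0.0, 0.0, False),
    ])
    def test_fold_rule(self, ovary, embryo, expected):
        assert classify_somatic(np.array([ovary]), np.array([embryo]))[0] \
            == expected

    @given(st.floats(0, 1000), st.floats(0, 1000), st.floats(0.1, 100))
    @settings(max_examples=50, deadline=None)
    def test_monotone(self, ovary, embryo, delta):
        base = classify_somatic(np.array([ovary]), np.array([embryo]))[0]
        more_ovary = classify_somatic(np.array([ovary + delta]),
                                      np.array([embryo]))[0]
        more_embryo = classify_somatic(np.array([ovary]),
                                       np.array([embryo + delta]))[0]
        assert more_ovary >= base
        assert more_embryo <= base


class TestAnnotateTiles:
    TILES = pd.DataFrame({"chrom": ["c"], "start": [0], "end": [200]})

    def test_cluster_beats_gypsy(self):
        annot = annotate_tiles(self.TILES,
                               cluster_intervals=[("c", 0, 120)],
                               gypsy_intervals=[("c", 0, 140, "g", "-")],
                               exon_intervals=[])
        assert annot[0] == "piRNA_cluster"

    def test_below_half_exon_is_other(self):
        annot = annotate_tiles(self.TILES, [], [],
                               exon_intervals=[("c", 0, 80)])
        assert annot[0] == "other"

    def test_exactly_half_gypsy_sense_inclusive(self):
        annot = annotate_tiles(self.TILES, [],
                               gypsy_intervals=[("c", 0, 100, "g", "+")],
                               exon_intervals=[])
        assert annot[0] == "gypsy_sense"

    def test_gypsy_strand_split(self):
        annot = annotate_tiles(self.TILES, [],
                               gypsy_intervals=[("c", 0, 150, "g", "-")],
                               exon_intervals=[])
        assert annot[0] == "gypsy_antisense"


class TestSomaComposition:
    def test_all_cluster(self):
        annot = pd.Series(["piRNA_cluster", "other"])
        comp = soma_composition(annot, np.array([True, False]),
                                np.array([80.0, 20.0]))
        assert comp["class_shares"]["piRNA_cluster"] == 1.0
        assert comp["soma_share_of_ovary"] == pytest.approx(0.8)

    def test_equal_split(self):
        annot = pd.Series(["piRNA_cluster", "other"])
        comp = soma_composition(annot, np.array([True, True]),
                                np.array([50.0, 50.0]))
        assert comp["class_shares"]["piRNA_cluster"] == 0.5
        assert comp["cluster_plus_gypsy_antisense"] == 0.5
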