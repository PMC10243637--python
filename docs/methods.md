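# Methods

## Read model and normalization

A library is a set of collapsed reads (distinct sequence, integer
multiplicity). Reads of 23 nt or longer count as piRNAs; 18–22 nt reads are
retained in files but excluded from every piRNA statistic. A read mapping to
`n` places contributes `1/n` per mapping instance, so multimappers distribute
exactly one unit of mass; per-reference and per-tile quantities are expressed
in counts per million genome-mapping reads (CPM), where the denominator
counts each distinct mapped read once with its multiplicity. Reads containing
N are excluded from mapping and all k-mer statistics.

Trimming inverts the cloning scheme: the 3′ adapter
(`AGATCGGAAGAGCACACGTCT`, preceded by a 4-nt UMI) is located by an exact
match of its first 10 bases scanning 5′→3′ with the leftmost hit winning;
the adapter and everything downstream are removed, then 4 bases from each
end of the remainder. Quality filtering is a mean-Phred ≥ 20 pass-through
(threshold configurable). The built-in mapper is an exhaustive
Hamming-distance search over both strands, valid for consensus sequences and
toy genomes (up to a few Mb); it supports all-hits and best-stratum
reporting. Real-genome alignments are ingested as BED/SAM produced by a
dedicated aligner.

## Linkage spectra

For a transposon end profile, the co-occurrence frequency at offset `k` is
the abundance-weighted product sum of two end vectors. Ping-pong uses the 5′
ends of sense and antisense reads with `f(k) = Σ_p s5(p)·a5(p+k−1)` over
overlaps `k = 1..20` (the linkage offset is `k = 10`); phasing uses 3′ and
5′ ends on one strand (default antisense, in the strand's own 5′→3′
orientation) over offsets `−9..+10` with linkage at `+1`.

The z-score of the linkage offset is computed against the other 19 offsets
of the window (their mean and population sd). An alternative
`sd_mode="window"` standardizes against all 20 values including the peak;
this form is algebraically bounded by `√19 ≈ 4.36` — the peak inflates its
own standard deviation — so it cannot express the very strong signatures
(z in the tens) that the background form reports. The background form is
therefore the default; the window form is kept because it is the natural
reading of "deviation from the window mean over the window sd" and is used
for hand-checkable examples. A zero-variance window reports `z = 0` with an
explicit flag rather than an infinity. Frequencies are bilinear in the end
vectors, so rescaling a library leaves every z-score unchanged.

## In-trans ping-pong statistic

Target recognition by a piRNA minimally requires complementarity of its
g2–g10 region, so a slicing-triggered responder piRNA carries, reverse
complemented at its g2–g10, the 9mer found at g1–g9 of the guide. Three
9mer categories are counted per genome-mapping piRNA (weighted by
multiplicity): `g1g9`, `last9`, `g2g10_revComp`. Each category's frequencies
are scaled to sum 1000; the per-million-genome-mappers intermediate is
exposed for inspection but cancels in the rescale. The linkage value is the
sum over 9mers of `freq_g1g9 · freq_g2g10_revComp`; the same product with
`last9` in place of `g1g9` estimates the genomic background, and the
difference estimates the percentage of reads in pairs. Estimates on null
pools may be slightly negative and are reported unclamped.

Implementation: profiles store exact integer counts and an integer total;
the linkage is an integer dot product scaled once at the end
(`10⁶·Σ cA·cB / (T_A·T_B)`), so profiles sum to 1000 exactly and the hashed
computation is bitwise equal to the brute-force all-pairs oracle.
Multimapping reads contribute once with their collapsed count; a
genome-unique mode restricts the pool to `n_hits = 1` reads, and a
cross-library mode takes `g2g10_revComp` from an IP library against `g1g9`
and `last9` of a total library.

### Spike-in calibration

The percent scale is established by injecting artificial pairs into a
simulated pool: two reads with an exact 10-nt complementary 5′ overlap, each
member at 100 CPM, added until pair reads form 0/1/3/5/10 % of the pool
(5 replicates per level), and the background-subtracted linkage regressed on
the achieved percentage. Because the 10-nt overlap makes each member's g1g9
the other's g2g10_revComp, one pair species contributes exactly
`2·(100 CPM · 10⁻³)² = 0.02` linkage units, and 1 % of a pool is 50 species
— hence the slope of one linkage unit per percentage point. Injected 9mers
are drawn to collide with no existing key so the designed signal stays
additive: the pair's shared head decamer is rejection-sampled against every
existing key, and each member's tail is resampled until its `last9` avoids
the `g2g10_revComp`-side keys (at 10⁵ species the 4⁹ key space is about
two-thirds occupied, so naive rejection over all six keys would not
terminate). Count granularity can shift the achieved percentage slightly;
the achieved value is reported and used in the regression.

The default calibration pool holds 10⁵ distinct species and 10⁶ counts with
power-law abundances (Pareto tail exponent 1.5, clipped at 500 CPM), under
which species at ≥ 100 CPM carry roughly 10–15 % of the pool mass — the
regime in which pairs at 100 CPM are representative of abundant piRNAs.

## Genomic tiles

Unique mappability marks a position when at least one 25mer overlapping it
occurs exactly once in the genome, an occurrence of the reverse complement
counting as a second occurrence (palindromic 25mers are never unique).
0.5 kb tiles qualify when ≥ 85 % of positions are unique; they carry
genome-unique piRNA counts. 0.2 kb tiles carry multimapper-weighted counts
(`count/n_hits` per instance). Reads are assigned to the single tile
containing their 5′ end — piRNA identity is defined by its 5′ end — rather
than split across overlapped tiles. The last partial tile of a contig is
kept when at least half the width. A tile is somatic when
`ovary > 10 × (embryo + 0.1)` in per-million units; the 0.1 pseudocount
keeps zero-embryo tiles finite (the same pseudocount, with a 3× fold, backs
the per-transposon soma/germline call). Annotation requires ≥ 50 % coverage
(inclusive) and resolves conflicts by the priority piRNA cluster > gypsy
antisense/sense > mRNA exon; between the two gypsy orientations the larger
coverage wins, ties going to antisense.

## Synthetic data

The generator emulates: piRNA lengths 23–29 nt, 1U bias (first base T with
an exact Bernoulli probability), phased trails (head-to-tail reads whose
junction bases are T with probability `p_u_downstream` — the junction base
is simultaneously the upstream read's +1 base and the downstream read's
first base, as one endonucleolytic cut produces both ends), ping-pong pairs
with exact 10-nt 5′ overlaps, per-transposon strand bias, power-law
abundances, and an ovary/embryo pair whose difference is a somatic
compartment confined to a flamenco-like uni-strand cluster.

Phased regions are generated reads-first: the precursor sequence is built
together with its read layout and the genomic segment is its reverse
complement. Generating reads against a fixed random reference instead would
bias the realized downstream-U frequency downward (a 23–29 nt cut window
contains no T about 13 % of the time), which would fail binomial-error
recovery of `p_u`. Consequences: the synthetic genome is locally composed of
read-derived sequence, and genome-level ping-pong pair loci live on a
dedicated random segment of the dual-strand cluster (spaced ≥ 40 nt) so pair
9mers do not systematically collide with trail 9mers.

What the generator does **not** emulate: sequence evolution of transposon
families (consensi are random sequence), mismatched mapping, true
multimapping structure (planted reads are effectively genome-unique),
transcriptional noise, and cross-contamination between compartments. Tests
passing on this surface therefore demonstrate correctness of the statistics
and their calibration, not robustness to annotation error or repeat-driven
mapping ambiguity in real genomes.

## Problem sizes and numerical choices

The test suite and the acceptance script run the calibration at its study
conditions (10⁵ species, 10⁶ counts, 5 replicates × 5 levels), null and
recovery checks on 10⁵-read pools over 10 seeds, linkage z-scores on pools
of a few hundred reads over 5 kb consensi, and tile recovery on a 200 kb
contig with a 20 kb somatic cluster at 200 bp resolution. Determinism: every
stochastic stage takes a seed or an explicit numpy Generator; identical
seeds give byte-identical outputs. Degenerate inputs: empty pools raise,
single-strand profiles raise for ping-pong, zero-variance windows are
flagged, zero denominators in ratios are guarded by the 0.1 pseudocount,
and contigs shorter than the 25mer get zero mappability.

## Known limitations

The brute-force mapper is quadratic and intended for desk-scale references
only. The in-trans estimate on small pools (≲ 10⁴ species) carries sampling
noise of a few percentage points because profile collisions in the 4⁹ key
space are Poisson-sparse; the statistic is designed for million-read
libraries. Real-data percentages from published libraries (e.g. mouse
pachytene ≥ 10 %, somatic cell lines < 1 %) require downloading those
libraries and are outside the desk-scale suite.
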