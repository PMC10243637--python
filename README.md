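# pirnakit

Analysis toolkit for PIWI-interacting RNA (piRNA) biogenesis signatures in
small-RNA sequencing data, built around the question of how transposon
antisense piRNAs are produced: by the slicer-driven **ping-pong** cycle, by
Zucchini-mediated **phasing**, or by slicing-triggered phasing acting between
loci (**in-trans ping-pong**).

It is aimed at researchers analysing ovarian, embryonic or IP small-RNA
libraries from *Drosophila* (or mouse germ cells) who want the standard
battery of piRNA diagnostics plus a genome-wide statistic for
slicing-triggered biogenesis — and at method developers, since every stage
comes with a synthetic-data generator so the whole pipeline is testable
without downloading any real library.

## What it computes

* **Preprocessing** — adapter/UMI trimming of raw reads, 18–40 nt size
  selection, spike removal, infrastructural-RNA filtering (with the miRNA
  count kept as a normalization denominator), tRNA-flank removal, and a
  brute-force Hamming mapper for toy references (real genomes are ingested as
  externally produced SAM/BED). Multimapping instances carry weight
  `1/n_hits`, so each read distributes one unit of mass.
* **Transposon profiles** — per-consensus 5′/3′ end coverage of piRNAs
  (≥ 23 nt) in counts per million genome mappers (CPM), antisense strand
  bias, per-length 1U fractions, nonredundant transposon selection and
  soma/germline compartment calls.
* **Linkage z-scores** — the ping-pong signature (sense/antisense 5′ ends
  overlapping by exactly 10 nt) and the phasing signature (3′→5′ distance of
  +1 on the same strand, with downstream-U preference), each scored as an
  abundance-weighted co-occurrence spectrum over a window of 20 offsets:

      f(k)    = Σ_p  end₁(p) · end₂(p + k)
      z(link) = ( f(link) − mean(f_background) ) / sd(f_background)

* **In-trans ping-pong** — from every genome-mapping piRNA, three 9mers are
  extracted: `g1g9` (bases 1–9), `last9` (3′-most 9 bases) and
  `g2g10_revComp` (reverse complement of bases 2–10). Each category becomes a
  frequency profile scaled to sum 1000, and

      linkage    = Σ_s freq_g1g9(s) · freq_g2g10_revComp(s)
      background = Σ_s freq_last9(s) · freq_g2g10_revComp(s)
      % pairs    ≈ linkage − background

  The percent interpretation rests on a spike-in calibration: injecting
  artificial ping-pong pairs (10-nt complementary 5′ overlaps, members at
  100 CPM) raises the background-subtracted linkage by one unit per 1 % of
  pair reads.
* **Genomic tiles** — 25mer unique-mappability, 0.5 kb unique-mapper tiles
  and 0.2 kb multimapper-weighted tiles, somatic tile calls (ovary > 10×
  embryo), annotation by priority piRNA cluster > gypsy antisense/sense >
  mRNA exon, and the somatic piRNA composition breakdown.
* **Synthetic data** — genomes with flamenco-like uni-strand and germline
  dual-strand clusters, phased read trails with exact head-to-tail spacing
  and Bernoulli downstream-U, engineered ping-pong pairs, power-law
  abundances, and matched ovary/embryo library pairs with truth labels.

## Worked example

```python
import numpy as np
from pirnakit import estimate_pair_percent
from pirnakit.intrans import inject_pairs
from pirnakit.synthetic import random_pool

rng = np.random.default_rng(1)
base = random_pool(rng, 100_000, total=1_000_000)   # 1e6-count random pool
spiked, achieved = inject_pairs(base, 5.0, rng)     # 5% engineered pairs
res = estimate_pair_percent(spiked)
print(achieved, res.foreground, res.background, res.estimated_percent)
```

prints (rounded)

```
5.003  8.441  3.584  4.857
```

i.e. the spiked pool truly contains 5.003 % pair reads; the foreground
sum-product is 8.44 linkage units of which 3.58 units are the genomic
background shared with the `last9` control, leaving an estimate of 4.86 % —
the engineered fraction recovered within sampling error. The same call on
the unspiked pool returns −0.19 %, a null pool's sampling noise around zero.

The same analyses are scriptable from the shell:

```bash
pirnakit simulate  --seed 1 --out sim/
pirnakit intrans   --reads sim/ovary.fa --out intrans/
pirnakit tiles     --genome sim/genome.fa --ovary-bed sim/ovary.bed \
                   --embryo-bed sim/embryo.bed --clusters sim/cluster.bed \
                   --gypsy sim/gypsy.bed --exons sim/exon.bed --out tiles/
pirnakit calibrate --seed 1 --out cal/
pirnakit report    --inputs tiles/ --inputs cal/ --out report/
```

On the default simulation (30 % somatic compartment confined to the
uni-strand cluster) the tile stage reports a somatic share of ovarian piRNAs
of 0.30 with the somatic mass entirely in piRNA-cluster tiles.

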