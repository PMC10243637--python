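"""Ping-pong and phasing linkage spectra with window-of-20 z-scores.

Ping-pong amplification leaves sense/antisense piRNA pairs whose 5' ends
overlap by exactly 10 nt; phased (Zucchini) biogenesis leaves consecutive
same-strand piRNAs whose 3' and 5' ends sit 1 nt apart, with a uridine
immediately downstream of each 3' end. Both signatures are scored as
abundance-weighted co-occurrence frequencies of end positions over a window
of 20 offsets containing the linkage offset, summarized as a z-score at the
linkage offset.

Two standardizations are provided. ``sd_mode="background"`` (default)
compares the linkage-offset frequency against the mean and population sd of
the 19 other offsets; this is the scale on which strong signals reach
z-scores in the tens. ``sd_mode="window"`` standardizes against all 20
values including the linkage offset; it is the literal window statistic but
is bounded above by sqrt(19) ~= 4.36, because the peak inflates its own sd.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .core import AlignmentRecord, PIRNA_MIN_LEN
from .te_profiles import EndProfile

PINGPONG_OFFSETS = tuple(range(1, 21))   # 5'-5' overlaps, linkage at +10
PHASING_OFFSETS = tuple(range(-9, 11))   # 3'-5' distances, linkage at +1


@dataclass
class LinkageSpectrum:
    kind: str
    offsets: np.ndarray
    frequencies: np.ndarray
    link_offset: int
    z: float
    zero_variance: bool = False

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"offset": self.offsets,
                             "frequency": self.frequencies})


def window_z(frequencies: Sequence[float], link_index: int,
             sd_mode: str = "background") -> tuple[float, bool]:
    """Z-score of the linkage-offset frequency within its window.

    Returns (z, zero_variance). A zero-variance window reports z = 0 with
    the flag set rather than an infinity.
    """
    f = np.asarray(frequencies, dtype=float)
    if sd_mode == "window":
        mean, sd = f.mean(), f.std()
    elif sd_mode == "background":
        bg = np.delete(f, link_index)
        mean, sd = bg.mean(), bg.std()
    else:
        raise ValueError(f"unknown sd_mode {sd_mode!r}")
    if sd == 0:
        return 0.0, True
    return float((f[link_index] - mean) / sd), False


def _shifted_dot(a: np.ndarray, b: np.ndarray, shift: int) -> float:
    """sum_p a[p] * b[p + shift] with out-of-range positions dropped."""
    n = len(a)
    if shift >= 0:
        if shift >= n:
            return 0.0
        return float(np.dot(a[:n - shift], b[shift:]))
    return float(np.dot(a[-shift:], b[:n + shift]))


def pingpong_spectrum(profile: EndProfile,
                      offsets: Sequence[int] = PINGPONG_OFFSETS,
                      link_offset: int = 10,
                      sd_mode: str = "background") -> LinkageSpectrum:
    """5'-5' overlap spectrum between sense and antisense piRNAs.

    The frequency at overlap k is sum_p senseFive(p) * antisenseFive(p+k-1),
    so k = 10 is the 10-nt overlap diagnostic of ping-pong.
    """
    if profile.sense_total == 0 or profile.antisense_total == 0:
        raise ValueError("ping-pong linkage needs reads on both strands")
    freqs = np.array([_shifted_dot(profile.five_sense, profile.five_antisense,
                                   k - 1) for k in offsets])
    link_index = list(offsets).index(link_offset)
    z, flat = window_z(freqs, link_index, sd_mode)
    return LinkageSpectrum("pingpong", np.asarray(offsets), freqs,
                           link_offset, z, flat)


def phasing_spectrum(profile: EndProfile, strand: str = "antisense",
                     offsets: Sequence[int] = PHASING_OFFSETS,
                     link_offset: int = 1,
                     sd_mode: str = "background") -> LinkageSpectrum:
    """3'-5' distance spectrum on one strand (default antisense).

    Positions are taken in the reading (5'->3') orientation of the strand, so
    +1 means the next piRNA's 5' end is the base immediately downstream of
    the previous 3' end, the head-to-tail signature of phasing.
    """
    if strand == "antisense":
        three, five = profile.three_antisense, profile.five_antisense
        total = profile.antisense_total
        three, five = three[::-1], five[::-1]  # genomic -> reading orientation
    elif strand == "sense":
        three, five = profile.three_sense, profile.five_sense
        total = profile.sense_total
    else:
        raise ValueError(f"unknown strand {strand!r}")
    if total == 0:
        raise ValueError(f"no {strand} reads in profile")
    freqs = np.array([_shifted_dot(three, five, k) for k in offsets])
    link_index = list(offsets).index(link_offset)
    z, flat = window_z(freqs, link_index, sd_mode)
    return LinkageSpectrum("phasing", np.asarray(offsets), freqs,
                           link_offset, z, flat)


def downstream_u_frequency(te_alignments: Iterable[AlignmentRecord],
                           te_sequence: str,
                           positions: Sequence[int] = tuple(range(1, 11)),
                           min_len: int = PIRNA_MIN_LEN) -> pd.Series:
    """Weighted fraction of reads with a U at positions relative to 3' ends.

    Positive positions run downstream in the read's own 5'->3' direction
    (+1 is the first base past the 3' end). Reads whose offset falls outside
    the reference are excluded at that offset only.
    """
    te_sequence = te_sequence.upper()
    L = len(te_sequence)
    hits = {p: 0.0 for p in positions}
    totals = {p: 0.0 for p in positions}
    for aln in te_alignments:
        if aln.read.length < min_len:
            continue
        mass = aln.read.count * aln.weight
        for p in positions:
            if aln.strand == "+":
                pos = aln.three_prime + p
                if not 0 <= pos < L:
                    continue
                is_u = te_sequence[pos] == "T"
            else:
                pos = aln.three_prime - p
                if not 0 <= pos < L:
                    continue
                is_u = te_sequence[pos] == "A"  # complement is T
            totals[p] += mass
            if is_u:
                hits[p] += mass
    return pd.Series(
        {p: (hits[p] / totals[p]) if totals[p] > 0 else np.nan
         for p in positions})


def linkage_summary(profiles, sd_mode: str = "background") -> pd.DataFrame:
    """Per-TE ping-pong and phasing z-scores for eligible profiles."""
    rows = []
    for prof in profiles:
        row = {"te": prof.reference, "pingpong_z": np.nan, "phasing_z": np.nan}
        if prof.sense_total > 0 and prof.antisense_total > 0:
            row["pingpong_z"] = pingpong_spectrum(prof, sd_mode=sd_mode).z
        if prof.antisense_total > 0:
            row["phasing_z"] = phasing_spectrum(prof, sd_mode=sd_mode).z
        rows.append(row)
    return pd.DataFrame(rows)
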