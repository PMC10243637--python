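"""The in-trans ping-pong 9mer sum-product statistic and its calibration."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pirnakit.core import SmallRNARead, revcomp
from pirnakit.intrans import (NinemerProfile, build_ninemer_profile, calibrate,
                              estimate_pair_percent, extract_ninemers,
                              inject_pairs, intrans_linkage, make_pair_species)
from pirnakit.synthetic import random_pool

dna = st.text(alphabet="ACGT", min_size=23, max_size=29)


def brute_force_linkage(reads_a, cat_a, reads_b, cat_b):
    """All-pairs sum-product oracle, independent of the hashed profiles."""
    idx = {"g1g9": 0, "last9": 1, "g2g10_revComp": 2}
    ta = sum(r.count for r in reads_a)
    tb = sum(r.count for r in reads_b)
    dot = 0
    for ra in reads_a:
        ka = extract_ninemers(ra.sequence)[idx[cat_a]]
        for rb in reads_b:
            if ka == extract_ninemers(rb.sequence)[idx[cat_b]]:
                dot += ra.count * rb.count
    return (1000.0 ** 2) * dot / (ta * tb)


class TestExtractNinemers:
    def test_worked_example(self):
        g1g9, last9, g2rc = extract_ninemers("TACGATCGGATTCGAGCTAGCTATA")
        assert g1g9 == "TACGATCGG"
        assert g2rc == "TCCGATCGT"
        assert last9 == "CTAGCTATA"

    def test_alternating_read_self_complementary(self):
        g1g9, _, g2rc = extract_ninemers("AT" * 12)
        assert g1g9 == "ATATATATA" == g2rc

    @given(dna)
    @settings(max_examples=50, deadline=None)
    def test_involution(self, seq):
        _, _, g2rc = extract_ninemers(seq)
        assert revcomp(g2rc) == seq[1:10]

    def test_short_read_rejected(self):
        with pytest.raises(ValueError):
            extract_ninemers("ACGTACGT")


class TestNinemerProfile:
    def test_single_species_normalizes_to_1000(self):
        prof = build_ninemer_profile([SmallRNARead("ACGTT" * 5, 17)], "g1g9")
        assert prof.frequencies == {"ACGTTACGT": 1000.0}

    def test_two_species_split(self):
        reads = [SmallRNARead("A" * 25, 75), SmallRNARead("C" * 25, 25)]
        prof = build_ninemer_profile(reads, "g1g9")
        assert prof.frequencies == {"A" * 9: 750.0, "C" * 9: 250.0}

    def test_cpm_scale_example(self):
        # 100 CPM in a million-count pool -> frequency 0.1
        reads = [SmallRNARead("A" * 25, 100),
                 SmallRNARead("C" * 25, 999_900)]
        prof = build_ninemer_profile(reads, "g1g9")
        assert prof.frequencies["A" * 9] == pytest.approx(0.1)
        assert prof.cpm(1e6)["A" * 9] == pytest.approx(100.0)

    def test_profile_sums_to_1000(self, rng):
        prof = build_ninemer_profile(random_pool(rng, 5000, total=50_000),
                                     "g2g10_revComp")
        assert sum(prof.frequencies.values()) == pytest.approx(1000.0)

    def test_n_reads_skipped_and_counted(self):
        reads = [SmallRNARead("A" * 25, 1), SmallRNARead("N" + "A" * 24, 1)]
        prof = build_ninemer_profile(reads, "g1g9")
        assert prof.total == 1 and prof.n_skipped == 1

    def test_empty_pool_rejected(self):
        with pytest.raises(ValueError):
            build_ninemer_profile([], "g1g9")


class TestIntransLinkage:
    def test_disjoint_supports_give_zero(self):
        reads = [SmallRNARead("A" * 25, 10)]
        g1g9 = build_ninemer_profile(reads, "g1g9")
        g2rc = build_ninemer_profile(reads, "g2g10_revComp")
        assert intrans_linkage(g1g9, g2rc) == 0.0

    def test_self_complementary_maximum(self):
        reads = [SmallRNARead("AT" * 12, 5)]
        g1g9 = build_ninemer_profile(reads, "g1g9")
        g2rc = build_ninemer_profile(reads, "g2g10_revComp")
        assert intrans_linkage(g1g9, g2rc) == 1000.0 * 1000.0

    def test_duplication_invariance(self, rng):
        pool = random_pool(rng, 500, total=5000)
        doubled = [SmallRNARead(r.sequence, 2 * r.count) for r in pool]
        a1 = build_ninemer_profile(pool, "g1g9")
        b1 = build_ninemer_profile(pool, "g2g10_revComp")
        a2 = build_ninemer_profile(doubled, "g1g9")
        b2 = build_ninemer_profile(doubled, "g2g10_revComp")
        assert intrans_linkage(a1, b1) == intrans_linkage(a2, b2)

    def test_matches_brute_force_oracle_exactly(self, rng):
        pool = random_pool(rng, 400, total=4000)
        g1g9 = build_ninemer_profile(pool, "g1g9")
        last9 = build_ninemer_profile(pool, "last9")
        g2rc = build_ninemer_profile(pool, "g2g10_revComp")
        assert intrans_linkage(g1g9, g2rc) == brute_force_linkage(
            pool, "g1g9", pool, "g2g10_revComp")
        assert intrans_linkage(last9, g2rc) == brute_force_linkage(
            pool, "last9", pool, "g2g10_revComp")


class TestEstimatePairPercent:
    def test_engineered_pair_detected(self):
        rng = np.random.default_rng(0)
        a, b = make_pair_species(rng)
        pool = [SmallRNARead(a, 50), SmallRNARead(b, 50),
                SmallRNARead("A" * 25, 900)]
        res = estimate_pair_percent(pool)
        assert res.foreground > res.background
        assert res.estimated_percent > 0

    def test_negative_estimate_not_clamped(self):
        # B's last9 equals the g2g10_revComp of A: pure background signal
        a = "TACGATCGGATTCGAGCTAGCTATA"
        g2rc = extract_ninemers(a)[2]
        b = "G" * 16 + g2rc
        res = estimate_pair_percent([SmallRNARead(a, 10), SmallRNARead(b, 10)])
        assert res.estimated_percent < 0

    def test_cross_library_mode(self):
        rng = np.random.default_rng(1)
        a, b = make_pair_species(rng)
        total = [SmallRNARead(a, 100), SmallRNARead("A" * 25, 900)]
        ip = [SmallRNARead(b, 100)]
        res = estimate_pair_percent(total, g2g10_reads=ip)
        # the IP pool supplies g2g10_revComp; A's g1g9 finds it
        assert res.foreground > 0

    def test_null_pool_near_zero(self):
        pool = random_pool(np.random.default_rng(3), 50_000)
        res = estimate_pair_percent(pool)
        assert abs(res.estimated_percent) < 0.5


class TestCalibration:
    def test_closed_form_single_pair_species(self):
        # one pair at 100 CPM of a 1e6 pool adds exactly 2*(0.1)^2 = 0.02
        base = [SmallRNARead("A" * 25, 999_800)]
        spiked, achieved = inject_pairs(base, 0.02, np.random.default_rng(4))
        assert sum(r.count for r in spiked) == 1_000_000
        assert achieved == pytest.approx(0.02)
        res = estimate_pair_percent(spiked)
        assert res.foreground == pytest.approx(0.02, abs=1e-12)
        assert res.background == 0.0

    def test_pair_members_complement_in_both_directions(self):
        a, b = make_pair_species(np.random.default_rng(5))
        assert extract_ninemers(a)[0] == extract_ninemers(b)[2]
        assert extract_ninemers(b)[0] == extract_ninemers(a)[2]

    def test_achieved_percent_reported_on_rounding(self):
        base = [SmallRNARead("A" * 25, 10_000)]
        _, achieved = inject_pairs(base, 5.0, np.random.default_rng(6))
        assert achieved == pytest.approx(5.0, abs=0.5)

    def test_unachievable_level_rejected(self):
        base = [SmallRNARead("A" * 25, 1000)]
        with pytest.raises(ValueError):
            inject_pairs(base, 0.001, np.random.default_rng(7))

    def test_zero_level_is_base_pool(self, rng):
        base = random_pool(rng, 2000, total=20_000)
        res = calibrate(base, percents=(0,), replicates=2, rng=rng)
        base_est = estimate_pair_percent(base).estimated_percent
        assert np.allclose(res.table["linkage"], base_est)

    def test_small_scale_slope_near_unity(self):
        rng = np.random.default_rng(8)
        base = random_pool(rng, 20_000, total=200_000)
        res = calibrate(base, replicates=2, rng=rng)
        assert 0.8 < res.slope < 1.15

    def test_slope_scale_invariance(self):
        # the linkage-per-percent scale does not depend on pool size
        slopes = []
        for n, total in ((10_000, 100_000), (30_000, 300_000)):
            rng = np.random.default_rng(9)
            base = random_pool(rng, n, total=total)
            slopes.append(calibrate(base, percents=(0, 5, 10),
                                    replicates=2, rng=rng).slope)
        assert slopes[0] == pytest.approx(slopes[1], abs=0.1)
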