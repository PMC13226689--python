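"""Ping-pong/phasing statistics: formulas, degenerate cases, quadratic
oracle agreement, null calibration and power."""

import statistics

import numpy as np
import pandas as pd
import pytest

from pirnakit import (
    OverlapHistogram,
    SimConfig,
    SmallRNARead,
    nt_bias,
    null_alignment_table,
    overlap_histogram,
    phasing_histogram,
    phasing_zscore,
    pingpong_alignment_table,
    pingpong_percent,
    pingpong_zscore,
    unistrand_alignment_table,
    zscore,
)
from pirnakit.mapping import ALIGNMENT_COLUMNS
from pirnakit.signatures import overlap_histogram_allpairs, phasing_histogram_allpairs


def _aln(rows):
    return pd.DataFrame(rows, columns=ALIGNMENT_COLUMNS)


def _row(rid, start, end, strand, copies=1, w=None):
    return (rid, "locus", start, end, strand, 0, True, copies,
            end - start, copies if w is None else w)


class TestOverlapHistogram:
    def test_ten_nt_overlap_lands_in_focal_bin(self):
        # plus 5' at 100, minus 5' at 109 -> d = 10
        aln = _aln([_row("a", 100, 126, "+"), _row("b", 84, 110, "-")])
        hist = overlap_histogram(aln)
        assert hist.counts[9] == 1.0
        assert hist.counts.sum() == 1.0

    def test_coincident_5prime_ends_are_distance_one(self):
        aln = _aln([_row("a", 100, 126, "+"), _row("b", 75, 101, "-")])
        hist = overlap_histogram(aln)
        assert hist.counts[0] == 1.0

    def test_multiplicities_multiply(self):
        aln = _aln([_row("a", 100, 126, "+", copies=3), _row("b", 84, 110, "-", copies=5)])
        assert overlap_histogram(aln).counts[9] == 15.0

    def test_matches_allpairs_oracle_on_random_reads(self, rng):
        rows = []
        for i in range(300):
            s = int(rng.integers(0, 500))
            L = int(rng.integers(23, 33))
            strand = "+" if rng.random() < 0.5 else "-"
            rows.append(_row(f"r{i}", s, s + L, strand, copies=int(rng.integers(1, 3))))
        aln = _aln(rows)
        fast = overlap_histogram(aln).counts
        slow = overlap_histogram_allpairs(aln).counts
        np.testing.assert_allclose(fast, slow)


class TestPhasingHistogram:
    def test_adjacent_reads_distance_one(self):
        # upstream 3' end at 0-based 124 (1-based 125), downstream 5' at 125
        aln = _aln([_row("a", 100, 125, "+"), _row("b", 125, 150, "+")])
        hist = phasing_histogram(aln)
        assert hist.counts[0] == 1.0

    def test_minus_strand_distances_follow_transcription(self):
        # minus strand: 5' at end-1, 3' at start; downstream = decreasing coord
        aln = _aln([_row("a", 100, 125, "-"), _row("b", 70, 99, "-")])
        hist = phasing_histogram(aln)
        assert hist.counts[1] == 1.0  # 3' at 100, next 5' at 98 -> d = 2

    def test_only_nearest_downstream_counted(self):
        aln = _aln(
            [_row("a", 100, 125, "+"), _row("b", 127, 150, "+"), _row("c", 140, 165, "+")]
        )
        hist = phasing_histogram(aln)
        # a->b d=3; b->c is 5'(140)-3'(149)? no: b 3'=149, c 5'=140 upstream -> none
        assert hist.counts[2] == 1.0
        assert hist.counts.sum() == 1.0

    def test_matches_allpairs_oracle_on_random_reads(self, rng):
        rows = []
        for i in range(250):
            s = int(rng.integers(0, 2000))
            L = int(rng.integers(23, 33))
            strand = "+" if rng.random() < 0.5 else "-"
            rows.append(_row(f"r{i}", s, s + L, strand))
        aln = _aln(rows)
        np.testing.assert_allclose(
            phasing_histogram(aln).counts, phasing_histogram_allpairs(aln).counts
        )


class TestZscore:
    def test_hand_computed_example(self):
        counts = np.zeros(29)
        bg = [2.0, 6.0] * 14  # 28 alternating background bins
        j = 0
        for d in range(1, 30):
            if d == 10:
                counts[d - 1] = 30.0
            else:
                counts[d - 1] = bg[j]
                j += 1
        res = zscore(OverlapHistogram(counts), focal_d=10, min_pairs=1)
        expected = (30 - statistics.mean(bg)) / statistics.stdev(bg)
        assert res.zscore == pytest.approx(expected)
        assert res.tier == "***"

    def test_flat_histogram_reported_missing(self):
        res = zscore(OverlapHistogram(np.full(30, 7.0)), focal_d=10, min_pairs=1)
        assert res.zscore is None and res.tier == "NA"

    def test_insufficient_pairs_reported_missing(self):
        counts = np.arange(30, dtype=float)
        res = zscore(OverlapHistogram(counts), focal_d=10, min_pairs=1000)
        assert res.tier == "NA"

    def test_zero_z_is_not_significant(self):
        counts = np.array([4.0, 6.0] * 15)
        counts[9] = statistics.mean(np.delete(counts, 9))
        res = zscore(OverlapHistogram(counts), focal_d=10, min_pairs=1)
        assert res.zscore == pytest.approx(0.0)
        assert res.pvalue == pytest.approx(0.5)
        assert res.tier == "ns"

    def test_tier_thresholds(self):
        from scipy import stats as sps

        for z, tier in ((1.0, "ns"), (2.0, "*"), (2.5, "**"), (3.5, "***")):
            p = float(sps.norm.sf(z))
            from pirnakit.signatures import _tier

            assert _tier(p) == tier


class TestPingpongPercent:
    def test_pure_pingpong_table_is_100(self):
        aln = pingpong_alignment_table(500, SimConfig(seed=1, pingpong_pair_fraction=1.0))
        assert pingpong_percent(aln) == pytest.approx(100.0)

    def test_pure_unistrand_is_zero(self):
        aln = unistrand_alignment_table(500, SimConfig(seed=1))
        assert pingpong_percent(aln) == 0.0

    def test_single_read_has_no_partner(self):
        aln = _aln([_row("a", 100, 126, "+")])
        assert pingpong_percent(aln) == 0.0


class TestNtBias:
    def test_all_u_starting_reads(self):
        reads = [SmallRNARead(f"r{i}", "T" + "ACG" * 8) for i in range(5)]
        assert nt_bias(reads)["U1"] == 1.0

    def test_empty_read_set_errors(self):
        with pytest.raises(ValueError):
            nt_bias([])

    def test_simulated_u1_bias_within_binomial_bound(self, strain1):
        from pirnakit import simulate_unistrand_pirnas

        cfg = SimConfig(seed=12, u1_bias=0.7)
        chrom = strain1.chrom
        reads = simulate_unistrand_pirnas(
            (chrom, 0, strain1.refset.chrom_length(chrom), "+"), 10_000, cfg,
            strain1.refset.genome,
        )
        u1 = nt_bias(reads)["U1"]
        assert abs(u1 - 0.7) <= 3 * np.sqrt(0.7 * 0.3 / 10_000)


class TestCalibrationAndPower:
    def test_pingpong_power_on_pair_table(self):
        res = pingpong_zscore(pingpong_alignment_table(10_000, SimConfig(seed=1, pingpong_pair_fraction=0.5)))
        assert res.zscore > 10

    def test_pingpong_null_calibrated(self):
        zs = [
            pingpong_zscore(null_alignment_table(10_000, seed=s)).zscore for s in range(20)
        ]
        assert np.mean(np.abs(zs) < 3) >= 0.95

    def test_phasing_power_on_tight_walk(self):
        cfg = SimConfig(seed=1, phasing_tightness=0.95)
        assert phasing_zscore(unistrand_alignment_table(10_000, cfg)).zscore > 10

    def test_phasing_null_calibrated_on_random_gap_walks(self):
        zs = [
            phasing_zscore(
                unistrand_alignment_table(5000, SimConfig(seed=s, phasing_tightness=0.0))
            ).zscore
            for s in range(20)
        ]
        assert np.mean(np.abs(zs) < 3) >= 0.95

    def test_pingpong_z_monotone_in_pair_fraction(self):
        """Seed-averaged ping-pong Z grows with the ping-pong pair share."""
        means = []
        for frac in (0.1, 0.4, 0.7, 1.0):
            zs = [
                pingpong_zscore(
                    pingpong_alignment_table(1500, SimConfig(seed=s, pingpong_pair_fraction=frac))
                ).zscore
                for s in range(20)
            ]
            means.append(np.mean(zs))
        assert all(a < b for a, b in zip(means, means[1:]))
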