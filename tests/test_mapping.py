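"""Aligner semantics: strata, uniqueness, strand conventions, and exact
agreement with a brute-force all-offsets oracle."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from pirnakit import SmallRNARead, brute_force_map, map_reads, revcomp
from pirnakit.coverage import coverage_track
from pirnakit.simulate import random_sequence
from pirnakit.trim import collapse_reads


@pytest.fixture(scope="module")
def consensus():
    return {"cons": random_sequence(np.random.default_rng(17), 2000)}


def _as_key_set(df):
    return set(
        zip(df["read_id"], df["ref_name"], df["start"], df["end"], df["strand"],
            df["mismatches"], df["unique"])
    )


class TestMapperSemantics:
    def test_exact_substring_single_unique_hit(self, consensus):
        seq = consensus["cons"][100:126]
        aln = map_reads([SmallRNARead("r", seq)], consensus)
        row = aln.iloc[0]
        assert (row["start"], row["end"], row["strand"], row["mismatches"]) == (100, 126, "+", 0)
        assert row["unique"] and row["weight"] == 1.0

    def test_reverse_complement_maps_minus_with_5prime_at_end(self, consensus):
        seq = revcomp(consensus["cons"][40:66])
        aln = map_reads([SmallRNARead("r", seq)], consensus)
        row = aln.iloc[0]
        assert row["strand"] == "-"
        assert row["end"] - 1 == 65  # 5' coordinate convention on minus

    def test_best_stratum_excludes_suboptimal(self, consensus):
        ref = consensus["cons"]
        # plant an exact copy and a 1-mismatch copy of the same 25-mer
        core = ref[300:325]
        mutated = core[:12] + ("A" if core[12] != "A" else "C") + core[13:]
        refs = {"r1": ref[:500] + core + mutated + ref[500:900]}
        aln = map_reads([SmallRNARead("x", core)], refs)
        assert (aln["mismatches"] == 0).all()
        # exact occurrences at 300 and 500; the 1-mismatch copy is not reported
        assert sorted(aln["start"]) == [300, 500]
        assert not aln["unique"].any()

    def test_mismatch_cap_respected(self, consensus):
        seq = list(consensus["cons"][700:726])
        for i in (3, 9, 15):  # three substitutions: beyond max_mismatches=2
            seq[i] = {"A": "C", "C": "G", "G": "T", "T": "A"}[seq[i]]
        aln = map_reads([SmallRNARead("r", "".join(seq))], consensus)
        assert aln.empty

    def test_n_bases_count_as_mismatch(self, consensus):
        seq = "NN" + consensus["cons"][502:526]
        aln = map_reads([SmallRNARead("r", seq)], consensus)
        assert not aln.empty
        assert (aln["mismatches"] == 2).all()

    def test_non_acgtn_read_skipped(self, consensus):
        aln, unmapped = map_reads(
            [SmallRNARead("r", "ACGTXACGTACGTACGTACGTACGT")], consensus, with_unmapped=True
        )
        assert aln.empty and unmapped == []

    def test_unmapped_reads_reported(self, consensus):
        foreign = random_sequence(np.random.default_rng(99), 26)
        aln, unmapped = map_reads([SmallRNARead("r", foreign)], consensus, with_unmapped=True)
        assert aln.empty
        assert [r.id for r in unmapped] == ["r"]

    def test_empty_references_rejected(self):
        with pytest.raises(ValueError):
            map_reads([SmallRNARead("r", "ACGT" * 7)], {})


class TestOracleEquivalence:
    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.integers(min_value=0, max_value=2**31 - 1))
    def test_matches_brute_force_on_random_fixtures(self, seed):
        rng = np.random.default_rng(seed)
        refs = {
            "a": random_sequence(rng, int(rng.integers(60, 400))),
            "b": random_sequence(rng, int(rng.integers(60, 400))),
        }
        reads = []
        for i in range(30):
            ref = refs["a" if rng.random() < 0.5 else "b"]
            L = int(rng.integers(18, 33))
            s = int(rng.integers(0, len(ref) - L))
            seq = list(ref[s : s + L])
            for _ in range(int(rng.integers(0, 3))):  # up to 2 substitutions
                j = int(rng.integers(0, L))
                seq[j] = "ACGT"[int(rng.integers(4))]
            read = "".join(seq)
            if rng.random() < 0.5:
                read = revcomp(read)
            reads.append(SmallRNARead(f"r{i}", read))
        fast = map_reads(reads, refs)
        slow = brute_force_map(reads, refs)
        assert _as_key_set(fast) == _as_key_set(slow)

    def test_matches_brute_force_with_planted_duplicates(self):
        rng = np.random.default_rng(5)
        core = random_sequence(rng, 1200)
        dup = core[200:500]
        ref = {"dup2": core + dup}  # the 300-nt block occurs twice
        reads = [SmallRNARead(f"d{i}", dup[j : j + 25]) for i, j in enumerate(range(0, 270, 9))]
        fast = map_reads(reads, ref)
        slow = brute_force_map(reads, ref)
        assert _as_key_set(fast) == _as_key_set(slow)
        assert not fast["unique"].any()
        assert np.allclose(fast["weight"], 0.5)


class TestCollapsingCommutes:
    def test_collapse_then_map_equals_map_then_aggregate(self, consensus):
        rng = np.random.default_rng(8)
        reads = []
        for i in range(80):
            s = int(rng.integers(0, 1950))
            reads.append(SmallRNARead(f"r{i}", consensus["cons"][s : s + 26]))
        direct = map_reads(reads, consensus)
        collapsed = map_reads(collapse_reads(reads), consensus)
        agg_a = direct.groupby(["start", "end", "strand"])["weight"].sum()
        agg_b = collapsed.groupby(["start", "end", "strand"])["weight"].sum()
        pd.testing.assert_series_equal(agg_a, agg_b)


class TestCoverage:
    def test_single_unique_alignment_footprint(self, consensus):
        aln = map_reads([SmallRNARead("r", consensus["cons"][100:126])], consensus)
        track = coverage_track(aln, "cons", 2000, "unique_only")
        assert track[100:126].tolist() == [1.0] * 26
        assert track.sum() == 26

    def test_fractional_splits_between_two_placements(self):
        rng = np.random.default_rng(5)
        core = random_sequence(rng, 600)
        ref = {"r2": core + core[100:150] + core[300:]}
        read = SmallRNARead("r", core[110:135])
        aln = map_reads([read], ref)
        assert len(aln) == 2
        track = coverage_track(aln, "r2", len(ref["r2"]), "fractional")
        assert track.max() == 0.5
        assert np.isclose(track.sum(), 25)

    @settings(max_examples=15, deadline=None, derandomize=True)
    @given(st.integers(min_value=0, max_value=2**31 - 1))
    def test_mass_conservation_on_random_fixtures(self, seed):
        rng = np.random.default_rng(seed)
        ref = {"c": random_sequence(rng, 800)}
        reads = []
        for i in range(60):
            L = int(rng.integers(20, 33))
            s = int(rng.integers(0, 800 - L))
            reads.append(SmallRNARead(f"r{i}", ref["c"][s : s + L], copies=int(rng.integers(1, 4))))
        aln = map_reads(reads, ref)
        track = coverage_track(aln, "c", 800, "fractional")
        expected = float((aln["weight"] * aln["length"]).sum())
        assert np.isclose(track.sum(), expected)
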