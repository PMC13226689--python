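"""Generator contracts: determinism, genome bookkeeping, read structure."""

import collections

import numpy as np
import pytest

from pirnakit import (
    GeneModel,
    InsertionSpec,
    SimConfig,
    build_toy_genome,
    simulate_dna_reads,
    simulate_mirnas,
    simulate_pingpong_pirnas,
    simulate_sirnas,
    simulate_unistrand_pirnas,
)
from pirnakit.mapping import five_prime_positions, three_prime_positions, map_reads
from pirnakit.simulate import random_consensus, random_sequence


@pytest.fixture(scope="module")
def toy():
    rng = np.random.default_rng(7)
    te = random_consensus(rng, "TE1", 5000)
    gene = GeneModel("g1", "chrX", 2000, 9000, "+", 7000, 9000)
    ins = InsertionSpec("TE1", "chrX", 8000, orientation="antisense", context="gene_3utr")
    refset = build_toy_genome([te], [ins], [gene], seed=11, chrom_lengths={"chrX": 20_000})
    return te, refset


class TestBuildToyGenome:
    def test_genome_length_adds_inserted_te(self, toy):
        te, refset = toy
        assert len(refset.genome["chrX"]) == 20_000 + 5000

    def test_antisense_utr_insertion_strand_opposes_host_gene(self, toy):
        _, refset = toy
        ins = refset.insertions[0]
        assert refset.genes[0].strand == "+"
        assert ins.genome_strand == "-"
        assert ins.host_gene == "g1"

    def test_gene_stretched_by_internal_insertion(self, toy):
        _, refset = toy
        g = refset.genes[0]
        assert (g.start, g.end) == (2000, 14_000)

    def test_internal_deletion_shortens_inserted_segment(self):
        rng = np.random.default_rng(3)
        te = random_consensus(rng, "TE1", 5000)
        ins = InsertionSpec(
            "TE1", "c", 1000, orientation="sense", internal_deletion=(600, 1352)
        )
        refset = build_toy_genome([te], [ins], [], seed=5, chrom_lengths={"c": 10_000})
        final = refset.insertions[0]
        assert final.end - final.start == 5000 - 752

    def test_zero_insertions_genome_equals_background(self):
        rng = np.random.default_rng(3)
        te = random_consensus(rng, "TE1", 500)
        bare = build_toy_genome([te], [], [], seed=5, chrom_lengths={"c": 5000})
        ins = InsertionSpec("TE1", "c", 1000, orientation="sense")
        with_ins = build_toy_genome([te], [ins], [], seed=5, chrom_lengths={"c": 5000})
        g = with_ins.genome["c"]
        spliced_out = g[:1000] + g[1500:]
        assert spliced_out == bare.genome["c"]

    def test_overlapping_insertions_rejected_naming_pair(self):
        rng = np.random.default_rng(3)
        te = random_consensus(rng, "TE1", 500)
        te2 = random_consensus(rng, "TE2", 500)
        ins = [
            InsertionSpec("TE1", "c", 1000),
            InsertionSpec("TE2", "c", 1000),
        ]
        with pytest.raises(ValueError, match="TE1.*TE2"):
            build_toy_genome([te, te2], ins, [], seed=5, chrom_lengths={"c": 5000})

    def test_inserted_sequence_matches_consensus(self, toy):
        te, refset = toy
        ins = refset.insertions[0]
        from pirnakit import revcomp

        segment = refset.genome["chrX"][ins.start : ins.end]
        assert revcomp(segment) == te.sequence  # antisense insertion


class TestUnistrand:
    def test_deterministic_per_seed(self, toy):
        te, refset = toy
        ivl = ("chrX", 8000, 13_000, "+")
        cfg = SimConfig(seed=42)
        a = simulate_unistrand_pirnas(ivl, 200, cfg, refset.genome)
        b = simulate_unistrand_pirnas(ivl, 200, cfg, refset.genome)
        assert [(r.id, r.sequence) for r in a] == [(r.id, r.sequence) for r in b]

    def test_perfect_tightness_gives_all_adjacent_distances(self, toy):
        _, refset = toy
        cfg = SimConfig(seed=1, phasing_tightness=1.0, u1_bias=0.0, antisense_fraction=1.0)
        reads = simulate_unistrand_pirnas(("chrX", 0, 20_000, "+"), 300, cfg, refset.genome)
        aln = map_reads(reads, {"chrX": refset.genome["chrX"]}, max_mismatches=1)
        p5 = np.sort(five_prime_positions(aln[aln["strand"] == "+"]))
        p3 = np.sort(three_prime_positions(aln[aln["strand"] == "+"]))
        # consecutive 3'->5' distance is 1 wherever the walk did not wrap
        idx = np.searchsorted(p5, p3 + 1)
        ok = idx < len(p5)
        d = p5[idx[ok]] - p3[ok]
        assert (d == 1).mean() > 0.95

    def test_zero_tightness_gap_distribution_uniform(self):
        cfg = SimConfig(seed=2, phasing_tightness=0.0)
        from pirnakit.simulate import _phased_walk

        rng = np.random.default_rng(cfg.seed)
        walk = _phased_walk(rng, 10_000, 23, 32, 0.0)
        gaps = [b[0] - (a[0] + a[1] - 1) for a, b in zip(walk, walk[1:])]
        counts = collections.Counter(gaps)
        assert counts[1] == 0
        freqs = np.array([counts[g] for g in range(2, 31)]) / len(gaps)
        assert np.allclose(freqs, 1 / 29, atol=3 * np.sqrt((1 / 29) * (28 / 29) / len(gaps)))

    def test_antisense_source_reads_map_minus_to_consensus(self, toy):
        te, refset = toy
        ins = refset.insertions[0]
        cfg = SimConfig(seed=3, u1_bias=0.0)
        reads = simulate_unistrand_pirnas(
            ("chrX", ins.start, ins.end, "+"), 100, cfg, refset.genome
        )
        aln = map_reads(reads, {"TE1": te.sequence})
        assert set(aln["strand"]) == {"-"}

    def test_interval_shorter_than_read_errors(self, toy):
        _, refset = toy
        with pytest.raises(ValueError, match="shorter"):
            simulate_unistrand_pirnas(("chrX", 0, 20, "+"), 10, SimConfig(seed=1), refset.genome)

    def test_u1_frequency_tracks_bias(self, toy):
        _, refset = toy
        for bias in (0.7, 1.0):
            cfg = SimConfig(seed=5, u1_bias=bias)
            reads = simulate_unistrand_pirnas(("chrX", 0, 20_000, "+"), 10_000, cfg, refset.genome)
            u1 = np.mean([r.sequence[0] == "T" for r in reads])
            sd = np.sqrt(bias * (1 - bias) / 10_000)
            assert abs(u1 - bias) <= 3 * sd + 1e-9


class TestPingpong:
    def test_pure_pairs_overlap_exactly_ten(self, toy):
        _, refset = toy
        cfg = SimConfig(seed=6, pingpong_pair_fraction=1.0, u1_bias=0.0)
        reads = simulate_pingpong_pirnas(("chrX", 0, 20_000, "+"), 200, cfg, refset.genome)
        aln = map_reads(reads, {"chrX": refset.genome["chrX"]})
        plus = aln[aln["strand"] == "+"].sort_values("read_id")
        minus = aln[aln["strand"] == "-"].sort_values("read_id")
        d = minus["end"].to_numpy() - 1 - plus["start"].to_numpy() + 1
        assert (d == 10).all()

    def test_each_pair_is_one_read_per_strand(self, toy):
        _, refset = toy
        cfg = SimConfig(seed=7)
        reads = simulate_pingpong_pirnas(("chrX", 0, 20_000, "+"), 50, cfg, refset.genome)
        assert len(reads) == 100
        assert sum(r.id.endswith("s") for r in reads) == 50

    def test_zero_fraction_overlaps_near_uniform(self, toy):
        from scipy import stats as sps

        _, refset = toy
        cfg = SimConfig(seed=8, pingpong_pair_fraction=0.0, u1_bias=0.0)
        reads = simulate_pingpong_pirnas(("chrX", 0, 20_000, "+"), 3000, cfg, refset.genome)
        aln = map_reads(reads, {"chrX": refset.genome["chrX"]})
        plus = aln[aln["strand"] == "+"].sort_values("read_id")
        minus = aln[aln["strand"] == "-"].sort_values("read_id")
        d = minus["end"].to_numpy() - 1 - plus["start"].to_numpy() + 1
        counts = collections.Counter(d)
        assert counts[10] == 0
        observed = [counts[k] for k in list(range(1, 10)) + list(range(11, 31))]
        chi2 = sps.chisquare(observed)
        assert chi2.pvalue > 1e-4  # consistent with uniform


class TestOtherLibraries:
    def test_sirnas_are_21nt_both_strands(self, toy):
        _, refset = toy
        cfg = SimConfig(seed=9)
        reads = simulate_sirnas(("chrX", 0, 2000, "+"), 500, cfg, refset.genome)
        assert {len(r.sequence) for r in reads} == {21}
        aln = map_reads(reads, {"chrX": refset.genome["chrX"]})
        assert set(aln["strand"]) == {"+", "-"}

    def test_dna_read_count_matches_coverage(self, toy):
        _, refset = toy
        reads = simulate_dna_reads({"c": "ACGT" * 25_000}, 30, 100, seed=4)
        assert len(reads) == 30_000

    def test_mirnas_are_exact_annotated_sequences(self, strain1):
        mirnas = strain1.refset.mirnas
        reads = simulate_mirnas(mirnas, 5000, seed=3)
        known = {m.mature_sequence for m in mirnas}
        assert all(r.sequence in known for r in reads)
        assert sum(r.copies for r in reads) == 5000

    def test_empty_mirna_annotation_errors(self):
        with pytest.raises(ValueError, match="empty"):
            simulate_mirnas([], 100, seed=1)


def test_dna_coverage_positive_required():
    with pytest.raises(ValueError):
        simulate_dna_reads({"c": "A" * 1000}, 0, 50, seed=1)


def test_random_sequence_alphabet(rng):
    seq = random_sequence(rng, 1000)
    assert set(seq) <= set("ACGT")
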