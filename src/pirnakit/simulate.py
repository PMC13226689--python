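"""Synthetic references and small-RNA / genomic-DNA libraries.

The generator builds toy genomes with TE insertions spliced into defined
contexts (piRNA cluster, host-gene 3' UTR, intergenic) and emits read sets
carrying the statistical structure the downstream analytics detect:

* unistrand sources: single-stranded, head-to-tail *phased* piRNAs
  (follicle-cell / flamenco-type biogenesis),
* germline-type sources: sense/antisense piRNA pairs whose 5' ends overlap
  by exactly 10 nt (*ping-pong* amplification),
* 21-nt siRNA duplex products, abundant miRNAs (the normalisation class),
  and uniform genomic DNA reads for copy-number estimation.

Reads are emitted post-trimming by default; ``raw_mode`` appends the four
random linker nucleotides plus a fixed 3' adapter so the trimming step can
be exercised end to end. A given seed fully determines all output.
"""

from __future__ import annotations

import numpy as np

from .models import (
    GeneModel,
    InsertionSpec,
    MirnaLocus,
    ReferenceSet,
    SimConfig,
    SmallRNARead,
    TEConsensus,
    revcomp,
)

BASES = np.frombuffer(b"ACGT", dtype="S1")

#: interval = (chrom, start, end, strand); strand is the precursor strand
SourceInterval = tuple[str, int, int, str]


def random_sequence(rng: np.random.Generator, length: int) -> str:
    return rng.choice(BASES, size=length).tobytes().decode()


def random_consensus(rng: np.random.Generator, name: str, length: int) -> TEConsensus:
    return TEConsensus(name, random_sequence(rng, length))


# ---------------------------------------------------------------------------
# toy genome
# ---------------------------------------------------------------------------


def build_toy_genome(
    te_set: list[TEConsensus],
    insertions: list[InsertionSpec],
    gene_models: list[GeneModel],
    seed: int,
    chrom_lengths: dict[str, int] | None = None,
    n_mirna: int = 20,
    mirna_length: int = 22,
    n_unique_regions: int = 5,
    unique_region_length: int = 2000,
) -> ReferenceSet:
    """Splice TE insertions into an i.i.d.-uniform ACGT background.

    ``insertions`` give the insertion point in *background* coordinates in
    their ``start`` field; the returned specs carry final genome coordinates
    with ``end = start + inserted length`` and the genome strand implied by
    orientation and context. Gene coordinates are shifted accordingly (an
    insertion inside a gene stretches it). Background regions far from any
    insertion are designated genome-unique; at toy scale the i.i.d.
    background makes multi-mapping there vanishingly unlikely.
    """
    rng = np.random.default_rng(seed)
    chrom_lengths = chrom_lengths or {"chr2L": 60_000}
    te_by_name = {te.name: te for te in te_set}
    genome: dict[str, str] = {c: random_sequence(rng, n) for c, n in chrom_lengths.items()}

    for g in gene_models:
        if g.chrom not in chrom_lengths or g.end > chrom_lengths[g.chrom]:
            raise ValueError(f"gene {g.gene_id} outside chromosome bounds")

    by_chrom: dict[str, list[InsertionSpec]] = {}
    for ins in insertions:
        by_chrom.setdefault(ins.chrom, []).append(ins)

    final_insertions: list[InsertionSpec] = []
    offsets: dict[str, list[tuple[int, int]]] = {}  # chrom -> [(site, inserted_len)]
    for chrom, chrom_ins in by_chrom.items():
        chrom_ins = sorted(chrom_ins, key=lambda i: i.start)
        for a, b in zip(chrom_ins, chrom_ins[1:]):
            if a.start == b.start:
                raise ValueError(
                    f"overlapping insertions at {chrom}:{a.start}: "
                    f"{a.te_name} vs {b.te_name}"
                )
        pieces = []
        cursor = 0
        shift = 0
        sites = []
        for ins in chrom_ins:
            te = te_by_name[ins.te_name]
            if not 0 <= ins.start <= chrom_lengths[chrom]:
                raise ValueError(f"insertion site {ins.start} outside {chrom}")
            seq = te.sequence
            if ins.internal_deletion is not None:
                d0, d1 = ins.internal_deletion
                ins.inserted_length(len(te))  # validates the interval
                seq = seq[:d0] + seq[d1:]
            strand = _genome_strand(ins, gene_models)
            if strand == "-":
                seq = revcomp(seq)
            pieces.append(genome[chrom][cursor : ins.start])
            pieces.append(seq)
            cursor = ins.start
            final = InsertionSpec(
                ins.te_name,
                chrom,
                ins.start + shift,
                ins.start + shift + len(seq),
                ins.orientation,
                ins.context,
                ins.internal_deletion,
                genome_strand=strand,
                host_gene=_host_gene(ins, gene_models),
            )
            final_insertions.append(final)
            sites.append((ins.start, len(seq)))
            shift += len(seq)
        pieces.append(genome[chrom][cursor:])
        genome[chrom] = "".join(pieces)
        offsets[chrom] = sites

    def lift(chrom: str, coord: int, is_end: bool) -> int:
        shift = 0
        for site, ilen in offsets.get(chrom, []):
            if site < coord or (site == coord and not is_end):
                shift += ilen
        return coord + shift

    final_genes = [
        GeneModel(
            g.gene_id,
            g.chrom,
            lift(g.chrom, g.start, False),
            lift(g.chrom, g.end, True),
            g.strand,
            lift(g.chrom, g.utr3_start, False),
            lift(g.chrom, g.utr3_end, True),
        )
        for g in gene_models
    ]

    # exclusion mask in background coordinates: insertion sites +/- margin
    margin = 500
    forbidden: dict[str, list[tuple[int, int]]] = {c: [] for c in chrom_lengths}
    for chrom, sites in offsets.items():
        for site, _ in sites:
            forbidden[chrom].append((site - margin, site + margin))

    def clear(chrom: str, s: int, e: int) -> bool:
        return all(e <= a or s >= b for a, b in forbidden[chrom])

    unique_regions: list[tuple[str, int, int]] = []
    for chrom, clen in chrom_lengths.items():
        s = 0
        while s + unique_region_length <= clen and len(unique_regions) < n_unique_regions:
            e = s + unique_region_length
            if clear(chrom, s, e):
                unique_regions.append((chrom, lift(chrom, s, False), lift(chrom, e, True)))
                s = e
            else:
                s += unique_region_length // 2
        if len(unique_regions) >= n_unique_regions:
            break

    mirnas: list[MirnaLocus] = []
    chroms = sorted(chrom_lengths)
    attempts = 0
    while len(mirnas) < n_mirna and attempts < 50 * n_mirna:
        attempts += 1
        chrom = chroms[int(rng.integers(len(chroms)))]
        s = int(rng.integers(0, chrom_lengths[chrom] - mirna_length))
        if not clear(chrom, s, s + mirna_length):
            continue
        if any(m.chrom == chrom and abs(m.start - lift(chrom, s, False)) < 200 for m in mirnas):
            continue
        strand = "+" if rng.random() < 0.5 else "-"
        fs, fe = lift(chrom, s, False), lift(chrom, s + mirna_length, True)
        seq = genome[chrom][fs:fe]
        if strand == "-":
            seq = revcomp(seq)
        mirnas.append(MirnaLocus(f"mir-{len(mirnas) + 1}", chrom, fs, fe, strand, seq))

    return ReferenceSet(
        genome=genome,
        te_consensi={te.name: te for te in te_set},
        insertions=final_insertions,
        genes=final_genes,
        unique_regions=unique_regions,
        mirnas=mirnas,
    )


def _host_gene(ins: InsertionSpec, genes: list[GeneModel]) -> str | None:
    if ins.context != "gene_3utr":
        return None
    for g in genes:
        if g.chrom == ins.chrom and g.start <= ins.start <= g.end:
            return g.gene_id
    raise ValueError(f"gene_3utr insertion at {ins.chrom}:{ins.start} has no host gene")


def _genome_strand(ins: InsertionSpec, genes: list[GeneModel]) -> str:
    """Genome strand of the TE: orientation is relative to host-gene
    transcription inside genes, to the plus strand elsewhere."""
    if ins.context == "gene_3utr":
        host = _host_gene(ins, genes)
        gene_strand = next(g.strand for g in genes if g.gene_id == host)
        if ins.orientation == "sense":
            return gene_strand
        return "+" if gene_strand == "-" else "-"
    return "+" if ins.orientation == "sense" else "-"


# ---------------------------------------------------------------------------
# read simulators
# ---------------------------------------------------------------------------


def _phased_walk(
    rng: np.random.Generator,
    n: int,
    lo: int,
    hi: int,
    tightness: float,
    region_length: int | None = None,
) -> list[tuple[int, int]]:
    """5'-positions and lengths of a phased 5'->3' walk.

    With probability ``tightness`` the next 5' end is 1 nt past the previous
    3' end; otherwise the 3'-to-5' gap is uniform in [2, 30]. With a finite
    ``region_length`` the walk restarts near the origin when it runs off the
    end (a multi-pass tiling of the precursor); without one it is a single
    unbounded pass.
    """
    out = []
    if region_length is not None:
        t = int(rng.integers(0, min(30, region_length - hi) + 1))
    else:
        t = int(rng.integers(0, 31))
    for _ in range(n):
        if region_length is not None and t + hi > region_length:
            t = int(rng.integers(0, min(30, region_length - hi) + 1))
        ell = int(rng.integers(lo, hi + 1))
        out.append((t, ell))
        gap = 1 if rng.random() < tightness else int(rng.integers(2, 31))
        t = t + ell - 1 + gap
    return out


def _apply_u1(seq: str, rng: np.random.Generator, u1_bias: float) -> str:
    """Force the exact 5' U (T in DNA space) frequency to ``u1_bias``."""
    if rng.random() < u1_bias:
        first = "T"
    else:
        first = "ACG"[int(rng.integers(3))]
    return first + seq[1:]


def _extract(genome: dict[str, str], chrom: str, s: int, e: int, strand: str) -> str:
    seq = genome[chrom][s:e]
    return seq if strand == "+" else revcomp(seq)


def simulate_unistrand_pirnas(
    source_interval: SourceInterval,
    n: int,
    cfg: SimConfig,
    genome: dict[str, str],
    id_prefix: str = "uni",
) -> list[SmallRNARead]:
    """Phased piRNAs tiled along one strand of a precursor transcript.

    With probability ``phasing_tightness`` the next read's 5' end sits
    exactly 1 nt downstream of the previous read's 3' end; otherwise the
    3'-to-5' gap is uniform in [2, 30]. ``antisense_fraction`` of reads come
    from the precursor strand; the remainder are opposite-strand noise.
    """
    chrom, start, end, strand = source_interval
    lo, hi = cfg.pirna_length_range
    length = end - start
    if length < hi:
        raise ValueError(f"source interval ({length} nt) shorter than max read length {hi}")
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(cfg.seed)
    n_main = int(round(n * cfg.antisense_fraction))
    reads: list[SmallRNARead] = []

    for i, (t, ell) in enumerate(_phased_walk(rng, n_main, lo, hi, cfg.phasing_tightness, length)):
        if strand == "+":
            seq = _extract(genome, chrom, start + t, start + t + ell, "+")
        else:
            seq = _extract(genome, chrom, end - t - ell, end - t, "-")
        seq = _apply_u1(seq, rng, cfg.u1_bias)
        reads.append(SmallRNARead(f"{id_prefix}{i}", seq))

    opp = "-" if strand == "+" else "+"
    for i in range(n - n_main):
        ell = int(rng.integers(lo, hi + 1))
        s = int(rng.integers(start, end - ell + 1))
        seq = _apply_u1(_extract(genome, chrom, s, s + ell, opp), rng, cfg.u1_bias)
        reads.append(SmallRNARead(f"{id_prefix}.op{i}", seq))
    return reads


def simulate_pingpong_pirnas(
    source_interval: SourceInterval,
    n_pairs: int,
    cfg: SimConfig,
    genome: dict[str, str],
    id_prefix: str = "pp",
) -> list[SmallRNARead]:
    """Sense/antisense piRNA pairs from a germline-type (dual-strand) source.

    A fraction ``pingpong_pair_fraction`` of pairs overlap by exactly 10 nt
    at their 5' ends; the rest overlap by a random d in {1..9, 11..30}.
    """
    chrom, start, end, _ = source_interval
    if n_pairs < 1:
        raise ValueError("n_pairs must be >= 1")
    lo, hi = cfg.pirna_length_range
    if end - start < hi + 31:
        raise ValueError("source interval too short for ping-pong pairs")
    rng = np.random.default_rng(cfg.seed)
    off_d = np.array([d for d in range(1, 31) if d != 10])
    reads: list[SmallRNARead] = []
    for i in range(n_pairs):
        d = 10 if rng.random() < cfg.pingpong_pair_fraction else int(rng.choice(off_d))
        l_plus = int(rng.integers(lo, hi + 1))
        l_minus = int(rng.integers(lo, hi + 1))
        p = int(rng.integers(start + hi, end - hi - 30))
        q = p + d - 1  # minus-strand 5' coordinate
        plus_seq = _apply_u1(_extract(genome, chrom, p, p + l_plus, "+"), rng, cfg.u1_bias)
        minus_seq = _apply_u1(
            _extract(genome, chrom, q - l_minus + 1, q + 1, "-"), rng, cfg.u1_bias
        )
        reads.append(SmallRNARead(f"{id_prefix}{i}s", plus_seq))
        reads.append(SmallRNARead(f"{id_prefix}{i}a", minus_seq))
    return reads


def simulate_mirnas(
    mirnas: list[MirnaLocus], n: int, seed: int, id_prefix: str = "mir"
) -> list[SmallRNARead]:
    """Mature miRNA reads: exact annotated sequences, Dirichlet abundances."""
    if not mirnas:
        raise ValueError("empty miRNA annotation")
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    weights = rng.dirichlet(np.full(len(mirnas), 2.0))
    counts = rng.multinomial(n, weights)
    return [
        SmallRNARead(f"{id_prefix}.{m.name}", m.mature_sequence, int(c))
        for m, c in zip(mirnas, counts)
        if c > 0
    ]


def simulate_sirnas(
    source_interval: SourceInterval,
    n: int,
    cfg: SimConfig,
    genome: dict[str, str],
    id_prefix: str = "si",
) -> list[SmallRNARead]:
    """Exactly 21-nt siRNAs from both strands of a double-stranded region."""
    chrom, start, end, _ = source_interval
    L = cfg.sirna_length
    if end - start < L:
        raise ValueError("interval shorter than siRNA length")
    rng = np.random.default_rng(cfg.seed)
    reads = []
    for i in range(n):
        s = int(rng.integers(start, end - L + 1))
        strand = "+" if rng.random() < 0.5 else "-"
        reads.append(SmallRNARead(f"{id_prefix}{i}", _extract(genome, chrom, s, s + L, strand)))
    return reads


def simulate_dna_reads(
    genome: dict[str, str],
    coverage: float,
    read_length: int,
    seed: int,
    id_prefix: str = "dna",
) -> list[SmallRNARead]:
    """Uniform single-end genomic DNA reads at the requested fold-coverage."""
    if coverage <= 0:
        raise ValueError("coverage must be > 0")
    rng = np.random.default_rng(seed)
    reads = []
    k = 0
    for chrom in sorted(genome):
        seq = genome[chrom]
        n = int(round(coverage * len(seq) / read_length))
        starts = rng.integers(0, len(seq) - read_length + 1, size=n)
        strands = rng.random(n) < 0.5
        for s, minus in zip(starts, strands):
            frag = seq[s : s + read_length]
            reads.append(SmallRNARead(f"{id_prefix}{k}", revcomp(frag) if minus else frag))
            k += 1
    return reads


# ---------------------------------------------------------------------------
# position-level library models (signature calibration at scale)
# ---------------------------------------------------------------------------


def _alignment_frame(rows) -> "pd.DataFrame":
    import pandas as pd

    from .mapping import ALIGNMENT_COLUMNS

    return pd.DataFrame(rows, columns=ALIGNMENT_COLUMNS)


def unistrand_alignment_table(n: int, cfg: SimConfig, ref_name: str = "locus"):
    """Alignment table of a phased single-strand library, built directly at
    the position level (single unbounded pass along the precursor).

    Bypasses sequence emission and mapping; used to calibrate the phasing
    statistic over many replicates where the read-level round trip is
    redundant.
    """
    rng = np.random.default_rng(cfg.seed)
    lo, hi = cfg.pirna_length_range
    rows = []
    for i, (t, ell) in enumerate(_phased_walk(rng, n, lo, hi, cfg.phasing_tightness)):
        rows.append((f"u{i}", ref_name, t, t + ell, "+", 0, True, 1, ell, 1.0))
    return _alignment_frame(rows)


def pingpong_alignment_table(
    n_pairs: int, cfg: SimConfig, region_length: int = 2000, ref_name: str = "locus"
):
    """Alignment table of sense/antisense 10-nt-overlap pairs at the
    position level (see `simulate_pingpong_pirnas` for the read-level op)."""
    rng = np.random.default_rng(cfg.seed)
    lo, hi = cfg.pirna_length_range
    off_d = np.array([d for d in range(1, 31) if d != 10])
    rows = []
    for i in range(n_pairs):
        d = 10 if rng.random() < cfg.pingpong_pair_fraction else int(rng.choice(off_d))
        l1 = int(rng.integers(lo, hi + 1))
        l2 = int(rng.integers(lo, hi + 1))
        p = int(rng.integers(hi, region_length - hi - 30))
        q = p + d - 1
        rows.append((f"p{i}s", ref_name, p, p + l1, "+", 0, True, 1, l1, 1.0))
        rows.append((f"p{i}a", ref_name, q - l2 + 1, q + 1, "-", 0, True, 1, l2, 1.0))
    return _alignment_frame(rows)


def null_alignment_table(
    n: int,
    seed: int,
    region_length: int = 300_000,
    lengths: tuple[int, int] = (23, 32),
    strand_symmetric: bool = True,
    ref_name: str = "locus",
):
    """Uniform-random 5'-position library: the null for both signatures.

    Strand-symmetric for the ping-pong null; single-strand for a
    no-phasing-structure null. The default region length keeps the 5'-end
    density sparse (~0.03 starts/nt), matching weakly covered source loci.
    """
    rng = np.random.default_rng(seed)
    lo, hi = lengths
    rows = []
    for i in range(n):
        ell = int(rng.integers(lo, hi + 1))
        s = int(rng.integers(0, region_length - ell))
        strand = "+" if (not strand_symmetric or rng.random() < 0.5) else "-"
        rows.append((f"n{i}", ref_name, s, s + ell, strand, 0, True, 1, ell, 1.0))
    return _alignment_frame(rows)


def add_linker(
    reads: list[SmallRNARead], adapter: str, n_random: int = 4, seed: int = 0
) -> list[SmallRNARead]:
    """Raw mode: append the randomised linker nucleotides plus the 3' adapter."""
    rng = np.random.default_rng(seed)
    out = []
    for r in reads:
        linker = random_sequence(rng, n_random)
        out.append(SmallRNARead(r.id, r.sequence + linker + adapter, r.copies))
    return out
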