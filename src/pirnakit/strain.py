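"""A complete synthetic strain: the end-to-end study conditions.

The strain mirrors the configuration the analytics were built to resolve:

* ``soma_te`` — an invading retrovirus-like element with (i) an *antisense*
  insertion in a host gene's 3' UTR carrying a 752-nt internal deletion,
  which acts as a unistrand piRNA source (piRNAs are transcribed with the
  host mRNA, hence antisense to the TE, phased, soma-style, not maternally
  deposited), and (ii) a second, full-length, piRNA-silent copy elsewhere.
  The deletion junction and the downstream 3'-UTR flank are the insertion's
  genome-unique diagnostic handle.
* ``germ_te`` — a germline-type element whose single insertion produces
  weak, bidirectional ping-pong piRNAs that are maternally deposited.
* six germline-exclusive reference TEs (Burdock, F-element, DOC, I-element,
  mdg3, flea) with ping-pong piRNAs in ovary and embryo, anchoring the
  maternal-deposition index.
* miRNA loci supplying the normalisation class, and uniform genomic DNA
  reads for copy-number estimation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .models import (
    GeneModel,
    InsertionSpec,
    ReferenceSet,
    SimConfig,
    SmallRNARead,
)
from .simulate import (
    build_toy_genome,
    random_consensus,
    simulate_dna_reads,
    simulate_mirnas,
    simulate_pingpong_pirnas,
    simulate_unistrand_pirnas,
)

REFERENCE_TE_NAMES = ("Burdock", "F-element", "DOC", "I-element", "mdg3", "flea")

SOMA_TE = "soma_te"
GERM_TE = "germ_te"
INTERNAL_DELETION = (600, 1352)  # 752 nt in consensus coordinates


def _child_seed(seed: int, k: int) -> int:
    return (seed * 1_000_003 + k) % (2**31)


@dataclass
class SyntheticStrain:
    refset: ReferenceSet
    utr_insertion: InsertionSpec  # soma_te in the host 3' UTR (source)
    silent_insertion: InsertionSpec  # soma_te full-length, piRNA-dead
    germ_insertion: InsertionSpec  # germ_te dual-strand source
    host_gene: GeneModel
    seed: int

    @property
    def chrom(self) -> str:
        return self.utr_insertion.chrom


def build_synthetic_strain(
    seed: int,
    utr_orientation: str = "antisense",
    te_length: int = 2000,
    reference_te_length: int = 1000,
    background_length: int = 46_000,
) -> SyntheticStrain:
    """Assemble the strain genome and annotations for one seed."""
    rng = np.random.default_rng(_child_seed(seed, 1))
    chrom = "chr2R"
    soma = random_consensus(rng, SOMA_TE, te_length)
    germ = random_consensus(rng, GERM_TE, te_length)
    refs = [random_consensus(rng, name, reference_te_length) for name in REFERENCE_TE_NAMES]

    host = GeneModel("host_gene", chrom, 5000, 12_000, "+", 9000, 12_000)
    insertions = [
        InsertionSpec(
            SOMA_TE, chrom, 10_000, orientation=utr_orientation, context="gene_3utr",
            internal_deletion=INTERNAL_DELETION,
        ),
        InsertionSpec(SOMA_TE, chrom, 18_000, orientation="sense", context="intergenic"),
        InsertionSpec(GERM_TE, chrom, 22_000, orientation="sense", context="intergenic"),
    ] + [
        InsertionSpec(name, chrom, 26_000 + 3000 * i, orientation="sense", context="intergenic")
        for i, name in enumerate(REFERENCE_TE_NAMES)
    ]
    refset = build_toy_genome(
        [soma, germ] + refs,
        insertions,
        [host],
        seed=_child_seed(seed, 2),
        chrom_lengths={chrom: background_length},
    )
    utr_ins, silent_ins, germ_ins = refset.insertions[:3]
    return SyntheticStrain(refset, utr_ins, silent_ins, germ_ins, refset.genes[0], seed)


def simulate_ovary_library(
    strain: SyntheticStrain,
    n_unistrand: int = 2500,
    n_germ_pairs: int = 400,
    n_reference_pairs: int = 250,
    n_mirna: int = 20_000,
    base_cfg: SimConfig | None = None,
) -> list[SmallRNARead]:
    """Ovarian Argonaute-bound small-RNA library for the strain.

    The unistrand source transcribes from the host gene's strand through
    the (antisense) insertion and its downstream 3' UTR; germline-type
    sources emit ping-pong pairs.
    """
    base = base_cfg or SimConfig()
    genome = strain.refset.genome
    chrom = strain.chrom
    host = strain.host_gene
    reads: list[SmallRNARead] = []

    precursor = (chrom, strain.utr_insertion.start, host.end, host.strand)
    cfg = SimConfig(
        seed=_child_seed(strain.seed, 3),
        antisense_fraction=0.97,
        u1_bias=base.u1_bias,
        phasing_tightness=base.phasing_tightness,
        pirna_length_range=base.pirna_length_range,
    )
    if n_unistrand > 0:
        reads += simulate_unistrand_pirnas(precursor, n_unistrand, cfg, genome, id_prefix="soma")

    g = strain.germ_insertion
    cfg_g = SimConfig(
        seed=_child_seed(strain.seed, 4),
        pingpong_pair_fraction=base.pingpong_pair_fraction,
        u1_bias=base.u1_bias,
        pirna_length_range=base.pirna_length_range,
    )
    if n_germ_pairs > 0:
        reads += simulate_pingpong_pirnas(
            (chrom, g.start, g.end, "+"), n_germ_pairs, cfg_g, genome, id_prefix="germ"
        )

    for i, ins in enumerate(strain.refset.insertions[3:]):
        cfg_r = SimConfig(
            seed=_child_seed(strain.seed, 10 + i),
            pingpong_pair_fraction=base.pingpong_pair_fraction,
            u1_bias=base.u1_bias,
            pirna_length_range=base.pirna_length_range,
        )
        reads += simulate_pingpong_pirnas(
            (chrom, ins.start, ins.end, "+"), n_reference_pairs, cfg_r, genome,
            id_prefix=f"ref{i}",
        )

    reads += simulate_mirnas(strain.refset.mirnas, n_mirna, _child_seed(strain.seed, 5))
    return reads


def simulate_embryo_library(
    strain: SyntheticStrain,
    n_germ_pairs: int = 400,
    n_reference_pairs: int = 250,
    n_mirna: int = 20_000,
    base_cfg: SimConfig | None = None,
) -> list[SmallRNARead]:
    """Early-embryo library: maternally deposited germline piRNAs only.

    Germline-type sources (germ_te and the reference TEs) are deposited;
    the somatic unistrand source contributes nothing.
    """
    base = base_cfg or SimConfig()
    genome = strain.refset.genome
    chrom = strain.chrom
    reads: list[SmallRNARead] = []
    g = strain.germ_insertion
    cfg_g = SimConfig(
        seed=_child_seed(strain.seed, 6),
        pingpong_pair_fraction=base.pingpong_pair_fraction,
        u1_bias=base.u1_bias,
        pirna_length_range=base.pirna_length_range,
    )
    if n_germ_pairs > 0:
        reads += simulate_pingpong_pirnas(
            (chrom, g.start, g.end, "+"), n_germ_pairs, cfg_g, genome, id_prefix="egerm"
        )
    for i, ins in enumerate(strain.refset.insertions[3:]):
        cfg_r = SimConfig(
            seed=_child_seed(strain.seed, 20 + i),
            pingpong_pair_fraction=base.pingpong_pair_fraction,
            u1_bias=base.u1_bias,
            pirna_length_range=base.pirna_length_range,
        )
        reads += simulate_pingpong_pirnas(
            (chrom, ins.start, ins.end, "+"), n_reference_pairs, cfg_r, genome,
            id_prefix=f"eref{i}",
        )
    reads += simulate_mirnas(strain.refset.mirnas, n_mirna, _child_seed(strain.seed, 7))
    return reads


def simulate_genomic_library(
    strain: SyntheticStrain, coverage: float = 30.0, read_length: int = 100
) -> list[SmallRNARead]:
    return simulate_dna_reads(
        strain.refset.genome, coverage, read_length, _child_seed(strain.seed, 8)
    )


def build_copy_number_genome(
    n_insertions: int,
    seed: int,
    te_length: int = 2000,
    background_length: int = 40_000,
) -> ReferenceSet:
    """Toy genome with n full-length copies of one TE, for copy-number
    recovery experiments."""
    rng = np.random.default_rng(_child_seed(seed, 30))
    te = random_consensus(rng, "focal_te", te_length)
    # insertions confined to the first 60% of the background so that clean
    # single-copy windows remain available for the coverage baseline
    region = int(background_length * 0.6)
    spacing = region // (n_insertions + 1)
    insertions = [
        InsertionSpec("focal_te", "chrA", spacing * (i + 1), orientation="sense")
        for i in range(n_insertions)
    ]
    return build_toy_genome(
        [te], insertions, [], seed=_child_seed(seed, 31),
        chrom_lengths={"chrA": background_length}, n_mirna=0,
    )
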