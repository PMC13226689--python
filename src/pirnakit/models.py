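"""Core domain types shared across the toolkit.

Coordinates are 0-based half-open everywhere in memory; BED dialect on disk.
Strand symbols are ``"+"`` and ``"-"``. Sequences are uppercase DNA (ACGT,
with N tolerated only in raw reads).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import yaml

VALID_ALPHABET = set("ACGT")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    """Reverse complement of an uppercase DNA string."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class TEConsensus:
    """A transposable-element consensus sequence.

    All consensus-level quantification and density profiles are computed
    against these sequences, one per TE family.
    """

    name: str
    sequence: str

    def __post_init__(self) -> None:
        if len(self.sequence) < 200:
            raise ValueError(
                f"consensus {self.name!r} is {len(self.sequence)} nt; minimum is 200"
            )
        bad = set(self.sequence) - VALID_ALPHABET
        if bad:
            raise ValueError(f"consensus {self.name!r} contains non-ACGT symbols {bad}")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class InsertionSpec:
    """One TE insertion in a (toy or real) genome.

    ``orientation`` is recorded relative to host-gene transcription when the
    insertion sits inside an annotated gene, and relative to the plus strand
    otherwise. ``genome_strand`` is the strand of the genome on which the TE
    consensus reads 5'->3'; it is filled in by the toy-genome builder.
    ``internal_deletion`` is a half-open interval in consensus coordinates.
    """

    te_name: str
    chrom: str
    start: int
    end: int = -1  # filled by the builder: start + inserted length
    orientation: str = "sense"  # {"sense", "antisense"}
    context: str = "intergenic"  # {"cluster", "gene_3utr", "intergenic"}
    internal_deletion: Optional[tuple[int, int]] = None
    genome_strand: str = "+"
    host_gene: Optional[str] = None

    def __post_init__(self) -> None:
        if self.orientation not in ("sense", "antisense"):
            raise ValueError(f"bad orientation {self.orientation!r}")
        if self.context not in ("cluster", "gene_3utr", "intergenic"):
            raise ValueError(f"bad context {self.context!r}")

    def inserted_length(self, consensus_length: int) -> int:
        if self.internal_deletion is None:
            return consensus_length
        d0, d1 = self.internal_deletion
        if not (0 <= d0 < d1 <= consensus_length):
            raise ValueError(
                f"internal deletion [{d0},{d1}) outside consensus [0,{consensus_length})"
            )
        return consensus_length - (d1 - d0)


@dataclass
class GeneModel:
    """A protein-coding gene with an annotated 3' UTR interval."""

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str
    utr3_start: int
    utr3_end: int

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"bad strand {self.strand!r}")
        if not (self.start <= self.utr3_start < self.utr3_end <= self.end):
            raise ValueError("3' UTR interval must lie within the gene")


@dataclass
class MirnaLocus:
    name: str
    chrom: str
    start: int
    end: int
    strand: str
    mature_sequence: str


@dataclass
class SmallRNARead:
    """A (possibly collapsed) small-RNA read."""

    id: str
    sequence: str
    copies: int = 1

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class SimConfig:
    """Parameters of the synthetic small-RNA / genomic-DNA library generator.

    The defaults describe an ovarian Argonaute-bound library: piRNAs of
    23-32 nt with a strong 5' U preference, a dominant antisense strand for
    unistrand (follicle-cell type) sources, tight head-to-tail phasing, and a
    majority of ping-pong pairs at germline-type sources. ``seed`` fully
    determines every emitted read.
    """

    seed: int = 0
    n_pirna_reads: int = 10_000
    n_mirna_reads: int = 20_000
    n_sirna_reads: int = 0
    n_dna_read_pairs: int = 0
    pirna_length_range: tuple[int, int] = (23, 32)
    sirna_length: int = 21
    antisense_fraction: float = 1.0
    u1_bias: float = 0.75
    pingpong_pair_fraction: float = 0.8
    phasing_tightness: float = 0.8
    dna_coverage: float = 30.0

    def __post_init__(self) -> None:
        for name in (
            "antisense_fraction",
            "u1_bias",
            "pingpong_pair_fraction",
            "phasing_tightness",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        lo, hi = self.pirna_length_range
        if not 0 < lo <= hi:
            raise ValueError(f"bad pirna_length_range {self.pirna_length_range}")

    def with_seed(self, seed: int) -> "SimConfig":
        return replace(self, seed=seed)

    @classmethod
    def from_yaml(cls, path) -> "SimConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if "pirna_length_range" in data:
            data["pirna_length_range"] = tuple(data["pirna_length_range"])
        return cls(**data)

    def to_yaml(self, path) -> None:
        data = self.__dict__.copy()
        data["pirna_length_range"] = list(self.pirna_length_range)
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=False)


@dataclass
class ReferenceSet:
    """Toy genome plus every annotation the pipeline consumes."""

    genome: dict[str, str]
    te_consensi: dict[str, TEConsensus]
    insertions: list[InsertionSpec] = field(default_factory=list)
    genes: list[GeneModel] = field(default_factory=list)
    unique_regions: list[tuple[str, int, int]] = field(default_factory=list)
    mirnas: list[MirnaLocus] = field(default_factory=list)

    def chrom_length(self, chrom: str) -> int:
        return len(self.genome[chrom])

    def fetch(self, chrom: str, start: int, end: int, strand: str = "+") -> str:
        seq = self.genome[chrom][start:end]
        return seq if strand == "+" else revcomp(seq)
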