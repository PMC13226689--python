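"""On-disk interchange: FASTA/FASTQ, BED6, GFF3 (gene + 3' UTR subset), bedGraph.

FASTA goes through Biopython; the tabular formats are plain TSV dialects and
are read/written with pandas. FASTQ qualities are uniform Phred+33 ``I``
(the simulator does not model base quality).
"""

from __future__ import annotations

import os
from typing import Iterable

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .models import (
    GeneModel,
    InsertionSpec,
    MirnaLocus,
    ReferenceSet,
    SmallRNARead,
    TEConsensus,
)

BED6_COLUMNS = ["chrom", "start", "end", "name", "score", "strand"]


def read_fasta(path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(sequences: dict[str, str], path) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in sequences.items()]
    SeqIO.write(records, str(path), "fasta")


def read_reads(path) -> list[SmallRNARead]:
    """Read small-RNA reads from FASTQ or FASTA (by extension).

    Collapsed-FASTA headers of the form ``id_xN`` carry multiplicity N.
    """
    path = str(path)
    fmt = "fastq" if path.endswith((".fastq", ".fq")) else "fasta"
    reads = []
    for rec in SeqIO.parse(path, fmt):
        copies = 1
        rid = rec.id
        if fmt == "fasta" and "_x" in rid:
            head, _, tail = rid.rpartition("_x")
            if tail.isdigit():
                rid, copies = head, int(tail)
        reads.append(SmallRNARead(rid, str(rec.seq).upper().replace("U", "T"), copies))
    return reads


def write_fastq(reads: Iterable[SmallRNARead], path) -> None:
    with open(path, "w") as fh:
        for r in reads:
            for i in range(r.copies):
                rid = r.id if r.copies == 1 else f"{r.id}.{i}"
                fh.write(f"@{rid}\n{r.sequence}\n+\n{'I' * len(r.sequence)}\n")


def write_collapsed_fasta(reads: Iterable[SmallRNARead], path) -> None:
    with open(path, "w") as fh:
        for r in reads:
            fh.write(f">{r.id}_x{r.copies}\n{r.sequence}\n")


def read_bed6(path) -> pd.DataFrame:
    df = pd.read_csv(
        str(path), sep="\t", header=None, names=BED6_COLUMNS, comment="#", dtype={"chrom": str}
    )
    return df


def write_bed6(df: pd.DataFrame, path) -> None:
    df.loc[:, BED6_COLUMNS].to_csv(str(path), sep="\t", header=False, index=False)


def insertions_to_bed(insertions: list[InsertionSpec]) -> pd.DataFrame:
    rows = []
    for ins in insertions:
        name = f"{ins.te_name}|{ins.context}|{ins.orientation}"
        if ins.internal_deletion is not None:
            name += f"|del:{ins.internal_deletion[0]}-{ins.internal_deletion[1]}"
        rows.append((ins.chrom, ins.start, ins.end, name, 0, ins.genome_strand))
    return pd.DataFrame(rows, columns=BED6_COLUMNS)


def mirnas_to_bed(mirnas: list[MirnaLocus]) -> pd.DataFrame:
    rows = [(m.chrom, m.start, m.end, m.name, 0, m.strand) for m in mirnas]
    return pd.DataFrame(rows, columns=BED6_COLUMNS)


def write_gff3(genes: list[GeneModel], path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            fh.write(
                f"{g.chrom}\tpirnakit\tgene\t{g.start + 1}\t{g.end}\t.\t{g.strand}\t.\t"
                f"ID={g.gene_id}\n"
            )
            fh.write(
                f"{g.chrom}\tpirnakit\tthree_prime_UTR\t{g.utr3_start + 1}\t{g.utr3_end}\t.\t"
                f"{g.strand}\t.\tParent={g.gene_id}\n"
            )


def read_gff3(path) -> list[GeneModel]:
    cols = ["chrom", "source", "type", "start", "end", "score", "strand", "phase", "attributes"]
    df = pd.read_csv(str(path), sep="\t", header=None, names=cols, comment="#", dtype={"chrom": str})

    def attr(s: str, key: str) -> str:
        for part in s.split(";"):
            k, _, v = part.partition("=")
            if k == key:
                return v
        raise KeyError(f"attribute {key} missing in {s!r}")

    utr_by_gene = {}
    for _, row in df[df["type"] == "three_prime_UTR"].iterrows():
        utr_by_gene[attr(row["attributes"], "Parent")] = (int(row.start) - 1, int(row.end))
    genes = []
    for _, row in df[df["type"] == "gene"].iterrows():
        gid = attr(row["attributes"], "ID")
        u0, u1 = utr_by_gene.get(gid, (int(row.start) - 1, int(row.end)))
        genes.append(
            GeneModel(gid, row.chrom, int(row.start) - 1, int(row.end), row.strand, u0, u1)
        )
    return genes


def write_bedgraph(values: np.ndarray, chrom: str, path, mode: str = "w") -> None:
    """Write a per-base vector as a run-length-compressed bedGraph track."""
    values = np.asarray(values, dtype=float)
    with open(path, mode) as fh:
        if len(values) == 0:
            return
        change = np.flatnonzero(np.diff(values)) + 1
        starts = np.concatenate(([0], change))
        ends = np.concatenate((change, [len(values)]))
        for s, e in zip(starts, ends):
            v = values[s]
            if v != 0.0:
                fh.write(f"{chrom}\t{s}\t{e}\t{v:.6g}\n")


def write_reference_set(refset: ReferenceSet, outdir) -> dict[str, str]:
    """Serialise a ReferenceSet to a directory; returns the path map."""
    os.makedirs(outdir, exist_ok=True)
    paths = {
        "genome": os.path.join(outdir, "genome.fa"),
        "te_consensus": os.path.join(outdir, "te_consensus.fa"),
        "insertions": os.path.join(outdir, "insertions.bed"),
        "genes": os.path.join(outdir, "genes.gff3"),
        "unique_regions": os.path.join(outdir, "unique_regions.bed"),
        "mirnas": os.path.join(outdir, "mirnas.bed"),
    }
    write_fasta(refset.genome, paths["genome"])
    write_fasta({n: te.sequence for n, te in refset.te_consensi.items()}, paths["te_consensus"])
    write_bed6(insertions_to_bed(refset.insertions), paths["insertions"])
    write_gff3(refset.genes, paths["genes"])
    uniq = pd.DataFrame(
        [(c, s, e, f"uniq{i}", 0, "+") for i, (c, s, e) in enumerate(refset.unique_regions)],
        columns=BED6_COLUMNS,
    )
    write_bed6(uniq, paths["unique_regions"])
    write_bed6(mirnas_to_bed(refset.mirnas), paths["mirnas"])
    return paths


def load_reference_set(
    genome_fa, te_fa, insertions_bed=None, genes_gff3=None, unique_bed=None, mirnas_bed=None
) -> ReferenceSet:
    genome = read_fasta(genome_fa)
    te = {n: TEConsensus(n, s) for n, s in read_fasta(te_fa).items()}
    insertions: list[InsertionSpec] = []
    if insertions_bed is not None:
        for _, row in read_bed6(insertions_bed).iterrows():
            fields = str(row["name"]).split("|")
            te_name = fields[0]
            context = fields[1] if len(fields) > 1 else "intergenic"
            orientation = fields[2] if len(fields) > 2 else "sense"
            deletion = None
            for f in fields[3:]:
                if f.startswith("del:"):
                    a, _, b = f[4:].partition("-")
                    deletion = (int(a), int(b))
            insertions.append(
                InsertionSpec(
                    te_name,
                    row["chrom"],
                    int(row["start"]),
                    int(row["end"]),
                    orientation,
                    context,
                    deletion,
                    genome_strand=row["strand"],
                )
            )
    genes = read_gff3(genes_gff3) if genes_gff3 is not None else []
    unique_regions = []
    if unique_bed is not None:
        for _, row in read_bed6(unique_bed).iterrows():
            unique_regions.append((row["chrom"], int(row["start"]), int(row["end"])))
    mirnas = []
    if mirnas_bed is not None:
        for _, row in read_bed6(mirnas_bed).iterrows():
            seq = genome[row["chrom"]][int(row["start"]) : int(row["end"])]
            if row["strand"] == "-":
                from .models import revcomp

                seq = revcomp(seq)
            mirnas.append(
                MirnaLocus(row["name"], row["chrom"], int(row["start"]), int(row["end"]), row["strand"], seq)
            )
    return ReferenceSet(genome, te, insertions, genes, unique_regions, mirnas)
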