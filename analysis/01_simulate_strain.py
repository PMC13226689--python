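#!/usr/bin/env python
"""Build the synthetic strain and write its references and read libraries.

The strain carries an antisense TE insertion (752-nt internal deletion) in a
host gene 3' UTR, a silent full-length copy of the same TE, a dual-strand
germline-type source, and six germline reference TEs. Ovary, embryo and
genomic-DNA libraries are emitted for the downstream steps.
"""

import os

from pirnakit.io import write_fastq, write_reference_set
from pirnakit.strain import (
    build_synthetic_strain,
    simulate_embryo_library,
    simulate_genomic_library,
    simulate_ovary_library,
)

OUT = os.path.join("results", "analysis", "01_simulate")
SEED = 1


def main() -> None:
    strain = build_synthetic_strain(seed=SEED)
    paths = write_reference_set(strain.refset, OUT)
    ovary = simulate_ovary_library(strain)
    embryo = simulate_embryo_library(strain)
    dna = simulate_genomic_library(strain)
    write_fastq(ovary, os.path.join(OUT, "ovary.fastq"))
    write_fastq(embryo, os.path.join(OUT, "embryo.fastq"))
    write_fastq(dna, os.path.join(OUT, "dna.fastq"))

    ins = strain.utr_insertion
    print(f"genome: {sum(len(s) for s in strain.refset.genome.values())} nt, "
          f"{len(strain.refset.insertions)} insertions, {len(strain.refset.mirnas)} miRNA loci")
    print(f"unistrand source: {ins.te_name} {ins.chrom}:{ins.start}-{ins.end} "
          f"({ins.orientation} in {ins.host_gene} 3' UTR, deletion {ins.internal_deletion})")
    print(f"libraries: ovary={len(ovary)} embryo={len(embryo)} dna={len(dna)} reads")
    print(f"references written to {paths['genome']}")


if __name__ == "__main__":
    main()
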