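import numpy as np
import pytest

from pirnakit import NormalizationFactor, map_reads
from pirnakit.strain import build_synthetic_strain, simulate_ovary_library
from pirnakit.trim import collapse_reads


@pytest.fixture(scope="session")
def strain1():
    """One synthetic strain: antisense 3'-UTR unistrand source (752-nt
    internal deletion), a silent full-length copy, a dual-strand germline
    source, and six germline reference TEs."""
    return build_synthetic_strain(seed=1)


@pytest.fixture(scope="session")
def ovary1(strain1):
    """Ovary library of strain1 plus its genome/consensus alignments and
    the miRNA normalisation factor."""
    reads = simulate_ovary_library(strain1)
    mirna_count = sum(r.copies for r in reads if r.id.startswith("mir"))
    collapsed = collapse_reads(reads)
    refset = strain1.refset
    genome_aln = map_reads(collapsed, refset.genome)
    te_aln = map_reads(collapsed, refset.te_consensi)
    return {
        "reads": reads,
        "genome_aln": genome_aln,
        "te_aln": te_aln,
        "norm": NormalizationFactor(mirna_count),
    }


@pytest.fixture()
def rng():
    return np.random.default_rng(20260101)
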