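"""TE copy number from genomic read depth.

Genomic DNA reads are aligned (fractional weighting) both to the TE
consensus sequences and to the genome; the estimate is the median per-base
consensus coverage divided by the median per-base coverage over designated
genome-unique regions. The consensus median includes zero-coverage
positions by default, which keeps internally deleted or diverged copies
from inflating the estimate.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .coverage import coverage_track
from .models import TEConsensus


@dataclass
class CopyNumberEstimate:
    te_name: str
    median_te_coverage: float
    median_unique_coverage: float
    estimate: Optional[float]


def unique_region_coverage(
    genome_alignments: pd.DataFrame,
    unique_regions: list[tuple[str, int, int]],
    chrom_lengths: dict[str, int],
    weighting: str = "fractional",
) -> np.ndarray:
    """Concatenated per-base coverage over all genome-unique intervals."""
    if not unique_regions:
        raise ValueError("empty unique-region set")
    chunks = []
    for chrom in sorted({c for c, _, _ in unique_regions}):
        track = coverage_track(genome_alignments, chrom, chrom_lengths[chrom], weighting)
        for c, s, e in unique_regions:
            if c == chrom:
                chunks.append(track[s:e])
    return np.concatenate(chunks)


def estimate_copy_number(
    consensus_alignments: pd.DataFrame,
    te_consensi: dict[str, TEConsensus],
    unique_coverage: np.ndarray,
    weighting: str = "fractional",
    include_zero_positions: bool = True,
) -> dict[str, CopyNumberEstimate]:
    """Median-coverage copy-number estimate per TE.

    Both tracks must come from the same read set and weighting. The estimate
    is missing when the unique-region median is zero (no usable baseline).
    """
    if len(unique_coverage) == 0:
        raise ValueError("empty unique-region coverage")
    med_unique = float(np.median(unique_coverage))
    out = {}
    for name, te in te_consensi.items():
        track = coverage_track(consensus_alignments, name, len(te), weighting)
        if not include_zero_positions:
            track = track[track > 0]
        med_te = float(np.median(track)) if len(track) else 0.0
        est = med_te / med_unique if med_unique > 0 else None
        out[name] = CopyNumberEstimate(name, med_te, med_unique, est)
    return out


def copy_number_table(estimates: dict[str, CopyNumberEstimate]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "te_name": e.te_name,
                "median_te_coverage": e.median_te_coverage,
                "median_unique_coverage": e.median_unique_coverage,
                "copy_number": e.estimate if e.estimate is not None else float("nan"),
            }
            for e in estimates.values()
        ]
    )
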