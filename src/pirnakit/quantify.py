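"""miRNA-normalised piRNA quantification.

Levels are expressed in PPM (reads per one million sequenced miRNAs) and,
for per-TE summaries, in thousand reads per kb per million miRNAs —
the heatmap unit used for antisense piRNA levels of >= 23 nt.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .coverage import alignment_weights, coverage_track, five_prime_track
from .models import TEConsensus

#: germline-exclusive TEs used to anchor the maternal-deposition ratio
DEFAULT_REFERENCE_TES = ("Burdock", "F-element", "DOC", "I-element", "mdg3", "flea")


@dataclass(frozen=True)
class NormalizationFactor:
    """Scale raw read counts to reads per one million sequenced miRNAs."""

    mirna_reads: int

    def __post_init__(self) -> None:
        if self.mirna_reads <= 0:
            raise ValueError("mirna_reads must be > 0")

    @property
    def scale(self) -> float:
        return 1_000_000 / self.mirna_reads


@dataclass
class DensityProfile:
    """Per-position sense/antisense piRNA density over a reference, in PPM."""

    ref_name: str
    sense: np.ndarray
    antisense: np.ndarray
    mode: str = "coverage"  # or "five_prime"

    def to_frame(self) -> pd.DataFrame:
        """Tabular export; antisense carries the negative-sign convention."""
        return pd.DataFrame(
            {
                "position": np.arange(len(self.sense)),
                "sense_ppm": self.sense,
                "antisense_ppm": -self.antisense,
            }
        )


@dataclass
class DepositionIndex:
    """Maternal-deposition index: embryo/ovary level ratio, self-normalised
    to the median ratio of germline-exclusive reference TEs. An index near 1
    marks deposition typical of germline piRNAs; near 0, a somatic-only
    source. Missing when the TE has no ovarian piRNAs."""

    te_name: str
    ovary_ppm: float
    embryo_ppm: float
    index: Optional[float]


def _length_strand_filter(
    alignments: pd.DataFrame, strand: str, min_len: int, max_len: int
) -> pd.DataFrame:
    sub = alignments[(alignments["length"] >= min_len) & (alignments["length"] <= max_len)]
    if strand == "sense":
        sub = sub[sub["strand"] == "+"]
    elif strand == "antisense":
        sub = sub[sub["strand"] == "-"]
    elif strand != "both":
        raise ValueError(f"strand must be sense/antisense/both, got {strand!r}")
    return sub


def te_pirna_ppm(
    alignments: pd.DataFrame,
    te: TEConsensus,
    norm: NormalizationFactor,
    strand: str = "antisense",
    min_len: int = 23,
    max_len: int = 32,
    weighting: str = "fractional",
) -> float:
    """Weighted read count on the consensus in PPM."""
    sub = _length_strand_filter(
        alignments[alignments["ref_name"] == te.name], strand, min_len, max_len
    )
    return float(alignment_weights(sub, weighting).sum() * norm.scale)


def te_pirna_level(
    alignments: pd.DataFrame,
    te: TEConsensus,
    norm: NormalizationFactor,
    strand: str = "antisense",
    min_len: int = 23,
    max_len: int = 32,
    weighting: str = "fractional",
) -> float:
    """piRNA level in thousand reads per kb per one million miRNAs."""
    if len(te) == 0:
        raise ValueError("zero-length reference")
    ppm = te_pirna_ppm(alignments, te, norm, strand, min_len, max_len, weighting)
    return ppm / (len(te) / 1000) / 1000


def density_profile(
    alignments: pd.DataFrame,
    reference: TEConsensus,
    norm: NormalizationFactor,
    mode: str = "coverage",
    weighting: str = "fractional",
    min_len: int = 0,
    max_len: int = 10_000,
) -> DensityProfile:
    """Sense/antisense density along a reference, in PPM per position."""
    if mode not in ("coverage", "five_prime"):
        raise ValueError(f"mode must be coverage or five_prime, got {mode!r}")
    track = coverage_track if mode == "coverage" else five_prime_track
    sub = alignments[
        (alignments["length"] >= min_len) & (alignments["length"] <= max_len)
    ]
    sense = track(sub, reference.name, len(reference), weighting, strand="+") * norm.scale
    anti = track(sub, reference.name, len(reference), weighting, strand="-") * norm.scale
    return DensityProfile(reference.name, sense, anti, mode)


def deposition_index(
    ovary_levels: dict[str, float],
    embryo_levels: dict[str, float],
    reference_tes: tuple[str, ...] = DEFAULT_REFERENCE_TES,
) -> dict[str, DepositionIndex]:
    """Embryo/ovary deposition index per TE, anchored on germline TEs.

    The reference statistic is the *median* embryo/ovary ratio across the
    germline-exclusive TEs (robust to one noisy reference). At least three
    reference TEs must have nonzero levels in both tissues.
    """
    ratios = []
    for te in reference_tes:
        o = ovary_levels.get(te, 0.0)
        e = embryo_levels.get(te, 0.0)
        if o > 0 and e > 0:
            ratios.append(e / o)
    if len(ratios) < 3:
        raise ValueError(
            f"only {len(ratios)} of {len(reference_tes)} reference TEs usable; need >= 3"
        )
    ref_ratio = float(np.median(ratios))
    out = {}
    for te, o in ovary_levels.items():
        e = embryo_levels.get(te, 0.0)
        idx = (e / o) / ref_ratio if o > 0 else None
        out[te] = DepositionIndex(te, o, e, idx)
    return out
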