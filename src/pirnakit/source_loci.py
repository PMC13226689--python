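"""Per-insertion piRNA-source calls and per-TE origin classification.

An individual insertion is judged from *genome-unique* reads only: reads
inside the insertion's diagnostic (single-copy) segments and in flanking
windows. A unistrand source shows a strong strand bias with phased piRNAs
extending into the downstream flank (the antisense-3'-UTR / flamenco
configuration); a dual-strand (germline-type) source shows weaker,
bidirectional reads. Classification thresholds are package policy with
documented defaults — the underlying biology is qualitative.

``antisense_fraction`` is measured relative to the inserted TE's genomic
orientation (reads antisense to the TE are the silencing-competent
species); the host-gene annotation orients the insertion itself.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .models import GeneModel, InsertionSpec
from .quantify import DepositionIndex, NormalizationFactor
from .signatures import SignatureResult, phasing_zscore, pingpong_zscore


@dataclass
class CallParams:
    """Thresholds for insertion-level and TE-level classification."""

    flank_window: int = 2000  # nt each side of the insertion
    min_len: int = 23  # piRNA length range: excludes miRNAs (22 nt) and
    max_len: int = 32  # siRNAs (21 nt) from insertion-level quantities
    antisense_min: float = 0.8  # unistrand strand-bias requirement
    dual_min_fraction: float = 0.2  # per-strand minimum for dual-strand
    min_read_weight: float = 20.0  # below this: silent / undetermined
    min_pairs: float = 100.0  # histogram support for a Z-score
    deposition_somatic_max: float = 0.2
    deposition_germline_range: tuple[float, float] = (0.5, 2.0)


@dataclass
class InsertionCall:
    insertion: InsertionSpec
    flank_window: int
    unique_ppm_inside: float
    unique_ppm_up: float
    unique_ppm_down: float
    antisense_fraction: float
    phasing: SignatureResult
    pingpong: SignatureResult
    call: str  # {"unistrand_source", "dualstrand_source", "silent"}
    host_gene: Optional[str]
    orientation: str


@dataclass
class OriginCall:
    te_name: str
    antisense_fraction: float
    pingpong: SignatureResult
    phasing: SignatureResult
    deposition: Optional[DepositionIndex]
    origin: str  # {"somatic", "germline", "mixed", "undetermined"}
    flags: list[str] = field(default_factory=list)


def _transcription_strand(ins: InsertionSpec, genes: list[GeneModel]) -> str:
    """Strand along which the piRNA precursor is expected to run: the host
    gene's strand inside genes, the plus strand otherwise."""
    if ins.host_gene is not None:
        for g in genes:
            if g.gene_id == ins.host_gene:
                return g.strand
    for g in genes:
        if g.chrom == ins.chrom and g.start <= ins.start and ins.end <= g.end:
            return g.strand
    return "+"


def _orientation(ins: InsertionSpec, tx_strand: str, annotated: bool) -> str:
    if annotated:
        return "sense" if ins.genome_strand == tx_strand else "antisense"
    return "sense" if ins.genome_strand == "+" else "antisense"


def call_insertion(
    insertion: InsertionSpec,
    genome_unique_alignments: pd.DataFrame,
    gene_models: list[GeneModel],
    norm: NormalizationFactor,
    params: CallParams | None = None,
    chrom_length: int | None = None,
) -> InsertionCall:
    """Classify one insertion as unistrand source, dual-strand source, or
    silent, from genome-unique alignments only.

    Multi-mapping reads never contribute: any non-unique rows in the input
    are discarded up front. Flanks extend ``flank_window`` nt each side;
    "downstream" follows the host gene's transcription (plus strand for
    intergenic insertions). Signature statistics are computed over the
    insertion plus its downstream flank.
    """
    params = params or CallParams()
    if chrom_length is not None and (insertion.start < 0 or insertion.end > chrom_length):
        raise ValueError(
            f"insertion {insertion.te_name} at {insertion.chrom}:{insertion.start}-"
            f"{insertion.end} outside genome bounds"
        )
    aln = genome_unique_alignments
    aln = aln[
        aln["unique"]
        & (aln["ref_name"] == insertion.chrom)
        & (aln["length"] >= params.min_len)
        & (aln["length"] <= params.max_len)
    ]

    host = next(
        (
            g.gene_id
            for g in gene_models
            if g.chrom == insertion.chrom and g.start <= insertion.start and insertion.end <= g.end
        ),
        None,
    )
    tx = _transcription_strand(insertion, gene_models)
    orientation = _orientation(insertion, tx, annotated=host is not None)

    fw = params.flank_window
    s, e = insertion.start, insertion.end
    left = (max(s - fw, 0), s)
    right = (e, e + fw)
    up, down = (left, right) if tx == "+" else (right, left)

    def weight_in(lo: int, hi: int) -> float:
        m = (aln["start"] < hi) & (aln["end"] > lo)
        return float(aln.loc[m, "copies"].sum())

    w_inside = weight_in(s, e)
    w_up = weight_in(*up)
    w_down = weight_in(*down)

    # strand bias relative to the TE: reads on the strand opposite the TE's
    # genomic orientation are antisense to the element
    span = aln[(aln["start"] < max(right[1], e)) & (aln["end"] > min(left[0], s))]
    total_w = float(span["copies"].sum())
    anti_w = float(span.loc[span["strand"] != insertion.genome_strand, "copies"].sum())
    anti_frac = anti_w / total_w if total_w > 0 else 0.0

    sig_lo, sig_hi = (s, e + fw) if tx == "+" else (s - fw, e)
    sig = aln[(aln["start"] >= sig_lo) & (aln["end"] <= sig_hi)]
    phasing = phasing_zscore(sig, min_pairs=params.min_pairs)
    pingpong = pingpong_zscore(sig, min_pairs=params.min_pairs)

    call = "silent"
    if total_w >= params.min_read_weight:
        both_strands = (
            total_w > 0
            and anti_frac >= params.dual_min_fraction
            and (1 - anti_frac) >= params.dual_min_fraction
        )
        if anti_frac >= params.antisense_min and w_down > 0 and phasing.significant:
            call = "unistrand_source"
        elif both_strands:
            call = "dualstrand_source"

    return InsertionCall(
        insertion=insertion,
        flank_window=fw,
        unique_ppm_inside=w_inside * norm.scale,
        unique_ppm_up=w_up * norm.scale,
        unique_ppm_down=w_down * norm.scale,
        antisense_fraction=anti_frac,
        phasing=phasing,
        pingpong=pingpong,
        call=call,
        host_gene=host,
        orientation=orientation,
    )


def classify_origin(
    te_name: str,
    sense_level: float,
    antisense_level: float,
    pingpong: SignatureResult,
    phasing: SignatureResult,
    deposition: Optional[DepositionIndex] = None,
    params: CallParams | None = None,
) -> OriginCall:
    """Classify a TE's overall piRNA origin as somatic, germline, mixed or
    undetermined.

    Somatic: antisense-dominant, phased, no ping-pong, and (when embryo data
    exist) a deposition index below threshold. Germline: significant
    ping-pong, or a deposition index near 1. Both lines of evidence: mixed.
    Without embryo data the decision is made from signatures alone and
    flagged ``no-embryo``.
    """
    params = params or CallParams()
    flags: list[str] = []
    total = sense_level + antisense_level
    anti_frac = antisense_level / total if total > 0 else 0.0
    dep_index = deposition.index if deposition is not None else None
    if deposition is None:
        flags.append("no-embryo")

    if total == 0:
        return OriginCall(te_name, 0.0, pingpong, phasing, deposition, "undetermined", flags)

    lo, hi = params.deposition_germline_range
    somatic_ev = (
        anti_frac >= params.antisense_min
        and phasing.significant
        and pingpong.tier in ("ns", "NA")
        and (dep_index is None or dep_index < params.deposition_somatic_max)
    )
    germline_ev = pingpong.significant or (dep_index is not None and lo <= dep_index <= hi)

    if somatic_ev and germline_ev:
        origin = "mixed"
    elif somatic_ev:
        origin = "somatic"
    elif germline_ev:
        origin = "germline"
    else:
        origin = "undetermined"
    return OriginCall(te_name, anti_frac, pingpong, phasing, deposition, origin, flags)


def promoter_distance_report(
    insertions: list[InsertionSpec],
    cluster_tss: int,
    genome_unique_alignments: pd.DataFrame,
    norm: NormalizationFactor,
    cluster_strand: str = "+",
    flank_window: int = 2000,
    min_len: int = 23,
    max_len: int = 32,
) -> pd.DataFrame:
    """Distance of each cluster insertion from the cluster promoter vs its
    downstream unique piRNA output (for monotonic-trend inspection).

    Insertions upstream of the TSS get a negative distance and are flagged
    excluded from the trend.
    """
    aln = genome_unique_alignments
    aln = aln[aln["unique"] & (aln["length"] >= min_len) & (aln["length"] <= max_len)]
    rows = []
    for ins in insertions:
        if cluster_strand == "+":
            dist = ins.start - cluster_tss
            lo, hi = ins.start, ins.end + flank_window
        else:
            dist = cluster_tss - ins.end
            lo, hi = ins.start - flank_window, ins.end
        sub = aln[
            (aln["ref_name"] == ins.chrom) & (aln["start"] < hi) & (aln["end"] > lo)
        ]
        level = float(sub["copies"].sum()) * norm.scale
        rows.append(
            {
                "te_name": ins.te_name,
                "chrom": ins.chrom,
                "start": ins.start,
                "end": ins.end,
                "distance_to_tss": dist,
                "downstream_unique_ppm": level,
                "in_trend": dist >= 0,
            }
        )
    return pd.DataFrame(rows)
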