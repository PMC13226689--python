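"""Ping-pong and phasing signature statistics.

The ping-pong signature is an excess of sense/antisense piRNA pairs whose 5'
ends overlap by exactly 10 nt (reciprocal slicer cleavage leaves a 10-nt
offset). The phasing signature is an excess of same-strand 3'-to-5'
distances of exactly 1 nt (head-to-tail processive cleavage). Both are
scored as a Z of the focal bin against the empirical background bins of the
same histogram, with a one-sided normal P and the usual significance tiers
(ns, *, **, ***). Pair weights multiply per-position 5'-end multiplicities
(positions, not reads, are the unit).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats as sps

from .coverage import alignment_weights
from .mapping import five_prime_positions, three_prime_positions

PINGPONG_FOCAL = 10
PHASING_FOCAL = 1
DEFAULT_MIN_PAIRS = 100


@dataclass
class OverlapHistogram:
    """counts[d-1] for d in 1..d_max: weight of sense/antisense 5'-end pairs
    overlapping by d nt (d = q - p + 1 for plus 5' at p, minus 5' at q)."""

    counts: np.ndarray
    focal_d: int = PINGPONG_FOCAL

    @property
    def d_values(self) -> np.ndarray:
        return np.arange(1, len(self.counts) + 1)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"overlap": self.d_values, "pairs": self.counts})


@dataclass
class PhasingHistogram:
    """counts[d-1] for d in 1..d_max: weight of same-strand 3'-to-nearest-
    downstream-5' distances of d nt (d = 1 means immediately adjacent)."""

    counts: np.ndarray
    focal_d: int = PHASING_FOCAL

    @property
    def d_values(self) -> np.ndarray:
        return np.arange(1, len(self.counts) + 1)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"distance": self.d_values, "pairs": self.counts})


@dataclass
class SignatureResult:
    zscore: Optional[float]
    pvalue: Optional[float]
    tier: str  # {"ns", "*", "**", "***", "NA"}
    n_pairs: float
    pingpong_percent: Optional[float] = None

    @property
    def significant(self) -> bool:
        return self.tier in ("*", "**", "***")


def _tier(p: float) -> str:
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"


def _five_prime_weights(alignments: pd.DataFrame, weighting: str):
    w = alignment_weights(alignments, weighting)
    pos = five_prime_positions(alignments)
    plus = alignments["strand"].to_numpy() == "+"
    return pos, w, plus


def overlap_histogram(
    alignments: pd.DataFrame,
    ref_name: str | None = None,
    weighting: str = "fractional",
    d_max: int = 30,
) -> OverlapHistogram:
    """5'-overlap histogram between plus- and minus-strand read 5' ends."""
    sub = alignments if ref_name is None else alignments[alignments["ref_name"] == ref_name]
    pos, w, plus = _five_prime_weights(sub, weighting)
    counts = np.zeros(d_max)
    if len(pos) == 0 or plus.all() or (~plus).all():
        return OverlapHistogram(counts)
    lo = int(pos.min())
    hi = int(pos.max())
    n = hi - lo + 1 + d_max
    wp = np.zeros(n)
    wm = np.zeros(n)
    np.add.at(wp, pos[plus] - lo, w[plus])
    np.add.at(wm, pos[~plus] - lo, w[~plus])
    for d in range(1, d_max + 1):
        # minus 5' at q = p + d - 1
        counts[d - 1] = float(np.dot(wp[: n - (d - 1)], wm[d - 1 :]))
    return OverlapHistogram(counts)


def phasing_histogram(
    alignments: pd.DataFrame,
    ref_name: str | None = None,
    weighting: str = "fractional",
    d_max: int = 50,
) -> PhasingHistogram:
    """Same-strand 3'-to-nearest-downstream-5' distance histogram.

    Computed independently per strand (coordinates mirrored on minus so
    "downstream" follows transcription), then summed across strands.
    """
    sub = alignments if ref_name is None else alignments[alignments["ref_name"] == ref_name]
    w = alignment_weights(sub, weighting)
    p5 = five_prime_positions(sub)
    p3 = three_prime_positions(sub)
    plus = sub["strand"].to_numpy() == "+"
    counts = np.zeros(d_max)
    for sel, sign in ((plus, 1), (~plus, -1)):
        if not sel.any():
            continue
        _accumulate_phasing(sign * p5[sel], sign * p3[sel], w[sel], counts, d_max)
    return PhasingHistogram(counts)


def _accumulate_phasing(p5, p3, w, counts, d_max):
    # aggregate weights per position
    pos5, inv5 = np.unique(p5, return_inverse=True)
    w5 = np.bincount(inv5, weights=w)
    pos3, inv3 = np.unique(p3, return_inverse=True)
    w3 = np.bincount(inv3, weights=w)
    # nearest strictly-downstream 5' end for each 3' end
    idx = np.searchsorted(pos5, pos3 + 1, side="left")
    ok = idx < len(pos5)
    d = pos5[idx[ok]] - pos3[ok]
    keep = d <= d_max
    np.add.at(counts, d[keep] - 1, w3[ok][keep] * w5[idx[ok]][keep])


def zscore(
    histogram,
    focal_d: int | None = None,
    min_pairs: float = DEFAULT_MIN_PAIRS,
) -> SignatureResult:
    """Z of the focal bin against the remaining (background) bins.

    Z = (counts[focal] - mean(background)) / sd(background), with the sample
    standard deviation over all non-focal bins; one-sided P = 1 - Phi(Z).
    Reported missing (tier "NA") when the background sd is zero or fewer
    than ``min_pairs`` pairs support the histogram — insufficient piRNAs
    for calculation.
    """
    focal = focal_d if focal_d is not None else histogram.focal_d
    counts = np.asarray(histogram.counts, dtype=float)
    if not 1 <= focal <= len(counts):
        raise ValueError(f"focal_d={focal} outside histogram range 1..{len(counts)}")
    background = np.delete(counts, focal - 1)
    if len(background) < 2:
        raise ValueError("histogram needs >= 2 background bins")
    total = float(counts.sum())
    sd = float(background.std(ddof=1))
    if sd == 0.0 or total < min_pairs:
        return SignatureResult(None, None, "NA", total)
    z = (counts[focal - 1] - background.mean()) / sd
    p = float(sps.norm.sf(z))
    return SignatureResult(float(z), p, _tier(p), total)


def pingpong_zscore(
    alignments: pd.DataFrame,
    ref_name: str | None = None,
    weighting: str = "fractional",
    d_max: int = 30,
    min_pairs: float = DEFAULT_MIN_PAIRS,
) -> SignatureResult:
    res = zscore(overlap_histogram(alignments, ref_name, weighting, d_max), PINGPONG_FOCAL, min_pairs)
    res.pingpong_percent = pingpong_percent(alignments, ref_name, weighting)
    return res


def phasing_zscore(
    alignments: pd.DataFrame,
    ref_name: str | None = None,
    weighting: str = "fractional",
    d_max: int = 50,
    min_pairs: float = DEFAULT_MIN_PAIRS,
) -> SignatureResult:
    return zscore(phasing_histogram(alignments, ref_name, weighting, d_max), PHASING_FOCAL, min_pairs)


def pingpong_percent(
    alignments: pd.DataFrame,
    ref_name: str | None = None,
    weighting: str = "fractional",
) -> float:
    """Percentage of read weight whose 5' end has an opposite-strand 5' end
    at overlap exactly 10."""
    sub = alignments if ref_name is None else alignments[alignments["ref_name"] == ref_name]
    pos, w, plus = _five_prime_weights(sub, weighting)
    total = float(w.sum())
    if total == 0.0:
        return 0.0
    minus_pos = set(pos[~plus].tolist())
    plus_pos = set(pos[plus].tolist())
    partnered = 0.0
    for p, wi, is_plus in zip(pos, w, plus):
        if is_plus:
            if p + PINGPONG_FOCAL - 1 in minus_pos:
                partnered += wi
        else:
            if p - PINGPONG_FOCAL + 1 in plus_pos:
                partnered += wi
    return 100.0 * partnered / total


def nt_bias(reads) -> dict[str, float]:
    """U1 and A10 positional base fractions (copies-weighted) — standard
    piRNA QC: primary piRNAs favour a 5' U, ping-pong responders an A at
    position 10."""
    total = 0
    u1 = 0
    a10 = 0
    for r in reads:
        if len(r.sequence) < 10:
            continue
        total += r.copies
        if r.sequence[0] == "T":
            u1 += r.copies
        if r.sequence[9] == "A":
            a10 += r.copies
    if total == 0:
        raise ValueError("no reads of >= 10 nt")
    return {"U1": u1 / total, "A10": a10 / total}


# ---------------------------------------------------------------------------
# quadratic oracles (tests and cross-checks only)
# ---------------------------------------------------------------------------


def overlap_histogram_allpairs(
    alignments: pd.DataFrame, weighting: str = "fractional", d_max: int = 30
) -> OverlapHistogram:
    """O(n^2) all-pairs reimplementation of `overlap_histogram`."""
    pos, w, plus = _five_prime_weights(alignments, weighting)
    counts = np.zeros(d_max)
    for i in np.flatnonzero(plus):
        for j in np.flatnonzero(~plus):
            d = pos[j] - pos[i] + 1
            if 1 <= d <= d_max:
                counts[d - 1] += w[i] * w[j]
    return OverlapHistogram(counts)


def phasing_histogram_allpairs(
    alignments: pd.DataFrame, weighting: str = "fractional", d_max: int = 50
) -> PhasingHistogram:
    """O(n^2) all-pairs reimplementation of `phasing_histogram`."""
    w = alignment_weights(alignments, weighting)
    p5 = five_prime_positions(alignments)
    p3 = three_prime_positions(alignments)
    plus = alignments["strand"].to_numpy() == "+"
    counts = np.zeros(d_max)
    for sel, sign in ((plus, 1), (~plus, -1)):
        if not sel.any():
            continue
        q5, q3, qw = sign * p5[sel], sign * p3[sel], w[sel]
        pos5 = np.unique(q5)
        w5 = {p: qw[q5 == p].sum() for p in pos5}
        for e in np.unique(q3):
            w3 = qw[q3 == e].sum()
            downstream = pos5[pos5 > e]
            if len(downstream) == 0:
                continue
            s = downstream.min()
            d = s - e
            if d <= d_max:
                counts[d - 1] += w3 * w5[s]
    return PhasingHistogram(counts)
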