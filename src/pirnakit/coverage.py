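"""Per-base coverage tracks from alignment tables.

Two weighting disciplines: ``fractional`` spreads a read's multiplicity
1/k over its k best-stratum placements (consensus-level quantification);
``unique_only`` counts only unique placements at full multiplicity
(genome-level source attribution).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

WEIGHTINGS = ("fractional", "unique_only")


def alignment_weights(alignments: pd.DataFrame, weighting: str) -> np.ndarray:
    if weighting == "fractional":
        return alignments["weight"].to_numpy(dtype=float)
    if weighting == "unique_only":
        return np.where(
            alignments["unique"].to_numpy(), alignments["copies"].to_numpy(dtype=float), 0.0
        )
    raise ValueError(f"weighting must be one of {WEIGHTINGS}, got {weighting!r}")


def coverage_track(
    alignments: pd.DataFrame,
    ref_name: str,
    ref_length: int,
    weighting: str = "fractional",
    strand: str | None = None,
) -> np.ndarray:
    """Per-base coverage over one reference; optional strand restriction."""
    sub = alignments[alignments["ref_name"] == ref_name]
    if strand is not None:
        sub = sub[sub["strand"] == strand]
    w = alignment_weights(sub, weighting)
    delta = np.zeros(ref_length + 1)
    np.add.at(delta, np.clip(sub["start"].to_numpy(int), 0, ref_length), w)
    np.add.at(delta, np.clip(sub["end"].to_numpy(int), 0, ref_length), -w)
    return np.cumsum(delta[:-1])


def five_prime_track(
    alignments: pd.DataFrame,
    ref_name: str,
    ref_length: int,
    weighting: str = "fractional",
    strand: str | None = None,
) -> np.ndarray:
    """Weighted 5'-end start counts per position (read-start track)."""
    from .mapping import five_prime_positions

    sub = alignments[alignments["ref_name"] == ref_name]
    if strand is not None:
        sub = sub[sub["strand"] == strand]
    w = alignment_weights(sub, weighting)
    track = np.zeros(ref_length)
    pos = five_prime_positions(sub)
    ok = (pos >= 0) & (pos < ref_length)
    np.add.at(track, pos[ok], w[ok])
    return track
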