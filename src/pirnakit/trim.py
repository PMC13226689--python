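"""Adapter/linker trimming and read collapsing.

Library structure: ``insert + N*n_random + adapter``, where the random
nucleotides come from the 5' end of the pre-adenylated DNA linker. Trimming
locates the leftmost adapter occurrence (prefix match of >= 8 nt with at
most one mismatch), then removes the adapter together with the ``n_random``
nucleotides immediately 5' of it.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

from .models import SmallRNARead

MIN_ADAPTER_MATCH = 8


@dataclass
class TrimStats:
    passed: int = 0
    no_adapter: int = 0
    too_short: int = 0
    too_long: int = 0
    reasons: Counter = field(default_factory=Counter)


def _find_adapter(seq: str, adapter: str) -> int:
    """Leftmost start of an adapter occurrence (>=8 nt prefix, <=1 mismatch);
    -1 if absent."""
    n = len(seq)
    for i in range(0, n - MIN_ADAPTER_MATCH + 1):
        m = min(len(adapter), n - i)
        mism = 0
        for a, b in zip(seq[i : i + m], adapter[:m]):
            if a != b:
                mism += 1
                if mism > 1:
                    break
        if mism <= 1:
            return i
    return -1


def trim_adapter_and_random_nt(
    reads: list[SmallRNARead],
    adapter: str,
    n_random: int = 4,
    min_len: int = 18,
    max_len: int = 35,
) -> tuple[list[SmallRNARead], TrimStats]:
    """Trim the 3' adapter and randomised linker nucleotides; length-filter.

    Reads without a detectable adapter are dropped and tallied; trimmed
    inserts outside [min_len, max_len] are dropped with a logged reason.
    """
    if n_random < 0:
        raise ValueError("n_random must be >= 0")
    if len(adapter) < MIN_ADAPTER_MATCH:
        raise ValueError(f"adapter must be >= {MIN_ADAPTER_MATCH} nt")
    stats = TrimStats()
    out: list[SmallRNARead] = []
    for r in reads:
        i = _find_adapter(r.sequence, adapter)
        if i < 0:
            stats.no_adapter += r.copies
            stats.reasons["no_adapter"] += r.copies
            continue
        insert = r.sequence[: max(i - n_random, 0)]
        if len(insert) < min_len:
            stats.too_short += r.copies
            stats.reasons["too_short"] += r.copies
        elif len(insert) > max_len:
            stats.too_long += r.copies
            stats.reasons["too_long"] += r.copies
        else:
            stats.passed += r.copies
            out.append(SmallRNARead(r.id, insert, r.copies))
    return out, stats


def collapse_reads(reads: list[SmallRNARead]) -> list[SmallRNARead]:
    """Collapse identical sequences, summing multiplicities.

    Collapsing commutes with mapping: aligning collapsed reads and weighting
    by ``copies`` gives the same coverage/signature mass as aligning each
    read separately.
    """
    agg: dict[str, int] = {}
    for r in reads:
        agg[r.sequence] = agg.get(r.sequence, 0) + r.copies
    return [SmallRNARead(f"c{i}", seq, n) for i, (seq, n) in enumerate(agg.items())]
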