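"""Exact / low-mismatch small-read alignment with best-stratum semantics.

For each read, every placement in the best stratum (the minimum achievable
mismatch count, capped at ``max_mismatches``) on either strand of any
reference is reported; a read is *unique* iff that stratum holds exactly one
placement across all references searched. No indels (piRNA-scale reads on
consensus/toy references do not need them).

Exact placements are found with C-level substring scans; reads without an
exact hit fall back to pigeonhole seeding (a placement with <= m mismatches
must contain at least one of m+1 exact read segments), with candidate
offsets verified by direct comparison. An N in a read mismatches every
reference base.
"""

from __future__ import annotations

import functools

import numpy as np
import pandas as pd

from .models import SmallRNARead, TEConsensus, revcomp

ALIGNMENT_COLUMNS = [
    "read_id",
    "ref_name",
    "start",
    "end",
    "strand",
    "mismatches",
    "unique",
    "copies",
    "length",
    "weight",
]

def _normalise_references(references) -> list[tuple[str, str]]:
    if isinstance(references, dict):
        items = list(references.items())
    else:
        items = list(references)
    out = []
    for item in items:
        if isinstance(item, TEConsensus):
            out.append((item.name, item.sequence))
        elif isinstance(item, tuple):
            name, seq = item
            out.append((name, seq if isinstance(seq, str) else seq.sequence))
        else:
            raise TypeError(f"cannot interpret reference {item!r}")
    if not out:
        raise ValueError("references must be non-empty")
    return out


_INDEX_THRESHOLD = 20_000  # above this, occurrence queries go through a k-mer index
_SEED_K = 7


@functools.lru_cache(maxsize=8)
def _kmer_index(ref: str, k: int) -> dict[str, list[int]]:
    index: dict[str, list[int]] = {}
    for i in range(len(ref) - k + 1):
        index.setdefault(ref[i : i + k], []).append(i)
    return index


def _occurrences(ref: str, query: str) -> list[int]:
    """All start positions of exact occurrences of ``query`` in ``ref``."""
    if not query or "N" in query:
        return []
    if len(ref) >= _INDEX_THRESHOLD and len(query) >= _SEED_K:
        index = _kmer_index(ref, _SEED_K)
        return [
            i for i in index.get(query[:_SEED_K], []) if ref.startswith(query, i)
        ]
    out = []
    i = ref.find(query)
    while i >= 0:
        out.append(i)
        i = ref.find(query, i + 1)
    return out


def _count_mismatches(query: str, ref: str, start: int, limit: int) -> int:
    mm = 0
    for a, b in zip(query, ref[start : start + len(query)]):
        if a != b or a == "N" or b == "N":
            mm += 1
            if mm > limit:
                break
    return mm


def _exact_hits(seq: str, refs: list[tuple[str, str]]):
    hits = []
    L = len(seq)
    rc = revcomp(seq)
    for name, ref in refs:
        for query, strand in ((seq, "+"), (rc, "-")):
            for i in _occurrences(ref, query):
                hits.append((name, i, i + L, strand, 0))
    return hits


def _seeded_hits(seq: str, refs: list[tuple[str, str]], max_mismatches: int):
    """All placements with mismatches <= max_mismatches.

    Pigeonhole: split the query into max_mismatches+1 segments; any placement
    within the budget matches at least one segment exactly, so enumerating
    segment occurrences enumerates every candidate offset.
    """
    L = len(seq)
    k = max_mismatches + 1
    if L < k:
        return []
    bounds = [round(i * L / k) for i in range(k + 1)]
    hits = []
    for name, ref in refs:
        if len(ref) < L:
            continue
        for query, strand in ((seq, "+"), (revcomp(seq), "-")):
            candidates = set()
            for b0, b1 in zip(bounds, bounds[1:]):
                for i in _occurrences(ref, query[b0:b1]):
                    cand = i - b0
                    if 0 <= cand <= len(ref) - L:
                        candidates.add(cand)
            for cand in candidates:
                mm = _count_mismatches(query, ref, cand, max_mismatches)
                if mm <= max_mismatches:
                    hits.append((name, cand, cand + L, strand, mm))
    return hits


def map_reads(
    reads: list[SmallRNARead],
    references,
    max_mismatches: int = 2,
    with_unmapped: bool = False,
):
    """Align reads to references; return a best-stratum alignment table.

    Returns a DataFrame with one row per placement (columns
    ``ALIGNMENT_COLUMNS``); ``weight = copies / k`` for a read with k
    best-stratum placements (fractional multi-mapper weighting). With
    ``with_unmapped=True`` also returns the list of unmapped reads.
    """
    refs = _normalise_references(references)
    cache: dict[str, list] = {}
    rows = []
    unmapped: list[SmallRNARead] = []
    skipped: list[SmallRNARead] = []
    for r in reads:
        seq = r.sequence
        if set(seq) - set("ACGTN"):
            skipped.append(r)
            continue
        if seq in cache:
            hits = cache[seq]
        else:
            hits = [] if "N" in seq else _exact_hits(seq, refs)
            if not hits and max_mismatches > 0:
                hits = _seeded_hits(seq, refs, max_mismatches)
                if hits:
                    best = min(h[4] for h in hits)
                    hits = [h for h in hits if h[4] == best]
            cache[seq] = hits
        if not hits:
            unmapped.append(r)
            continue
        uniq = len(hits) == 1
        w = r.copies / len(hits)
        for name, s, e, strand, mm in hits:
            rows.append((r.id, name, s, e, strand, mm, uniq, r.copies, len(seq), w))
    df = pd.DataFrame(rows, columns=ALIGNMENT_COLUMNS)
    if with_unmapped:
        return df, unmapped
    return df


def brute_force_map(
    reads: list[SmallRNARead], references, max_mismatches: int = 2
) -> pd.DataFrame:
    """Independent oracle: per-offset mismatch counting over every reference,
    offset, and strand; best stratum kept. Quadratic; for small fixtures."""
    refs = _normalise_references(references)
    rows = []
    for r in reads:
        if set(r.sequence) - set("ACGTN"):
            continue
        hits = []
        for name, ref in refs:
            for strand in "+-":
                query = r.sequence if strand == "+" else revcomp(r.sequence)
                for i in range(len(ref) - len(query) + 1):
                    mm = sum(
                        1
                        for a, b in zip(query, ref[i : i + len(query)])
                        if a != b or a == "N" or b == "N"
                    )
                    if mm <= max_mismatches:
                        hits.append((name, i, i + len(query), strand, mm))
        if not hits:
            continue
        best = min(h[4] for h in hits)
        hits = [h for h in hits if h[4] == best]
        uniq = len(hits) == 1
        for name, s, e, strand, mm in hits:
            rows.append(
                (r.id, name, s, e, strand, mm, uniq, r.copies, len(r.sequence), r.copies / len(hits))
            )
    return pd.DataFrame(rows, columns=ALIGNMENT_COLUMNS)


def five_prime_positions(alignments: pd.DataFrame) -> np.ndarray:
    """0-based 5'-end coordinate per alignment row (start on +, end-1 on -)."""
    plus = alignments["strand"].to_numpy() == "+"
    return np.where(plus, alignments["start"].to_numpy(), alignments["end"].to_numpy() - 1)


def three_prime_positions(alignments: pd.DataFrame) -> np.ndarray:
    """0-based 3'-end coordinate per alignment row (end-1 on +, start on -)."""
    plus = alignments["strand"].to_numpy() == "+"
    return np.where(plus, alignments["end"].to_numpy() - 1, alignments["start"].to_numpy())


def alignments_to_bed(alignments: pd.DataFrame) -> pd.DataFrame:
    """BED6 export: name = read id, score = mismatch count."""
    return pd.DataFrame(
        {
            "chrom": alignments["ref_name"],
            "start": alignments["start"],
            "end": alignments["end"],
            "name": alignments["read_id"],
            "score": alignments["mismatches"],
            "strand": alignments["strand"],
        }
    )
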