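"""Read-level filters: quality filter, 3' adapter trimming, length filter,
and collapsing to unique sequences.

The stage order is fixed: quality -> trim -> length -> collapse.  The
quality rule keeps a read iff at least a fraction ``p`` of its bases reach
Phred ``q`` (FASTX ``-q 20 -p 80`` semantics, with >= on both thresholds).
Adapter matching is 3'-anchored with cutadapt-style semantics: the best
(longest) occurrence of the adapter — full, or a prefix reaching the read
end — with a mismatch fraction at or below ``error_rate`` is removed
together with everything 3' of it.  Bases called N never count toward the
quality numerator but are otherwise retained.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Iterator

from .io_formats import ReadRecord

#: TruSeq small-RNA 3' adapter.
DEFAULT_ADAPTER = "TGGAATTCTCGGGTGCCAAGG"


@dataclass(frozen=True, slots=True)
class CollapsedRead:
    """A unique surviving sequence and its occurrence count in the sample."""

    sequence: str
    multiplicity: int


def quality_filter(
    reads: Iterable[ReadRecord], q: int = 20, p: float = 0.80
) -> Iterator[ReadRecord]:
    """Yield reads whose fraction of bases at Phred >= ``q`` is >= ``p``.

    N bases count toward the denominator but never the numerator.  Empty
    reads are rejected with a warning.
    """
    for read in reads:
        n = len(read.sequence)
        if n == 0:
            warnings.warn(f"rejecting empty read {read.read_id!r}")
            continue
        good = sum(
            1
            for base, score in zip(read.sequence, read.qualities)
            if base != "N" and score >= q
        )
        if good / n >= p:
            yield read


def trim_adapter(
    read: ReadRecord,
    adapter: str = DEFAULT_ADAPTER,
    error_rate: float = 0.1,
    min_overlap: int = 3,
) -> ReadRecord:
    """Remove the best 3'-anchored adapter occurrence from ``read``.

    Scans candidate start positions 5'->3'; the first position where the
    adapter (or its prefix reaching the read end) matches with at most
    ``floor(error_rate * overlap)`` mismatches wins, which selects the
    longest admissible overlap.  Qualities are truncated in step.  If no
    admissible occurrence exists the read is returned unchanged.
    """
    if not adapter:
        raise ValueError("adapter must be non-empty")
    seq = read.sequence
    n, m = len(seq), len(adapter)
    for i in range(0, n - min_overlap + 1):
        overlap = min(m, n - i)
        allowed = int(error_rate * overlap)
        mismatches = 0
        ok = True
        for a, b in zip(seq[i : i + overlap], adapter):
            if a != b:
                mismatches += 1
                if mismatches > allowed:
                    ok = False
                    break
        if ok:
            return ReadRecord(read.read_id, seq[:i], read.qualities[:i])
    return read


def length_filter(reads: Iterable[ReadRecord], min_len: int = 15) -> Iterator[ReadRecord]:
    """Yield reads of length >= ``min_len`` (applied after trimming)."""
    for read in reads:
        if len(read.sequence) >= min_len:
            yield read


def collapse(reads: Iterable[ReadRecord]) -> list[CollapsedRead]:
    """Collapse reads to unique sequences with occurrence counts.

    Ordered by multiplicity descending, ties broken lexicographically by
    sequence, so output is deterministic for any input order.
    """
    tally: dict[str, int] = {}
    for read in reads:
        tally[read.sequence] = tally.get(read.sequence, 0) + 1
    return [
        CollapsedRead(seq, mult)
        for seq, mult in sorted(tally.items(), key=lambda kv: (-kv[1], kv[0]))
    ]


def preprocess_sample(
    reads: Iterable[ReadRecord],
    adapter: str = DEFAULT_ADAPTER,
    min_quality: int = 20,
    min_quality_fraction: float = 0.80,
    min_length: int = 15,
    error_rate: float = 0.1,
    min_overlap: int = 3,
) -> tuple[list[CollapsedRead], dict[str, int]]:
    """Run the full read-level pipeline on one sample.

    Returns the collapsed reads plus a per-stage count log
    (input / after_quality / after_length / unique_sequences).
    """
    reads = list(reads)
    stats = {"input": len(reads)}
    surviving = list(quality_filter(reads, q=min_quality, p=min_quality_fraction))
    stats["after_quality"] = len(surviving)
    trimmed = [trim_adapter(r, adapter, error_rate, min_overlap) for r in surviving]
    kept = list(length_filter(trimmed, min_len=min_length))
    stats["after_length"] = len(kept)
    collapsed = collapse(kept)
    stats["unique_sequences"] = len(collapsed)
    stats["surviving_mass"] = sum(c.multiplicity for c in collapsed)
    return collapsed, stats
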