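"""Read filtering and size-distribution summaries for small-RNA libraries.

Raw reads are screened in a fixed rule order — quality, ambiguous bases,
adapter, length — and each rejected read is charged to the first rule it
fails, so the rejection counts partition the rejected set.  Collapsed
libraries are then floored at a minimum read count to suppress sequences
likely to arise from sequencing error.
"""

from __future__ import annotations

import dataclasses
from collections import Counter
from typing import Sequence

from .seq_io import CollapsedRead, SequenceRecord

REJECTION_ORDER = ("quality", "ambiguous", "adapter", "length")


@dataclasses.dataclass(frozen=True)
class FilterConfig:
    """Filtering thresholds for raw small-RNA reads.

    Defaults follow common small-RNA practice: mean Phred >= 20, read length
    18-32 nt after adapter removal, and a collapsed-count floor of 5 reads.
    """

    min_quality: int = 20
    min_len: int = 18
    max_len: int = 32
    adapter: str | None = None
    min_reads: int = 5
    quality_mode: str = "mean"  # "mean" or "min"

    def __post_init__(self) -> None:
        if self.min_len > self.max_len:
            raise ValueError("min_len must be <= max_len")
        if self.min_quality < 0:
            raise ValueError("min_quality must be >= 0")
        if self.min_reads < 1:
            raise ValueError("min_reads must be >= 1")
        if self.quality_mode not in ("mean", "min"):
            raise ValueError("quality_mode must be 'mean' or 'min'")


def _passes_quality(rec: SequenceRecord, config: FilterConfig) -> bool:
    if config.min_quality == 0:
        return True
    if rec.qualities is None:
        raise ValueError(
            f"read {rec.id!r} has no qualities but min_quality={config.min_quality}"
        )
    if config.quality_mode == "mean":
        return sum(rec.qualities) / len(rec.qualities) >= config.min_quality
    return min(rec.qualities) >= config.min_quality


def trim_adapter(rec: SequenceRecord, adapter: str) -> tuple[SequenceRecord, bool]:
    """Trim a 3' adapter by exact-prefix search.

    The first 8 nt of the adapter (or the whole adapter if shorter) are
    searched in the 3' half of the read; the read is cut at the match start.
    Returns (possibly trimmed record, whether an adapter was found).
    """
    probe = adapter[:8].upper().replace("U", "T")
    half = len(rec.sequence) // 2
    idx = rec.sequence.find(probe, half)
    if idx == -1:
        return rec, False
    quals = rec.qualities[:idx] if rec.qualities is not None else None
    if idx == 0:  # adapter dimer: nothing left of the insert
        return rec, True
    return SequenceRecord(rec.id, rec.sequence[:idx], quals), True


def filter_reads(
    records: Sequence[SequenceRecord], config: FilterConfig
) -> tuple[list[SequenceRecord], dict[str, int]]:
    """Apply quality/N/adapter/length filters to raw reads.

    Returns the kept (adapter-trimmed) reads and per-rule rejection counts.
    ``counts['no_adapter']`` tallies kept reads in which no adapter was found
    (kept untrimmed, flagged); it is informational and not a rejection rule,
    so ``len(kept) + sum(rejections) == len(records)``.
    """
    kept: list[SequenceRecord] = []
    counts = Counter({rule: 0 for rule in REJECTION_ORDER})
    counts["no_adapter"] = 0
    for rec in records:
        if not _passes_quality(rec, config):
            counts["quality"] += 1
            continue
        if "N" in rec.sequence:
            counts["ambiguous"] += 1
            continue
        found = True
        if config.adapter is not None:
            rec, found = trim_adapter(rec, config.adapter)
            if found and len(rec.sequence) == 0:
                counts["adapter"] += 1
                continue
        if not config.min_len <= len(rec.sequence) <= config.max_len:
            counts["length"] += 1
            continue
        if not found:
            counts["no_adapter"] += 1
        kept.append(rec)
    return kept, dict(counts)


def abundance_filter(
    collapsed: Sequence[CollapsedRead], min_reads: int = 5
) -> list[CollapsedRead]:
    """Keep collapsed entries with count >= min_reads."""
    return [r for r in collapsed if r.count >= min_reads]


def size_distribution(collapsed: Sequence[CollapsedRead]) -> dict[int, int]:
    """Total reads per sequence length; sums to the library's read mass."""
    dist: Counter[int] = Counter()
    for r in collapsed:
        dist[len(r.sequence)] += r.count
    return dict(sorted(dist.items()))


def size_modes(dist: dict[int, int]) -> list[int]:
    """Length(s) carrying the maximum read mass, ascending."""
    if not dist:
        return []
    peak = max(dist.values())
    return sorted(length for length, n in dist.items() if n == peak)
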