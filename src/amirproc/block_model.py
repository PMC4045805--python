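"""Sequence blocks along a miR319-family precursor.

Loop-to-base processing of miR319-type hairpins releases several small-RNA
duplexes, not just the miRNA/miRNA*: each arm region that yields a distinct
small-RNA population is a *block* (B1 and B1* are the guide/passenger
regions, B2/B2* the loop-proximal duplex, B3/B3* the regions between them).
A block is anchored by its representative — the most abundant read mapping
in the region — and membership of any other read is decided purely by
precursor-coordinate geometry: an overlap of more than 15 nt with the
representative interval, extending no more than 6 nt beyond it at either
end.

B3+ is special: reads that start in B3 but whose 3' ends run into the
middle of B1.  They would fail the generic rule for both B3 and B1 (too
long an extension), so they are recognised first by their own start/end
predicate.
"""

from __future__ import annotations

import dataclasses
import warnings
from collections import defaultdict
from typing import Mapping, Sequence

from .hairpin_map import MappedRead
from .seq_io import Hairpin

#: literal reading of "more than a 15 nt overlap": >= 16 nt
MIN_OVERLAP = 16
#: "extending for no more than 6 nt beyond ... at either end"
MAX_EXTENSION = 6


@dataclasses.dataclass(frozen=True)
class Block:
    """A precursor region anchored by its representative sequence."""

    name: str
    representative: str
    rep_start: int  # 1-based inclusive on the precursor
    rep_end: int

    def __post_init__(self) -> None:
        if self.rep_end - self.rep_start + 1 != len(self.representative):
            raise ValueError(
                f"block {self.name}: representative length does not match interval"
            )


@dataclasses.dataclass(frozen=True)
class B3PlusRule:
    """Membership predicate for B3+ reads: start inside the B3 region and
    end at least one base inside the B1 region."""

    name: str = "B3+"
    b3_interval: tuple[int, int] = (0, 0)
    b1_interval: tuple[int, int] = (0, 0)

    def matches(self, start: int, end: int) -> bool:
        return (
            self.b3_interval[0] <= start <= self.b3_interval[1]
            and end >= self.b1_interval[0]
        )


@dataclasses.dataclass(frozen=True)
class BlockAssignment:
    read: MappedRead
    block: str  # block name or "unassigned"
    overlap: int
    left_extension: int
    right_extension: int


def _interval_overlap(a: tuple[int, int], b: tuple[int, int]) -> int:
    return max(0, min(a[1], b[1]) - max(a[0], b[0]) + 1)


def select_representatives(
    mapped_reads: Sequence[MappedRead],
    region_hints: Mapping[str, tuple[int, int]],
    hairpin: Hairpin | None = None,
) -> list[Block]:
    """Pick the most abundant read in each hinted region as its block anchor.

    A read belongs to a hinted region when the midpoint of its mapped
    interval falls inside the region.  Ties on count are broken by longer
    read, then lexicographically.  Regions with no mapped reads are omitted
    with a warning.
    """
    by_region: dict[str, list[MappedRead]] = defaultdict(list)
    for read in mapped_reads:
        mid = (read.start + read.end) / 2
        for rname, (lo, hi) in region_hints.items():
            if lo <= mid <= hi:
                by_region[rname].append(read)
    blocks: list[Block] = []
    for rname in region_hints:
        members = by_region.get(rname)
        if not members:
            warnings.warn(f"region {rname!r} has no mapped reads; block omitted")
            continue
        rep = min(
            members, key=lambda r: (-r.count, -len(r.sequence), r.sequence)
        )
        if hairpin is not None:
            assert hairpin.sequence[rep.start - 1 : rep.end] == rep.sequence
        blocks.append(Block(rname, rep.sequence, rep.start, rep.end))
    return blocks


def assign_block(
    read: MappedRead,
    blocks: Sequence[Block],
    special: Sequence[B3PlusRule] = (),
    min_overlap: int = MIN_OVERLAP,
    max_extension: int = MAX_EXTENSION,
) -> BlockAssignment:
    """Assign a mapped read to a block by the overlap/extension rule.

    Special (B3+-style) rules are evaluated first so that reads bridging B3
    into B1 are not swallowed by B1's extension allowance.  Among qualifying
    generic blocks the largest overlap wins; ties go to the left-most block.
    """
    for rule in special:
        if rule.matches(read.start, read.end):
            b3_iv = rule.b3_interval
            return BlockAssignment(
                read,
                rule.name,
                _interval_overlap(read.interval, b3_iv),
                max(0, b3_iv[0] - read.start),
                max(0, read.end - b3_iv[1]),
            )
    best: BlockAssignment | None = None
    best_key: tuple[int, int] | None = None
    for block in blocks:
        rep_iv = (block.rep_start, block.rep_end)
        ov = _interval_overlap(read.interval, rep_iv)
        left = max(0, block.rep_start - read.start)
        right = max(0, read.end - block.rep_end)
        if ov >= min_overlap and left <= max_extension and right <= max_extension:
            key = (-ov, block.rep_start)
            if best_key is None or key < best_key:
                best_key = key
                best = BlockAssignment(read, block.name, ov, left, right)
    if best is not None:
        return best
    return BlockAssignment(read, "unassigned", 0, 0, 0)


def block_proportions(
    assignments: Sequence[BlockAssignment],
    over: str = "all",
) -> tuple[dict[str, float], float]:
    """Fraction of read mass per block.

    ``over="all"`` divides by all precursor-matched reads (assigned or not)
    and additionally returns the unassigned fraction; ``over="assigned"``
    restricts the denominator to assigned reads.  Fractions are over read
    counts, not unique sequences.
    """
    if over not in ("all", "assigned"):
        raise ValueError("over must be 'all' or 'assigned'")
    assigned = [a for a in assignments if a.block != "unassigned"]
    if not assigned:
        raise ValueError("no assigned reads: proportions undefined")
    totals: dict[str, int] = defaultdict(int)
    for a in assigned:
        totals[a.block] += a.read.count
    unassigned_mass = sum(a.read.count for a in assignments) - sum(totals.values())
    denom = sum(totals.values()) + (unassigned_mass if over == "all" else 0)
    fractions = {name: n / denom for name, n in sorted(totals.items())}
    unassigned_fraction = unassigned_mass / denom if over == "all" else 0.0
    return fractions, unassigned_fraction
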