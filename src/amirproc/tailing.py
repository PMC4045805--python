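"""3'-tailed variant decomposition and tabulation.

Small RNAs that fail to map perfectly to their precursor often consist of a
5' genome-matched component (5GMC) — a prefix matching the precursor
exactly — plus a short non-templated 3' tail added post-transcriptionally
(predominantly uridine in plants).  The decomposition is the longest
templated prefix; by maximality the first tail base necessarily differs
from the templated base that follows the 5GMC, which is what makes the
split identifiable.
"""

from __future__ import annotations

import dataclasses
from collections import Counter, defaultdict
from typing import Sequence

import pandas as pd

from .block_model import B3PlusRule, Block, BlockAssignment, assign_block
from .hairpin_map import MappedRead
from .seq_io import CollapsedRead, Hairpin, normalize, to_rna

#: observed 5GMC length bounds, encoded as defaults rather than laws
MIN_GMC = 17
MAX_GMC = 31
MAX_TAIL = 3


@dataclasses.dataclass(frozen=True)
class TailedVariant:
    """A read split into templated 5GMC and non-templated 3' tail."""

    sequence: str  # full read, internal DNA alphabet
    count: int
    gmc_start: int  # 1-based inclusive on the precursor
    gmc_end: int
    tail: str  # 1..MAX_TAIL nt
    block: str = "unassigned"

    @property
    def gmc_len(self) -> int:
        return self.gmc_end - self.gmc_start + 1

    @property
    def gmc_sequence(self) -> str:
        return self.sequence[: self.gmc_len]

    @property
    def display(self) -> str:
        """Table-style rendering: 5GMC lower-case, tail upper-case."""
        return self.gmc_sequence.lower() + self.tail.upper()


def longest_templated_prefix(read: str, precursor: str) -> tuple[int, int]:
    """Length and left-most 1-based start of the longest read prefix that
    occurs exactly in the precursor; (0, 0) if even the first base is absent.

    Occurrence of a prefix implies occurrence of every shorter prefix, so
    the length is found by bisection over prefix lengths.
    """
    lo, hi = 0, len(read)
    while lo < hi:
        mid = (lo + hi + 1) // 2
        if precursor.find(read[:mid]) != -1:
            lo = mid
        else:
            hi = mid - 1
    if lo == 0:
        return 0, 0
    return lo, precursor.find(read[:lo]) + 1


def decompose_tail(
    read: CollapsedRead,
    hairpin: Hairpin,
    min_gmc: int = MIN_GMC,
    max_tail: int = MAX_TAIL,
    blocks: Sequence[Block] = (),
    special: Sequence[B3PlusRule] = (),
) -> TailedVariant | None:
    """Split a non-templated read into 5GMC + 3' tail, or return None.

    Returns a variant iff the longest templated prefix is at least
    ``min_gmc`` long and the remainder is 1..``max_tail`` nt.  Fully
    templated reads return None (they belong to exact mapping, not here).
    When blocks are supplied the variant inherits the block assignment of
    its 5GMC interval.
    """
    seq = normalize(read.sequence)
    gmc_len, gmc_start = longest_templated_prefix(seq, hairpin.sequence)
    tail_len = len(seq) - gmc_len
    if gmc_len == 0 or tail_len == 0:
        return None
    if gmc_len < min_gmc or tail_len > max_tail:
        return None
    variant = TailedVariant(
        sequence=seq,
        count=read.count,
        gmc_start=gmc_start,
        gmc_end=gmc_start + gmc_len - 1,
        tail=seq[gmc_len:],
    )
    if blocks or special:
        placed = MappedRead(
            variant.gmc_sequence, read.count, hairpin.name,
            variant.gmc_start, variant.gmc_end, "+", 0,
        )
        assignment: BlockAssignment = assign_block(placed, blocks, special=special)
        variant = dataclasses.replace(variant, block=assignment.block)
    return variant


def decompose_library(
    collapsed: Sequence[CollapsedRead],
    hairpin: Hairpin,
    min_gmc: int = MIN_GMC,
    max_tail: int = MAX_TAIL,
    blocks: Sequence[Block] = (),
    special: Sequence[B3PlusRule] = (),
) -> tuple[list[TailedVariant], list[CollapsedRead]]:
    """Decompose every non-templated read in a library.

    Returns (variants, unexplained): reads that neither map exactly nor
    decompose within the 5GMC/tail bounds are reported, not dropped.
    """
    variants: list[TailedVariant] = []
    unexplained: list[CollapsedRead] = []
    for read in collapsed:
        seq = normalize(read.sequence)
        if hairpin.sequence.find(seq) != -1:
            continue  # fully templated: handled by map_exact
        var = decompose_tail(
            read, hairpin, min_gmc=min_gmc, max_tail=max_tail,
            blocks=blocks, special=special,
        )
        if var is None:
            unexplained.append(read)
        else:
            variants.append(var)
    return variants, unexplained


def tail_composition(
    variants: Sequence[TailedVariant], weight_by_reads: bool = True
) -> dict[str, float]:
    """Percentage of each nucleotide among all tail bases.

    Each tail contributes each of its bases, weighted by the variant's read
    count when ``weight_by_reads``.  Reported in RNA notation (U for T);
    percentages over {U, A, C, G} sum to 100 up to rounding.
    """
    if not variants:
        raise ValueError("tail composition of an empty variant list")
    tally: Counter[str] = Counter()
    for v in variants:
        w = v.count if weight_by_reads else 1
        for base in v.tail:
            tally[to_rna(base)] += w
    total = sum(tally.values())
    return {base: 100.0 * tally.get(base, 0) / total for base in "UACG"}


def tail_length_distribution(
    variants: Sequence[TailedVariant], max_tail: int = MAX_TAIL
) -> dict[int, int]:
    """Read-weighted histogram over tail lengths 1..max_tail."""
    dist = {length: 0 for length in range(1, max_tail + 1)}
    for v in variants:
        dist[len(v.tail)] += v.count
    return dist


def tabulate_tailed(variants: Sequence[TailedVariant]) -> pd.DataFrame:
    """Per-block table of tailed variants, printed-table style.

    Columns: sequence (tail upper-cased), reads, block, block_total.  Rows
    are sorted within block by descending reads; blocks appear in order of
    their first (most abundant) member.
    """
    by_block: dict[str, list[TailedVariant]] = defaultdict(list)
    for v in variants:
        by_block[v.block].append(v)
    rows = []
    order = sorted(
        by_block, key=lambda b: -max(v.count for v in by_block[b])
    )
    for block in order:
        members = sorted(by_block[block], key=lambda v: (-v.count, v.sequence))
        total = sum(v.count for v in members)
        for v in members:
            rows.append((v.display, v.count, block, total))
    return pd.DataFrame(rows, columns=["sequence", "reads", "block", "block_total"])


def block_tail_totals(variants: Sequence[TailedVariant]) -> dict[str, int]:
    """Total tailed-read count per block."""
    totals: dict[str, int] = defaultdict(int)
    for v in variants:
        totals[v.block] += v.count
    return dict(totals)
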