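"""Read-to-reference mapping: exact on precursors, mismatch-tolerant on
transcripts, plus coverage profiles and the secondary-siRNA scan.

Mapping is deliberately exhaustive (every offset is examined) rather than
indexed: references here are hairpin precursors and single transcripts, at
most a few kilobases, where an all-offsets scan is both fast and serves as
its own specification.  Positions are 1-based inclusive on the sense strand;
antisense hits report the read's reverse complement location on the sense
strand.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np

from .seq_io import CollapsedRead, Hairpin, normalize

_COMP = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


@dataclasses.dataclass(frozen=True)
class MappedRead:
    """A gap-free placement of a read on a reference."""

    sequence: str
    count: int
    reference: str
    start: int  # 1-based, inclusive, sense strand
    end: int
    strand: str  # "+" (sense) or "-" (antisense)
    mismatches: int = 0

    def __post_init__(self) -> None:
        if self.end - self.start + 1 != len(self.sequence):
            raise ValueError("interval length != read length")
        if self.strand not in ("+", "-"):
            raise ValueError("strand must be '+' or '-'")

    @property
    def interval(self) -> tuple[int, int]:
        return (self.start, self.end)


def _as_array(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode("ascii"), dtype=np.uint8)


def map_exact(
    collapsed: Sequence[CollapsedRead], hairpin: Hairpin | str, name: str | None = None
) -> list[MappedRead]:
    """Report every exact sense-strand occurrence of each read on a precursor.

    Reads with no occurrence are simply omitted (they flow to the tailing
    decomposition); reads occurring several times yield one hit per offset.
    """
    if isinstance(hairpin, Hairpin):
        ref, refname = hairpin.sequence, hairpin.name
    else:
        ref, refname = normalize(hairpin), name or "reference"
    hits: list[MappedRead] = []
    for read in collapsed:
        seq = normalize(read.sequence)
        idx = ref.find(seq)
        while idx != -1:
            hits.append(
                MappedRead(seq, read.count, refname, idx + 1, idx + len(seq), "+", 0)
            )
            idx = ref.find(seq, idx + 1)
    return hits


def map_mismatch(
    collapsed: Sequence[CollapsedRead],
    transcript: str,
    name: str = "transcript",
    max_mm: int = 4,
    strands: str = "both",
) -> list[MappedRead]:
    """All gap-free alignments with Hamming distance <= max_mm at any offset.

    ``strands`` is "both", "sense" or "antisense".  Antisense means the
    read's reverse complement matches the sense strand; the reported
    interval is always in sense-strand coordinates.
    """
    if max_mm < 0:
        raise ValueError("max_mm must be >= 0")
    ref = _as_array(normalize(transcript))
    hits: list[MappedRead] = []
    todo = []
    if strands in ("both", "sense"):
        todo.append("+")
    if strands in ("both", "antisense"):
        todo.append("-")
    if not todo:
        raise ValueError("strands must be 'both', 'sense' or 'antisense'")
    for read in collapsed:
        seq = normalize(read.sequence)
        L = len(seq)
        if L > len(ref):
            continue
        n_offsets = len(ref) - L + 1
        windows = np.lib.stride_tricks.sliding_window_view(ref, L)
        for strand in todo:
            query = _as_array(seq if strand == "+" else revcomp(seq))
            mm = (windows != query).sum(axis=1)
            for off in np.flatnonzero(mm <= max_mm):
                hits.append(
                    MappedRead(
                        seq, read.count, name,
                        int(off) + 1, int(off) + L, strand, int(mm[off]),
                    )
                )
        del n_offsets
    return hits


def coverage_profile(mapped: Sequence[MappedRead], hairpin: Hairpin | str) -> np.ndarray:
    """Per-position read depth; index i is position i+1. Multi-hit reads count
    fully at every hit (no fractional weighting)."""
    length = len(hairpin.sequence if isinstance(hairpin, Hairpin) else hairpin)
    depth = np.zeros(length, dtype=np.int64)
    for hit in mapped:
        depth[hit.start - 1 : hit.end] += hit.count
    return depth


def secondary_sirna_scan(
    collapsed: Sequence[CollapsedRead],
    transcript: str,
    primary_site_interval: tuple[int, int],
    name: str = "transcript",
    min_reads: int = 5,
    max_mm: int = 4,
    strands: str = "both",
) -> list[MappedRead]:
    """Search for abundant reads mapping outside the primary amiRNA site.

    A target under active small-RNA cleavage can template phased secondary
    siRNAs; their absence shows up as an empty result here.  Reads with
    count >= min_reads are mapped with up to max_mm mismatches on either
    strand, and any hit overlapping the primary site interval is excluded.
    """
    lo, hi = primary_site_interval
    if not (1 <= lo <= hi <= len(transcript)):
        raise ValueError("primary_site_interval must lie on the transcript")
    abundant = [r for r in collapsed if r.count >= min_reads]
    hits = map_mismatch(abundant, transcript, name=name, max_mm=max_mm, strands=strands)
    return [h for h in hits if h.end < lo or h.start > hi]
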