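"""5'-RACE-style cleavage-site mapping on targets and on the hairpin.

RNA-ligase-mediated 5' RACE captures the 5' end of the 3' (downstream)
fragment left by slicer cleavage, so a cleavage site is encoded as the
1-based position of the first nucleotide of that downstream fragment.
Plant RISCs cut their target between the bases pairing positions 10 and 11
of the guide small RNA; the canonical site is therefore the target base
pairing guide position 10.
"""

from __future__ import annotations

import dataclasses
from collections import Counter
from typing import Sequence

from .seq_io import Hairpin, normalize


@dataclasses.dataclass(frozen=True)
class CleavageSite:
    reference: str
    position: int  # first base of the downstream cleavage fragment, 1-based
    clones: int

    def __post_init__(self) -> None:
        if self.position < 1:
            raise ValueError("position must be >= 1")
        if self.clones < 1:
            raise ValueError("clones must be >= 1")


@dataclasses.dataclass(frozen=True)
class IntermediateProfile:
    """Ordered cleavage sites along a hairpin and their spacing."""

    positions: tuple[int, ...]  # in observation (processing) order
    distances: tuple[int, ...]  # successive absolute differences
    direction: str  # "loop-to-base" | "base-to-loop" | "undetermined"
    irregular: tuple[int, ...] = ()  # distances outside the expected 20-23 nt


def map_5p_ends(
    race_reads: Sequence[str],
    reference: str,
    name: str = "reference",
    anchor: int = 20,
) -> tuple[list[CleavageSite], int]:
    """Anchor each RACE read's 5' end on the reference by exact k-mer match.

    Each read's first ``anchor`` nt must occur exactly in the reference
    (left-most occurrence on multi-hits); clones are aggregated per mapped
    position.  Unanchored reads are counted as non-specific amplification
    products.  Returns (sites sorted by position, n_non_specific).
    """
    ref = normalize(reference)
    if len(ref) < anchor:
        raise ValueError(f"reference shorter than anchor length {anchor}")
    tally: Counter[int] = Counter()
    non_specific = 0
    for read in race_reads:
        seq = normalize(read)
        probe = seq[:anchor]
        idx = ref.find(probe) if len(probe) == anchor else -1
        if idx == -1:
            non_specific += 1
        else:
            tally[idx + 1] += 1
    sites = [CleavageSite(name, pos, n) for pos, n in sorted(tally.items())]
    return sites, non_specific


def canonical_site(small_rna: str, target_start: int, site_len: int | None = None) -> int:
    """Target position of the first base of the downstream fragment after
    slicing opposite guide positions 10/11.

    ``target_start`` is the 1-based first position of the site on the
    transcript; the site (5'->3') pairs the guide antiparallel, so guide
    position 10 pairs target position ``target_start + L - 10``.
    """
    L = site_len if site_len is not None else len(small_rna)
    if L < 11:
        raise ValueError("alignment shorter than 11 nt has no 10/11 cleavage site")
    return target_start + L - 10


def classify_sites(
    sites: Sequence[CleavageSite], canonical: int
) -> tuple[int, int, int]:
    """Partition clone counts into (at, upstream, downstream) of the
    canonical position; upstream means a smaller transcript coordinate."""
    at = upstream = downstream = 0
    for site in sites:
        if site.position == canonical:
            at += site.clones
        elif site.position < canonical:
            upstream += site.clones
        else:
            downstream += site.clones
    return at, upstream, downstream


def intermediate_profile(
    hairpin_sites: Sequence[int],
    hairpin: Hairpin | None = None,
    loop_position: int | None = None,
    expected_range: tuple[int, int] = (20, 23),
) -> IntermediateProfile:
    """Spacing and direction of successive processing-intermediate 5' ends.

    ``hairpin_sites`` must be in the order the cuts occur (RACE band
    intensity / simulation order).  Direction is inferred from the hairpin's
    loop annotation: cuts moving monotonically away from the loop are
    loop-to-base, toward it base-to-loop, otherwise undetermined.  Distances
    outside ``expected_range`` (DCL1 cuts at ~21-nt intervals) are flagged.
    """
    if len(hairpin_sites) < 2:
        raise ValueError("need at least two sites to profile spacing")
    if hairpin is not None:
        for pos in hairpin_sites:
            if not 1 <= pos <= len(hairpin):
                raise ValueError(f"site {pos} off the hairpin (len {len(hairpin)})")
        if loop_position is None and "loop" in hairpin.regions:
            lo, hi = hairpin.regions["loop"]
            loop_position = (lo + hi) // 2
    positions = tuple(hairpin_sites)
    distances = tuple(
        abs(b - a) for a, b in zip(positions, positions[1:])
    )
    direction = "undetermined"
    if loop_position is not None:
        offsets = [abs(p - loop_position) for p in positions]
        if all(b > a for a, b in zip(offsets, offsets[1:])):
            direction = "loop-to-base"
        elif all(b < a for a, b in zip(offsets, offsets[1:])):
            direction = "base-to-loop"
    lo, hi = expected_range
    irregular = tuple(d for d in distances if not lo <= d <= hi)
    return IntermediateProfile(positions, distances, direction, irregular)
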