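"""Simulator of loop-to-base hairpin processing, 3' tailing and RACE
fragments, plus the printed-table fixtures.

The generator emulates the statistical structure the analysis assumes:
sequential DCL1-style cleavage starting below the terminal loop and moving
toward the base at ~21-nt intervals (jitter over the 20-23 nt range),
excision of small-RNA duplex partners with a 2-nt 3' overhang, multinomial
read sampling over block proportions, 1-3-nt non-templated 3' tails with a
configurable nucleotide distribution, and 5'-RACE fragments whose 5' ends
sit at the slicer-predicted position with configurable accuracy.

``make_fixtures`` returns the two printed tailed-variant tables
(sequence + read count), together with precursor scaffolds.  The full
precursor sequences are not printed in the source tables, so the scaffolds
are *synthetic* reconstructions: the guide/star/junction segments come
verbatim from the printed cloning-primer and small-RNA sequences, laid out
in hairpin order, and the unprinted stretches (pads, loop, star-side
fillers) are neutral synthetic sequence.  Every printed read decomposes on
them into exactly the printed 5GMC/tail split.
"""

from __future__ import annotations

import dataclasses
from collections import Counter
from typing import Sequence

import numpy as np

from .cleavage_race import canonical_site
from .block_model import B3PlusRule
from .hairpin_map import revcomp
from .seq_io import CollapsedRead, Hairpin, SequenceRecord, normalize

_BASES = "ACGT"


@dataclasses.dataclass(frozen=True)
class SimulationConfig:
    """Study-condition parameters for the hairpin-processing simulator.

    Defaults encode the observed scenario: guide-block share 43% with the
    remainder spread over the other duplex blocks (the published bar chart
    prints no exact values for the minor blocks; these are presets), tails
    mostly 1 nt and never longer than 3, tail nucleotides U 45% / A 28% /
    C 16% / G 11%, cleavage intervals 21 +/- jitter covering 20-23 nt, and
    2-nt 3' overhangs on excised duplexes.
    """

    hairpin: Hairpin | None = None
    block_proportions: dict[str, float] = dataclasses.field(
        default_factory=lambda: {
            "B1": 0.43, "B1*": 0.25, "B2": 0.20, "B2*": 0.12,
        }
    )
    depth: int = 10_000
    interval_mean: int = 21
    interval_jitter: tuple[int, ...] = (-1, 0, 1, 2)
    overhang: int = 2
    tail_prob: float = 0.04
    tail_len_dist: dict[int, float] = dataclasses.field(
        default_factory=lambda: {1: 0.80, 2: 0.15, 3: 0.05}
    )
    tail_nt_dist: dict[str, float] = dataclasses.field(
        default_factory=lambda: {"U": 0.45, "A": 0.28, "C": 0.16, "G": 0.11}
    )
    seq_error_rate: float = 0.0
    seed: int = 0
    #: resample the first tail base when it equals the next templated base,
    #: keeping the 5GMC/tail split identifiable (off = "realistic" mode)
    resample_ambiguous_first_base: bool = True

    def __post_init__(self) -> None:
        if self.depth < 1:
            raise ValueError("depth must be >= 1")
        if abs(sum(self.block_proportions.values()) - 1.0) > 1e-9:
            raise ValueError("block proportions must sum to 1")
        if abs(sum(self.tail_len_dist.values()) - 1.0) > 1e-9:
            raise ValueError("tail length distribution must sum to 1")
        if abs(sum(self.tail_nt_dist.values()) - 1.0) > 1e-9:
            raise ValueError("tail nucleotide distribution must sum to 1")


@dataclasses.dataclass(frozen=True)
class SimProduct:
    """A templated small RNA excised from the hairpin."""

    block: str
    sequence: str
    start: int  # 1-based inclusive on the hairpin
    end: int
    arm: str  # "5p" or "3p"


def make_hairpin(
    arm_len: int = 95, loop_len: int = 14, seed: int = 0, name: str = "sim-hairpin"
) -> Hairpin:
    """A perfectly self-complementary synthetic stem-loop for simulations."""
    rng = np.random.default_rng(seed)
    arm3 = "".join(rng.choice(list(_BASES), size=arm_len))
    loop = "".join(rng.choice(list(_BASES), size=loop_len))
    arm5 = revcomp(arm3)
    seq = arm5 + loop + arm3
    structure = "(" * arm_len + "." * loop_len + ")" * arm_len
    regions = {
        "arm5": (1, arm_len),
        "loop": (arm_len + 1, arm_len + loop_len),
        "arm3": (arm_len + loop_len + 1, len(seq)),
    }
    return Hairpin(name=name, sequence=seq, structure=structure, regions=regions)


def simulate_processing(
    config: SimulationConfig,
) -> tuple[list[SimProduct], list[int]]:
    """Sequential loop-to-base cleavage of the configured hairpin.

    Four cuts are placed on the 3' arm — the first directly below the
    terminal loop, three more toward the base at ``interval_mean`` plus
    jitter — releasing three duplexes named (loop-proximal to base)
    B2/B2*, B3/B3*, B1/B1*.  Star partners mirror the guide interval across
    the stem with the configured 3' overhang.  Returns the products and the
    3'-arm cut positions in processing order (for intermediate profiling).
    """
    hp = config.hairpin
    if hp is None or "loop" not in hp.regions:
        raise ValueError("simulate_processing needs a hairpin with a loop region")
    rng = np.random.default_rng(config.seed)
    loop_lo, loop_hi = hp.regions["loop"]
    jitters = rng.choice(config.interval_jitter, size=3)
    cuts = [loop_hi + 1]
    for j in jitters:
        cuts.append(cuts[-1] + config.interval_mean + int(j))
    if cuts[-1] - 1 > len(hp):
        raise ValueError("hairpin too short for 4 loop-to-base cuts")
    names = ["B2", "B3", "B1"]

    def mirror(pos: int) -> int:
        # position on the 5' arm pairing 3'-arm position pos (ideal stem)
        return (loop_lo - 1) - (pos - (loop_hi + 1))

    products: list[SimProduct] = []
    for k, name in enumerate(names):
        s, e = cuts[k], cuts[k + 1] - 1
        products.append(
            SimProduct(name, hp.sequence[s - 1 : e], s, e, "3p")
        )
        star_s = mirror(e) + config.overhang
        star_e = mirror(s) + config.overhang
        if star_s < 1 or star_e > len(hp):
            raise ValueError("hairpin too short for star-strand excision")
        products.append(
            SimProduct(
                name + "*", hp.sequence[star_s - 1 : star_e], star_s, star_e, "5p"
            )
        )
    return products, cuts


def sample_library(
    products: Sequence[SimProduct],
    config: SimulationConfig,
    as_records: bool = False,
) -> list[CollapsedRead] | list[SequenceRecord]:
    """Multinomial sampling of reads over block proportions.

    Blocks absent from the products are dropped and the remaining
    proportions renormalized.  With ``seq_error_rate > 0`` each sampled copy
    is independently mutated per base.  Returns a collapsed library, or raw
    records (uniform quality 40) when ``as_records``.
    """
    if not products:
        raise ValueError("no products to sample from")
    by_block = {p.block: p for p in products}
    blocks = [b for b in config.block_proportions if b in by_block]
    if not blocks:
        raise ValueError("no overlap between proportions and product blocks")
    probs = np.array([config.block_proportions[b] for b in blocks], dtype=float)
    probs /= probs.sum()
    rng = np.random.default_rng(config.seed + 1)
    counts = rng.multinomial(config.depth, probs)
    tally: Counter[str] = Counter()
    for block, n in zip(blocks, counts):
        seq = by_block[block].sequence
        if config.seq_error_rate > 0:
            for _ in range(int(n)):
                arr = list(seq)
                errs = np.flatnonzero(
                    rng.random(len(arr)) < config.seq_error_rate
                )
                for i in errs:
                    arr[i] = rng.choice([b for b in _BASES if b != arr[i]])
                tally["".join(arr)] += 1
        elif n:
            tally[seq] += int(n)
    collapsed = [
        CollapsedRead(s, c)
        for s, c in sorted(tally.items(), key=lambda kv: (-kv[1], kv[0]))
    ]
    if not as_records:
        return collapsed
    records = []
    i = 0
    for r in collapsed:
        for _ in range(r.count):
            records.append(
                SequenceRecord(f"sim_{i}", r.sequence, (40,) * len(r.sequence))
            )
            i += 1
    return records


def add_tails(
    reads: Sequence[CollapsedRead],
    config: SimulationConfig,
    hairpin: Hairpin | None = None,
) -> list[CollapsedRead]:
    """Append non-templated 3' tails to a fraction of read copies.

    Each copy is tailed with probability ``tail_prob``; tail length and
    bases follow the configured distributions.  When a hairpin is given and
    ``resample_ambiguous_first_base`` is set, a first tail base equal to
    the next templated base is redrawn so the 5GMC/tail decomposition stays
    exact.  With ``tail_prob == 0`` the library is returned unchanged.
    """
    if config.tail_prob == 0:
        return list(reads)
    hp = hairpin if hairpin is not None else config.hairpin
    rng = np.random.default_rng(config.seed + 2)
    lengths = sorted(config.tail_len_dist)
    len_probs = np.array([config.tail_len_dist[k] for k in lengths])
    bases = list(config.tail_nt_dist)
    base_probs = np.array([config.tail_nt_dist[b] for b in bases])
    tally: Counter[str] = Counter()
    for read in reads:
        n_tailed = rng.binomial(read.count, config.tail_prob)
        if read.count - n_tailed:
            tally[read.sequence] += read.count - n_tailed
        next_base = None
        if hp is not None and config.resample_ambiguous_first_base:
            idx = hp.sequence.find(normalize(read.sequence))
            end = idx + len(read.sequence)
            if idx != -1 and end < len(hp):
                next_base = hp.sequence[end]
        for _ in range(int(n_tailed)):
            k = int(rng.choice(lengths, p=len_probs))
            tail = [str(rng.choice(bases, p=base_probs)) for _ in range(k)]
            if next_base is not None:
                while normalize(tail[0]) == next_base:
                    tail[0] = str(rng.choice(bases, p=base_probs))
            tally[read.sequence + normalize("".join(tail))] += 1
    return [
        CollapsedRead(s, c)
        for s, c in sorted(tally.items(), key=lambda kv: (-kv[1], kv[0]))
    ]


def simulate_race(
    target: str,
    small_rna: str,
    site_start: int,
    accuracy: float = 1.0,
    n: int = 20,
    seed: int = 0,
    frag_len: int = 40,
    max_shift: int = 5,
) -> list[str]:
    """5'-RACE fragments from slicer cleavage of a target site.

    ``site_start`` is the 1-based first position of the site on the target.
    A fraction ``accuracy`` of the n fragments start exactly at the
    canonical position (pairing guide position 10); the rest are displaced
    by +/- 1..max_shift nt uniformly.  Fragments run downstream for up to
    ``frag_len`` nt.
    """
    ref = normalize(target)
    guide = normalize(small_rna)
    if site_start < 1 or site_start + len(guide) - 1 > len(ref):
        raise ValueError("site does not fit the target")
    if n == 0:
        return []
    canonical = canonical_site(guide, site_start)
    rng = np.random.default_rng(seed)
    n_at = int(round(accuracy * n))
    starts = [canonical] * n_at
    for _ in range(n - n_at):
        shift = int(rng.integers(1, max_shift + 1)) * (
            1 if rng.random() < 0.5 else -1
        )
        starts.append(min(max(1, canonical + shift), len(ref)))
    return [ref[s - 1 : s - 1 + frag_len] for s in starts]


# --------------------------------------------------------------------------
# Printed-table fixtures
# --------------------------------------------------------------------------

#: the engineered 21-nt guide silencing chalcone synthase (printed sequence)
AMIRCHS1 = "TGTTGGTACATCATGAGTCGC"

#: cloning primers used to substitute the guide/star into the miR319a
#: backbone (printed table); they pin down the precursor junction context
PRIMERS = {
    "amiRchs1-I": "gatgttggtacatcatgagtcgctctctcttttgtattcc",
    "amiRchs1-II": "gagcgactcatgatgtaccaacatcaaagagaatcaatga",
    "amiRchs1-III": "gagcaactcatgatgaaccaacttcacaggtcgtgatatg",
    "amiRchs1-IV": "gaagttggttcatcatgagttgctctacatatatattcct",
}

#: tailed variants from the engineered precursor: (display, reads, block);
#: lower case = templated 5GMC, upper case = non-templated tail, leading
#: dashes in the source table (5'-truncation padding) removed
AMIRCHS1_TAILED_ROWS: tuple[tuple[str, int, str], ...] = (
    ("tgttggtacatcatgagtcgT", 28, "B1"),
    ("tgttggtacatcatgagtcgcA", 23, "B1"),
    ("tgttggtacatcatgagtcgcC", 18, "B1"),
    ("tgttggtacatcatgagtcgctctT", 10, "B1"),
    ("tgttggtacatcatgagtcgctT", 10, "B1"),
    ("tgttggtacatcatgagtcT", 9, "B1"),
    ("tgttggtacatcatgagtcgctctA", 8, "B1"),
    ("tgttggtacatcatgagtcgTTC", 5, "B1"),
    ("tgttggtacatcatgagtcgcCT", 5, "B1"),
    ("aactcatgatgaaccaacttcT", 41, "B1*"),
    ("ctcatgatgaaccaacttcacT", 27, "B1*"),
    ("tcatgatgaaccaacttcacT", 46, "B1*"),
    ("catgatgaaccaacttcT", 28, "B1*"),
    ("aatgaatgatgcggtagacaaaA", 103, "B2"),
    ("aatgaatgatgcggtagacaaatC", 48, "B2"),
    ("aatgaatgatgcggtagacaaatG", 47, "B2"),
    ("aatgaatgatgcggtagacaaaC", 32, "B2"),
    ("aatgaatgatgcggtagacaaatA", 22, "B2"),
    ("aatgaatgatgcggtagacaaT", 12, "B2"),
    ("aatgaatgatgcggtagacT", 10, "B2"),
    ("aatgaatgatgcggtagacaaTT", 9, "B2"),
    ("aatgaatgatgcggtagacaaaG", 9, "B2"),
    ("aatgaatgatgcggtagacaT", 7, "B2"),
    ("aatgaatgatgcggtagacaaG", 6, "B2"),
    ("aatgaatgatgcggtagacaaaAC", 6, "B2"),
    ("ttggatcattgattctctttgatgttggtacT", 7, "B3+"),
    ("ttggatcattgattctctttgatgttggtacC", 5, "B3+"),
)

#: tailed variants from the endogenous petunia miR319a-family precursor
PHY_TAILED_ROWS: tuple[tuple[str, int, str], ...] = (
    ("ttggactgaagggagctccTT", 112, "B1"),
    ("cttggactgaagggagctccT", 95, "B1"),
    ("cttggactgaagggagctccTT", 80, "B1"),
    ("ttggactgaagggagctccctT", 73, "B1"),
    ("cttggactgaagggagctcccC", 54, "B1"),
    ("ttggactgaagggagctcccC", 40, "B1"),
    ("ttggactgaagggagctccT", 36, "B1"),
    ("cttggactgaagggagctccctT", 11, "B1"),
    ("attcaacgatgcatgagctgG", 12, "B1*"),
    ("attcaacgatgcatgagctgC", 6, "B1*"),
    ("attcaacgatgcatgagctgtT", 5, "B1*"),
)


def _scaffold(segments: dict[str, str], name: str) -> Hairpin:
    """Concatenate named segments into a hairpin with region annotations."""
    seq = ""
    regions: dict[str, tuple[int, int]] = {}
    for seg_name, seg in segments.items():
        start = len(seq) + 1
        seq += normalize(seg)
        if not seg_name.startswith("pad"):
            regions[seg_name] = (start, len(seq))
    return Hairpin(name=name, sequence=seq, regions=regions)


def amirchs1_scaffold() -> Hairpin:
    """Synthetic reconstruction of the engineered guide's precursor.

    Segment layout follows the hairpin scheme (5' arm base->loop, loop,
    3' arm loop->base).  B1*/B3* context and the B3|B1 junction and 3'
    trailer are verbatim from the printed cloning primers; pads, B2* and
    the loop are synthetic filler (the source prints no sequence there).
    """
    return _scaffold(
        {
            "pad5": "GGCAAT",
            "ctx5": "AGGAATATATATGTAG",           # rc of primer IV 5' part
            "B1*": "AGCAACTCATGATGAACCAACTTCAC",  # primers III/IV overlap
            "B3*": "AGGTCGTGATATG",               # primer III trailer
            "B2*": "ATTTGTCTACCGCATCATTCATT",     # synthetic (rc of B2 core)
            "loop": "GTTGTTGTTTATGGTT",           # synthetic
            "B2": "AATGAATGATGCGGTAGACAAA",       # printed 5GMC core
            "B3": "TTGGATCATTGATTCTCTTTGA",       # printed B3+ 5' segment
            "B1": AMIRCHS1,
            "ctx3": "TCTCTCTTTTGTATTCC",          # primer I trailer
            "pad3": "ACGGCG",
        },
        name="amiRchs1-precursor-scaffold[synthetic]",
    )


def phy_mir319a_scaffold() -> Hairpin:
    """Synthetic scaffold for the endogenous petunia precursor, stitched
    from the printed tailed-variant 5GMC sequences; filler elsewhere."""
    return _scaffold(
        {
            "pad5": "GCAGAG",
            "B1*": "ATTCAACGATGCATGAGCTGT",       # printed 5GMC core
            "ctx5": "ACGGTCGTGTTTCAGG",           # synthetic
            "loop": "GTTGAAGTTTATGGA",            # synthetic
            "B2": "CCTTGAAGCGGAGCTTCAAGG",        # synthetic stand-in
            "B3": "TAGAGTAAG",                    # synthetic stand-in
            "B1": "CTTGGACTGAAGGGAGCTCCCT",       # printed 5GMC core
            "ctx3": "GTATCTTCAAG",                # synthetic
            "pad3": "GAGTGC",
        },
        name="phy-miR319a-precursor-scaffold[synthetic]",
    )


@dataclasses.dataclass(frozen=True)
class Fixtures:
    """Printed-table libraries and their synthetic precursor scaffolds."""

    amirchs1_tailed: tuple[CollapsedRead, ...]
    phy_tailed: tuple[CollapsedRead, ...]
    amirchs1_hairpin: Hairpin
    phy_hairpin: Hairpin
    amirchs1: str = AMIRCHS1

    def region_hints(self, which: str) -> dict[str, tuple[int, int]]:
        """Block-region hints for representative selection."""
        hp = self.amirchs1_hairpin if which == "amirchs1" else self.phy_hairpin
        names = ("B1", "B1*", "B2") if which == "amirchs1" else ("B1", "B1*")
        return {n: hp.regions[n] for n in names}

    def b3plus_rule(self, which: str = "amirchs1") -> B3PlusRule:
        hp = self.amirchs1_hairpin if which == "amirchs1" else self.phy_hairpin
        return B3PlusRule(
            "B3+", b3_interval=hp.regions["B3"], b1_interval=hp.regions["B1"]
        )


def _rows_to_library(rows: Sequence[tuple[str, int, str]]) -> tuple[CollapsedRead, ...]:
    return tuple(CollapsedRead(normalize(seq), count) for seq, count, _ in rows)


def make_fixtures() -> Fixtures:
    """Build the printed-table collapsed libraries and precursor scaffolds."""
    return Fixtures(
        amirchs1_tailed=_rows_to_library(AMIRCHS1_TAILED_ROWS),
        phy_tailed=_rows_to_library(PHY_TAILED_ROWS),
        amirchs1_hairpin=amirchs1_scaffold(),
        phy_hairpin=phy_mir319a_scaffold(),
    )
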