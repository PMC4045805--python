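"""Small-RNA/target duplex alignment, nearest-neighbor free energy, amiRNA
design rules, and transcriptome target scanning.

Plant miRNA target recognition is dominated by sequence complementarity, so
a gap-free antiparallel alignment with per-position states — Watson-Crick
(W), G:U wobble (G), mismatch (M), indexed from the small RNA's 5' end — is
the working object.  Duplex stability is a nearest-neighbor sum over the
packaged Turner-2004 stack table: initiation + stacks for contiguous paired
dinucleotides + a per-run internal penalty for opposed mismatches + terminal
A:U/G:U penalties.  Target acceptance follows the empirical plant criteria:
no mismatch opposite the cleavage site (guide positions 10-11), at most one
mismatch in the 5' core (2-12), at most four 3' of position 12 and never
more than two in a row, and duplex free energy at least 70% of the
perfectly complementary duplex.
"""

from __future__ import annotations

import dataclasses
import warnings
from typing import Mapping, Sequence

from . import _nn_params as nn
from .hairpin_map import revcomp
from .seq_io import SequenceRecord, normalize, to_rna

_RNA_COMP = {"A": "U", "U": "A", "G": "C", "C": "G"}


def _pair_state(guide_base: str, target_base: str) -> str:
    """W / G / M for an RNA base pair (guide base vs target base)."""
    if _RNA_COMP.get(guide_base) == target_base:
        return "W"
    if (guide_base, target_base) in (("G", "U"), ("U", "G")):
        return "G"
    return "M"


@dataclasses.dataclass
class DuplexAlignment:
    """Gap-free antiparallel pairing of a small RNA and a target site.

    ``states[i]`` is the state at small-RNA position i+1 (5'->3').  The
    site sequence is 5'->3' on the transcript; its first base pairs the
    small RNA's last base.  Energies are attached by :func:`evaluate_duplex`.
    """

    small_rna: str  # 5'->3', internal DNA alphabet
    target_site: str  # 5'->3' on the transcript
    offset: int  # 0-based start of the site on the transcript
    states: str
    transcript: str = "target"
    dg: float | None = None
    dg_perfect: float | None = None
    energy_fraction: float | None = None

    def __len__(self) -> int:
        return len(self.small_rna)

    @property
    def target_interval(self) -> tuple[int, int]:
        """1-based inclusive site interval on the transcript."""
        return (self.offset + 1, self.offset + len(self.target_site))

    def mismatch_positions(self, gu_as_mismatch: bool = False) -> list[int]:
        bad = "MG" if gu_as_mismatch else "M"
        return [i + 1 for i, s in enumerate(self.states) if s in bad]

    def n_mismatches(self, gu_as_mismatch: bool = False) -> int:
        return len(self.mismatch_positions(gu_as_mismatch))


def align_duplex(
    small_rna: str,
    transcript: str,
    offset: int,
    name: str = "target",
) -> DuplexAlignment:
    """Pair a small RNA against the transcript window starting at ``offset``
    (0-based), antiparallel and gap-free."""
    guide = normalize(small_rna)
    ref = normalize(transcript)
    L = len(guide)
    if offset < 0 or offset + L > len(ref):
        raise ValueError(
            f"site window [{offset}, {offset + L}) outside transcript of "
            f"length {len(ref)}"
        )
    site = ref[offset : offset + L]
    # guide position i (1-based) pairs site base L-i (0-based)
    states = "".join(
        _pair_state(to_rna(guide[i]), to_rna(site[L - 1 - i])) for i in range(L)
    )
    return DuplexAlignment(guide, site, offset, states, transcript=name)


def _partner(aln: DuplexAlignment, i: int) -> str:
    """RNA base on the target paired with guide position i (0-based)."""
    return to_rna(aln.target_site[len(aln) - 1 - i])


def duplex_energy(alignment: DuplexAlignment, temperature: float = 37.0) -> float:
    """Nearest-neighbor duplex free energy in kcal/mol.

    Initiation + stacks over contiguous paired (W/G) dinucleotides +
    internal mismatch-run penalties + terminal A:U/G:U penalties at the
    outermost paired positions.  Mismatch runs at the duplex ends are
    treated as unpaired overhangs (no charge).  The default 37 degC returns
    the published dG37 values; other temperatures rescale via dH - T*dS.
    """
    paired = [s in "WG" for s in alignment.states]
    if not any(paired):
        raise ValueError("duplex has no paired positions")
    dg = nn.init_dg(temperature)
    guide = to_rna(alignment.small_rna)
    for i in range(len(alignment) - 1):
        if paired[i] and paired[i + 1]:
            pair5 = guide[i] + _partner(alignment, i)
            pair3 = _partner(alignment, i + 1) + guide[i + 1]
            dg += nn.stack_dg(pair5, pair3, temperature)
    first = paired.index(True)
    last = len(paired) - 1 - paired[::-1].index(True)
    for end in (first, last):
        pair = guide[end] + _partner(alignment, end)
        if pair in ("AU", "UA", "GU", "UG"):
            dg += nn.terminal_au_dg(temperature)
    # internal mismatch runs (flanked by pairs on both sides)
    run = 0
    for i in range(first, last + 1):
        if not paired[i]:
            run += 1
        elif run:
            dg += nn.MM_OPEN + nn.MM_EXTEND * (run - 1)
            run = 0
    return round(dg, 10)


def perfect_duplex(small_rna: str) -> DuplexAlignment:
    """The small RNA paired with its exact reverse complement."""
    guide = normalize(small_rna)
    return align_duplex(guide, revcomp(guide), 0, name="perfect-complement")


def energy_fraction(alignment: DuplexAlignment, temperature: float = 37.0) -> float:
    """Duplex dG as a percentage of the perfectly complementary duplex dG.

    Exactly 100.0 when every state is Watson-Crick.
    """
    if all(s == "W" for s in alignment.states):
        return 100.0
    dg_perfect = duplex_energy(perfect_duplex(alignment.small_rna), temperature)
    if dg_perfect >= 0:
        raise ValueError("perfect-complement dG is non-negative; fraction undefined")
    dg = duplex_energy(alignment, temperature)
    return 100.0 * dg / dg_perfect


def evaluate_duplex(
    alignment: DuplexAlignment, temperature: float = 37.0
) -> DuplexAlignment:
    """Attach dg, dg_perfect and energy_fraction to an alignment."""
    alignment.dg = duplex_energy(alignment, temperature)
    alignment.dg_perfect = duplex_energy(
        perfect_duplex(alignment.small_rna), temperature
    )
    alignment.energy_fraction = (
        100.0
        if all(s == "W" for s in alignment.states)
        else 100.0 * alignment.dg / alignment.dg_perfect
    )
    return alignment


@dataclasses.dataclass(frozen=True)
class DesignRuleReport:
    """Empirical amiRNA design-rule checks for a candidate guide."""

    length_ok: bool
    u_at_1: bool
    a_at_10: bool
    match_at_2: bool
    match_at_12: bool
    five_prime_instability: bool

    @property
    def overall(self) -> bool:
        return (
            self.length_ok
            and self.u_at_1
            and self.a_at_10
            and self.match_at_2
            and self.match_at_12
            and self.five_prime_instability
        )


def _window_stack_sum(alignment: DuplexAlignment, lo: int, hi: int) -> float:
    """Stack-term sum over guide positions lo..hi (1-based, inclusive)."""
    guide = to_rna(alignment.small_rna)
    paired = [s in "WG" for s in alignment.states]
    total = 0.0
    for i in range(lo - 1, hi - 1):
        if paired[i] and paired[i + 1]:
            pair5 = guide[i] + _partner(alignment, i)
            pair3 = _partner(alignment, i + 1) + guide[i + 1]
            total += nn.stack_dg(pair5, pair3)
    return total


def check_design_rules(
    candidate: str,
    target_alignment: DuplexAlignment | None = None,
    instability_window: int = 5,
    gu_as_mismatch: bool = False,
) -> DesignRuleReport:
    """Evaluate the 21-nt / 5'U / 10A / 2,12-match / 5'-instability rules.

    5' instability is operationalized as the ``instability_window``-bp
    duplex window at the guide 5' end being less stable (higher stack-sum
    dG) than the window at the 3' end, evaluated on the target alignment
    (or the perfect complement when none is given) as a proxy for the
    miRNA/miRNA* duplex.
    """
    guide = normalize(candidate)
    if len(guide) < 12:
        raise ValueError("candidate shorter than 12 nt cannot be scored")
    aln = target_alignment if target_alignment is not None else perfect_duplex(guide)
    bad = "MG" if gu_as_mismatch else "M"
    w = instability_window
    dg5 = _window_stack_sum(aln, 1, w)
    dg3 = _window_stack_sum(aln, len(guide) - w + 1, len(guide))
    return DesignRuleReport(
        length_ok=len(guide) == 21,
        u_at_1=guide[0] == "T",
        a_at_10=guide[9] == "A",
        match_at_2=aln.states[1] not in bad,
        match_at_12=aln.states[11] not in bad,
        five_prime_instability=dg5 > dg3,
    )


@dataclasses.dataclass(frozen=True)
class TargetCriteria:
    """Empirical plant miRNA target-acceptance thresholds."""

    no_mm_10_11: bool = True
    max_mm_2_12: int = 1
    max_mm_after_13: int = 4
    max_consecutive_mm: int = 2
    energy_fraction_ge: float = 70.0
    gu_as_mismatch: bool = False  # strict mode counts wobbles as mismatches

    def __post_init__(self) -> None:
        if self.energy_fraction_ge <= 0:
            raise ValueError("energy_fraction_ge must be positive")


def check_target_criteria(
    alignment: DuplexAlignment,
    criteria: TargetCriteria = TargetCriteria(),
    temperature: float = 37.0,
) -> tuple[bool, dict[str, bool]]:
    """Evaluate an alignment against the target-acceptance criteria.

    Returns (overall pass, per-rule detail).
    """
    if len(alignment) != 21:
        warnings.warn(
            f"target criteria were calibrated for 21-nt guides; got "
            f"{len(alignment)} nt"
        )
    mm = set(alignment.mismatch_positions(criteria.gu_as_mismatch))
    runs: list[int] = []
    run = 0
    for pos in range(1, len(alignment) + 1):
        if pos in mm:
            run += 1
        else:
            if run:
                runs.append(run)
            run = 0
    if run:
        runs.append(run)
    detail = {
        "no_mm_10_11": not ({10, 11} & mm) if criteria.no_mm_10_11 else True,
        "le_mm_2_12": len([p for p in mm if 2 <= p <= 12]) <= criteria.max_mm_2_12,
        "le_mm_after_13": len([p for p in mm if p >= 13]) <= criteria.max_mm_after_13,
        "le_consecutive_mm": all(r <= criteria.max_consecutive_mm for r in runs),
        "energy_fraction": energy_fraction(alignment, temperature)
        >= criteria.energy_fraction_ge,
    }
    return all(detail.values()), detail


def scan_targets(
    small_rna: str,
    transcripts: Mapping[str, str] | Sequence[SequenceRecord],
    max_mm: int = 5,
    criteria: TargetCriteria = TargetCriteria(),
    temperature: float = 37.0,
) -> list[DuplexAlignment]:
    """Scan every offset of every transcript for acceptable target sites.

    Sites with at most ``max_mm`` mismatches that pass the criteria are
    returned with energies attached, ranked by energy fraction descending
    (ties by transcript name and offset).
    """
    if not transcripts:
        raise ValueError("no transcripts to scan")
    if isinstance(transcripts, Mapping):
        items = list(transcripts.items())
    else:
        items = [(rec.id, rec.sequence) for rec in transcripts]
    guide = normalize(small_rna)
    L = len(guide)
    hits: list[DuplexAlignment] = []
    for name, seq in items:
        ref = normalize(seq)
        for offset in range(len(ref) - L + 1):
            aln = align_duplex(guide, ref, offset, name=name)
            if aln.n_mismatches(criteria.gu_as_mismatch) > max_mm:
                continue
            ok, _ = check_target_criteria(aln, criteria, temperature)
            if ok:
                hits.append(evaluate_duplex(aln, temperature))
    hits.sort(key=lambda a: (-a.energy_fraction, a.transcript, a.offset))
    return hits
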