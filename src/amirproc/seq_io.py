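"""Sequence and tabular I/O shared by every pipeline stage.

All sequences are held internally in the DNA alphabet (``T``); ``U`` is
converted on input so that reads printed in RNA or DNA notation compare
equal.  Coordinates are 1-based and inclusive throughout the package.
"""

from __future__ import annotations

import dataclasses
from collections import Counter
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO

VALID_BASES = frozenset("ACGTN")


class FormatError(ValueError):
    """Raised for malformed FASTA/FASTQ/TSV input."""


def normalize(seq: str) -> str:
    """Upper-case and convert RNA ``U`` to the internal DNA ``T`` alphabet."""
    s = seq.upper().replace("U", "T")
    bad = set(s) - VALID_BASES
    if bad:
        raise FormatError(f"non-nucleotide characters {sorted(bad)} in sequence")
    return s


def to_rna(seq: str) -> str:
    """Render an internal DNA-alphabet sequence in RNA notation."""
    return seq.upper().replace("T", "U")


@dataclasses.dataclass(frozen=True)
class SequenceRecord:
    """A named nucleotide sequence with optional Phred qualities."""

    id: str
    sequence: str
    qualities: tuple[int, ...] | None = None

    def __post_init__(self) -> None:
        if len(self.sequence) < 1:
            raise FormatError(f"record {self.id!r} has an empty sequence")
        if self.qualities is not None and len(self.qualities) != len(self.sequence):
            raise FormatError(
                f"record {self.id!r}: {len(self.qualities)} quality values for "
                f"{len(self.sequence)} bases"
            )


@dataclasses.dataclass(frozen=True, order=True)
class CollapsedRead:
    """A unique small-RNA sequence with its library read count."""

    sequence: str
    count: int

    def __post_init__(self) -> None:
        if self.count < 1:
            raise ValueError("collapsed read count must be >= 1")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclasses.dataclass(frozen=True)
class Hairpin:
    """A precursor: single sense strand 5'->3' with optional structure/regions.

    ``regions`` maps a name (arm, loop, or block hint such as ``B1``) to a
    1-based inclusive ``(start, end)`` interval on the sequence.
    """

    name: str
    sequence: str
    structure: str | None = None
    regions: dict[str, tuple[int, int]] = dataclasses.field(default_factory=dict)

    def __post_init__(self) -> None:
        object.__setattr__(self, "sequence", normalize(self.sequence))
        if self.structure is not None:
            if len(self.structure) != len(self.sequence):
                raise FormatError(
                    f"hairpin {self.name!r}: structure length "
                    f"{len(self.structure)} != sequence length {len(self.sequence)}"
                )
            depth = 0
            for ch in self.structure:
                if ch == "(":
                    depth += 1
                elif ch == ")":
                    depth -= 1
                    if depth < 0:
                        raise FormatError(f"hairpin {self.name!r}: unbalanced ')'")
                elif ch != ".":
                    raise FormatError(
                        f"hairpin {self.name!r}: invalid structure char {ch!r}"
                    )
            if depth != 0:
                raise FormatError(f"hairpin {self.name!r}: unbalanced '('")
        for rname, (start, end) in self.regions.items():
            if not (1 <= start <= end <= len(self.sequence)):
                raise FormatError(
                    f"hairpin {self.name!r}: region {rname} interval "
                    f"({start}, {end}) outside [1, {len(self.sequence)}]"
                )

    def __len__(self) -> int:
        return len(self.sequence)

    def region_seq(self, name: str) -> str:
        start, end = self.regions[name]
        return self.sequence[start - 1 : end]


def read_fasta(path: str | Path) -> list[SequenceRecord]:
    """Read a FASTA file into records, preserving order, upper-cased."""
    records = []
    try:
        for rec in SeqIO.parse(str(path), "fasta"):
            if len(rec.seq) == 0:
                raise FormatError(f"{path}: empty sequence for record {rec.id!r}")
            records.append(SequenceRecord(id=rec.id, sequence=normalize(str(rec.seq))))
    except FormatError:
        raise
    except ValueError as exc:
        raise FormatError(f"{path}: {exc}") from exc
    if not records:
        # Distinguish an empty/garbage file from a legal empty list: a FASTA
        # file must contain at least one '>' header to be well-formed here.
        text = Path(path).read_text()
        if ">" not in text:
            raise FormatError(f"{path}: no FASTA records found")
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n{rec.sequence}\n")


def read_fastq(path: str | Path) -> list[SequenceRecord]:
    """Read 4-line FASTQ (Phred+33); qualities decoded to integers."""
    records = []
    try:
        for rec in SeqIO.parse(str(path), "fastq"):
            quals = tuple(rec.letter_annotations["phred_quality"])
            records.append(
                SequenceRecord(
                    id=rec.id, sequence=normalize(str(rec.seq)), qualities=quals
                )
            )
    except FormatError:
        raise
    except ValueError as exc:
        raise FormatError(f"{path}: {exc}") from exc
    return records


def write_fastq(records: Iterable[SequenceRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for rec in records:
            quals = rec.qualities
            if quals is None:
                quals = (40,) * len(rec.sequence)
            qline = "".join(chr(q + 33) for q in quals)
            fh.write(f"@{rec.id}\n{rec.sequence}\n+\n{qline}\n")


def collapse_reads(records: Sequence[SequenceRecord | str]) -> list[CollapsedRead]:
    """Collapse identical sequences into (sequence, count) entries.

    The result is sorted by descending count, ties broken lexicographically,
    and conserves total read mass: sum(counts) == len(records).
    """
    if not records:
        raise ValueError("cannot collapse an empty read list")
    tally: Counter[str] = Counter()
    for rec in records:
        seq = rec if isinstance(rec, str) else rec.sequence
        tally[normalize(seq)] += 1
    return [
        CollapsedRead(seq, n)
        for seq, n in sorted(tally.items(), key=lambda kv: (-kv[1], kv[0]))
    ]


def collapse_library(reads: Sequence[CollapsedRead]) -> list[CollapsedRead]:
    """Re-collapse a weighted library (idempotent on collapsed input)."""
    tally: Counter[str] = Counter()
    for r in reads:
        tally[normalize(r.sequence)] += r.count
    return [
        CollapsedRead(seq, n)
        for seq, n in sorted(tally.items(), key=lambda kv: (-kv[1], kv[0]))
    ]


def write_table(rows: Sequence[Sequence], path: str | Path, header: Sequence[str]) -> None:
    """Write rectangular rows as a TSV with header."""
    width = len(header)
    for i, row in enumerate(rows):
        if len(row) != width:
            raise FormatError(f"row {i} has {len(row)} fields, expected {width}")
    pd.DataFrame(list(rows), columns=list(header)).to_csv(path, sep="\t", index=False)


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_collapsed_tsv(reads: Sequence[CollapsedRead], path: str | Path) -> None:
    write_table([(r.sequence, r.count) for r in reads], path, header=("sequence", "count"))


def read_collapsed_tsv(path: str | Path) -> list[CollapsedRead]:
    """Read a collapsed library TSV (columns: sequence, count; extra columns ignored)."""
    df = read_table(path)
    if "sequence" not in df.columns or "count" not in df.columns:
        raise FormatError(f"{path}: expected columns 'sequence' and 'count'")
    return [
        CollapsedRead(normalize(s), int(c))
        for s, c in zip(df["sequence"], df["count"])
    ]


def read_hairpin(path: str | Path, name: str | None = None) -> Hairpin:
    """Read a 2-line companion file: sequence line, then dot-bracket line.

    A plain 1-line file (sequence only) yields a structure-less hairpin.
    """
    lines = [ln.strip() for ln in Path(path).read_text().splitlines() if ln.strip()]
    if not lines:
        raise FormatError(f"{path}: empty hairpin file")
    if lines[0].startswith(">"):
        hname = name or lines[0][1:].strip()
        lines = lines[1:]
    else:
        hname = name or Path(path).stem
    if not lines:
        raise FormatError(f"{path}: header without sequence")
    seq = lines[0]
    structure = lines[1] if len(lines) > 1 else None
    return Hairpin(name=hname, sequence=seq, structure=structure)


def write_hairpin(hp: Hairpin, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(f">{hp.name}\n{hp.sequence}\n")
        if hp.structure is not None:
            fh.write(hp.structure + "\n")
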