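"""End-to-end orchestration: filter -> map -> blocks -> tails -> reports.

Every stage is a thin call into the corresponding module; report numbers
are the module outputs themselves, written as TSV/JSON without
recomputation.  All randomness (simulation subcommands) flows through the
single seed recorded in the run log.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path
from typing import Sequence

from . import __version__
from .block_model import B3PlusRule, Block, assign_block, block_proportions, select_representatives
from .hairpin_map import MappedRead, map_exact
from .preprocess import FilterConfig, abundance_filter, filter_reads, size_distribution
from .seq_io import (
    CollapsedRead,
    Hairpin,
    collapse_reads,
    read_collapsed_tsv,
    read_fastq,
    read_hairpin,
    write_table,
)
from .tailing import (
    TailedVariant,
    block_tail_totals,
    decompose_library,
    tabulate_tailed,
    tail_composition,
    tail_length_distribution,
)


class PipelineError(RuntimeError):
    """A stage failed; message names the stage and cause."""


@dataclasses.dataclass
class PipelineConfig:
    reads_path: str | None = None  # FASTQ or collapsed TSV
    precursor_path: str | None = None
    out_dir: str = "amirproc_out"
    filter_config: FilterConfig = dataclasses.field(default_factory=FilterConfig)
    region_hints: dict[str, tuple[int, int]] = dataclasses.field(default_factory=dict)
    b3plus: tuple[tuple[int, int], tuple[int, int]] | None = None  # (B3, B1) intervals
    proportions_over: str = "all"
    seed: int = 0


def tailed_block_report(
    collapsed: Sequence[CollapsedRead],
    hairpin: Hairpin,
    region_hints: dict[str, tuple[int, int]],
    b3plus: B3PlusRule | None = None,
):
    """Decompose tailed variants and assign them to blocks in two passes.

    Pass 1 decomposes without block labels; block representatives are then
    selected from the 5GMC placements per region hint; pass 2 re-labels
    each variant by its 5GMC interval.  Returns (variants, unexplained,
    blocks, table) where table is the printed-table-style report.
    """
    special = (b3plus,) if b3plus is not None else ()
    variants, unexplained = decompose_library(collapsed, hairpin)
    placed = [
        MappedRead(v.gmc_sequence, v.count, hairpin.name, v.gmc_start, v.gmc_end, "+", 0)
        for v in variants
    ]
    blocks = select_representatives(placed, region_hints, hairpin=hairpin)
    labelled: list[TailedVariant] = []
    for v, p in zip(variants, placed):
        assignment = assign_block(p, blocks, special=special)
        labelled.append(dataclasses.replace(v, block=assignment.block))
    return labelled, unexplained, blocks, tabulate_tailed(labelled)


def run_pipeline(config: PipelineConfig) -> dict:
    """Run preprocess -> exact mapping -> blocks -> tailing and write reports.

    Returns a summary dict (also written as report.json).  Any stage
    failure aborts with the stage name and cause.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    hashed = dataclasses.asdict(config)
    hashed.pop("out_dir")  # output location must not change report content
    summary: dict = {
        "tool": f"amirproc {__version__}",
        "seed": config.seed,
        "config_hash": hashlib.sha256(repr(hashed).encode()).hexdigest()[:16],
    }

    def stage(name):
        def wrap(fn, *args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except Exception as exc:  # noqa: BLE001 - re-raised with stage name
                raise PipelineError(f"stage {name!r} failed: {exc}") from exc
        return wrap

    # --- preprocess ---------------------------------------------------
    if config.reads_path is None:
        raise PipelineError("stage 'input' failed: no reads_path configured")
    path = Path(config.reads_path)
    if path.suffix in (".tsv", ".txt"):
        collapsed = stage("input")(read_collapsed_tsv, path)
        rejections = {}
    else:
        records = stage("input")(read_fastq, path)
        kept, rejections = stage("preprocess")(
            filter_reads, records, config.filter_config
        )
        collapsed = stage("preprocess")(collapse_reads, kept)
    collapsed = abundance_filter(collapsed, config.filter_config.min_reads)
    summary["n_unique"] = len(collapsed)
    summary["n_reads"] = sum(r.count for r in collapsed)
    summary["rejections"] = rejections

    dist = size_distribution(collapsed)
    write_table(sorted(dist.items()), out / "size_distribution.tsv",
                header=("length", "reads"))

    # --- mapping + blocks + tails ------------------------------------
    if config.precursor_path is not None:
        hairpin = stage("map")(read_hairpin, config.precursor_path)
        mapped = stage("map")(map_exact, collapsed, hairpin)
        write_table(
            [(m.sequence, m.count, m.reference, m.start, m.end, m.strand,
              m.mismatches) for m in mapped],
            out / "mapped.tsv",
            header=("sequence", "count", "reference", "start", "end",
                    "strand", "mismatches"),
        )
        hints = config.region_hints or hairpin.regions
        b3plus = None
        if config.b3plus is not None:
            b3plus = B3PlusRule("B3+", *config.b3plus)
        special = (b3plus,) if b3plus is not None else ()
        blocks: list[Block] = stage("blocks")(
            select_representatives, mapped, hints, hairpin
        )
        assignments = [assign_block(m, blocks, special=special) for m in mapped]
        write_table(
            [(b.name, b.representative, b.rep_start, b.rep_end) for b in blocks],
            out / "blocks.tsv",
            header=("name", "representative", "rep_start", "rep_end"),
        )
        if any(a.block != "unassigned" for a in assignments):
            fractions, unassigned = stage("blocks")(
                block_proportions, assignments, config.proportions_over
            )
            write_table(
                sorted(fractions.items()) + [("unassigned", unassigned)],
                out / "block_proportions.tsv",
                header=("block", "fraction"),
            )
            summary["block_fractions"] = fractions
        variants, unexplained, _, table = stage("tails")(
            tailed_block_report, collapsed, hairpin, hints, b3plus
        )
        table.to_csv(out / "tailed_variants.tsv", sep="\t", index=False)
        summary["tailed_block_totals"] = block_tail_totals(variants)
        summary["n_unexplained"] = len(unexplained)
        if variants:
            summary["tail_composition"] = tail_composition(variants)
            summary["tail_lengths"] = tail_length_distribution(variants)

    (out / "report.json").write_text(json.dumps(summary, indent=2, sort_keys=True))
    return summary
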