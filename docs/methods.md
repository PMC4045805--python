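# Methods

## Scope and model

`amirproc` analyses how faithfully a miR319-family hairpin precursor is
processed into small RNAs. The underlying biology: miR319/miR159-type
precursors have unusually long fold-backs and are matured *loop-to-base* —
DCL1 cuts first below the terminal loop and then three more times at
roughly 21-nt intervals toward the base, releasing successive ~21-nt
duplexes with 2-nt 3' overhangs. Only one of those duplexes carries the
guide; the others (here named B2/B2\*, B3/B3\*, and the passenger B1\*) are
by-products that can accumulate, acquire non-templated 3' tails, and in
principle silence unintended targets. The package therefore combines four
analyses over a precursor and a small-RNA library: block classification,
tail decomposition, cleavage-site mapping, and target-complementarity
scanning.

Coordinates are 1-based inclusive everywhere. Sequences are held in the
DNA alphabet internally (U→T on input); tail compositions are reported in
RNA notation (U for T), matching how such tables are conventionally
printed (DNA in tables, RNA in prose).

## Block model

A *block* is a precursor region producing a distinct small-RNA population,
anchored by its representative — the most abundant read mapping inside the
region hint (membership of a read in a hint is decided by its interval
midpoint; ties on count go to the longer read, then lexicographic). Any
read is assigned to a block iff its precursor-coordinate interval overlaps
the representative interval by **at least 16 nt** (a literal reading of
"more than a 15 nt overlap") and extends **at most 6 nt** beyond it at
either end. If several blocks qualify, the largest overlap wins; exact
ties go to the left-most block (only overlapping block definitions can
tie, since two disjoint 21-nt representatives cannot both be overlapped by
16 nt under the 6-nt extension cap).

B3+ reads — starting in B3 but running at least 1 nt into B1 — fail the
generic rule for both B3 and B1 (their extensions are far beyond 6 nt), so
a dedicated start/end predicate recognises them *before* the generic rule
is applied. Block proportions are computed over read counts, not unique
sequences; by default the denominator is all precursor-matched reads, with
the unassigned fraction reported separately (a flag restricts the
denominator to assigned reads).

## Tail decomposition

A read that does not map perfectly to the precursor is split into the
longest prefix occurring exactly in the precursor (the 5' genome-matched
component, 5GMC; left-most occurrence on ties, found by bisection over
prefix lengths) plus the remainder as a non-templated 3' tail. A variant
is emitted iff the 5GMC is ≥17 nt and the tail is 1–3 nt — these bounds
are the observed ranges in the data this models, encoded as defaults
rather than laws; reads outside them are returned as "unexplained", never
silently dropped. By maximality of the prefix, the first tail base always
differs from the next templated base (except at the precursor 3' end,
where bases beyond the terminus are treated as tail). Tail composition is
read-weighted by default, with each tail contributing each of its bases.

## Read filtering

Raw reads pass a fixed rule order — quality, ambiguous bases, adapter,
length — and each rejected read is charged to the first failing rule, so
the counts partition the rejections. "Q value < 20" is interpreted as
*mean* Phred < 20 (configurable to min-base mode). Adapter removal is a
deliberately simple exact search of the adapter's first 8 nt in the read's
3' half (cut at match start); error-tolerant adapter alignment is out of
scope, and reads with no adapter hit are kept untrimmed but flagged. The
collapsed-library abundance floor is count ≥ 5: the source tables titled
"cloned more than 5 times" themselves contain 5-read rows, so ≥5 is the
operative rule. Length bounds default to 18–32 nt.

## Mapping

Precursor mapping is exact (every sense-strand occurrence reported;
multi-hit reads count fully at every hit so tallies stay integral).
Transcript mapping is an exhaustive all-offsets Hamming scan with ≤4
mismatches by default, on both strands (whether the original analysis
considered the antisense strand is unstated; a flag restricts it).
References here are single precursors/transcripts of at most a few kb, so
the exhaustive scan doubles as its own specification — the test suite
checks both mappers against independent brute-force oracles. The
secondary-siRNA scan maps abundant reads (≥5 by default) and reports hits
not overlapping the primary guide site; an empty result mirrors the
absence of phased secondary siRNAs.

## Cleavage sites

A cleavage site is encoded as the 1-based position of the first nucleotide
of the downstream fragment — exactly what 5' RLM-RACE ligates to. RACE
reads are anchored by exact match of their first 20 nt (configurable; the
stringency of the original clone assignment is unstated), unanchored reads
counted as non-specific. The canonical slicer site for a guide aligned at
target positions [s, s+L−1] is s+L−10: the base pairing guide position 10,
i.e. cleavage between the bases opposite positions 10 and 11. Intermediate
profiles take hairpin cut positions in processing order, report successive
distances, flag any outside 20–23 nt, and call the direction loop-to-base
or base-to-loop from monotone movement relative to the annotated loop.

## Duplex thermodynamics

Alignments are gap-free and antiparallel with per-position states W
(Watson-Crick), G (G:U wobble), M (mismatch), indexed from the guide 5'
end. Free energy is a nearest-neighbor sum: duplex initiation (+4.10
kcal/mol) + Turner-2004 stack terms for every contiguous paired (W/G)
dinucleotide + a terminal +0.50 penalty per outer A:U/G:U closing pair +
an internal charge of 1.70 + 1.10·(k−1) kcal/mol per run of k opposed
mismatches. Mismatch runs touching a duplex end are treated as unpaired
overhangs (no charge). No bulges are modelled (gaps are disallowed
throughout). The stack ΔG37/ΔH tables are the published Turner-2004
values at 0.1 kcal/mol precision; ΔH values enable linear rescaling
ΔG(T) = ΔH − T·ΔS. The default evaluation temperature is 37 °C — the
reference temperature of the published duplex energies this reproduces —
while the 23 °C hybridization setting used for target scanning can be
requested explicitly (it uniformly stabilizes duplexes and barely moves
the energy *fraction*, which is a ratio).

Two numerical caveats, stated rather than hidden. First, the 21-nt guide
paired with its perfect complement evaluates to −37.50 kcal/mol with this
table; the corresponding published figure is −37.02, a 1.3% residual
attributable to parameter-set version and ensemble-vs-minimum-free-energy
differences between cofolding tools. Second, "added mismatches never
stabilize" holds when mismatches replace Watson-Crick pairs (the tested
property); adjacent G:U/G:U stacks are genuinely destabilizing in the
Turner table, so a wobble-dense context is excluded from that universal
claim, and a wobble next to a strong pair can rival the corresponding
Watson-Crick stack — the invariant ΔG_perfect ≤ ΔG is therefore typical,
not theorematic.

The energy fraction is 100·ΔG/ΔG_perfect and is exactly 100 for an all-W
alignment by construction. G:U wobbles count as paired for energy and as
non-mismatches for the positional criteria, but are tracked separately; a
strict mode counts them as mismatches (the source criteria mention only
"mismatch" while describing wobbles as a distinct category, so both
interpretations are exposed).

Design rules for a candidate guide: 21 nt, U at position 1, A at position
10, no mismatch to the target at positions 2 and 12, and 5' instability —
operationalized (the source does not) as the 5-bp stack-sum window at the
guide 5' end being weaker than at the 3' end, evaluated on the target
alignment as a proxy for the guide/passenger duplex. Window length 5 is a
documented default.

## Simulator

The generator emulates the statistical structure the analysis assumes: a
perfectly self-complementary synthetic stem-loop (default 95-nt arms,
14-nt loop); four sequential cuts from below the loop toward the base at
21 nt + jitter drawn from {−1, 0, +1, +2} (spanning the observed 20–23 nt
spacing); duplex partners mirrored across the ideal stem with a 2-nt 3'
overhang; multinomial read sampling over block proportions (default
B1 43%, B1\* 25%, B2 20%, B2\* 12% — the 43% guide share is the published
value, the minor-block split is a preset since no exact figures are
printed); per-copy tailing with probability 0.04 (≈ the tailed fraction of
precursor-matched reads in the source library), tail lengths {1: 0.80,
2: 0.15, 3: 0.05} ("mostly 1 nt, longest 3 nt"), and tail nucleotides
U 45 / A 28 / C 16 / G 11 % (the published engineered-precursor tail
composition); RACE fragments placed at the canonical slicer position with
configurable accuracy, the remainder displaced ±1–5 nt.

By default the first tail base is resampled when it equals the next
templated base, which keeps the 5GMC/tail decomposition exactly
identifiable (recovery properties then hold with equality); switching
this off gives a "realistic" mode in which ambiguous tails occur and
decomposition recall is expectedly below 100%. All randomness flows
through one integer seed; identical seed + config gives byte-identical
output.

What the simulator does *not* emulate — and what passing recovery tests
therefore do not show about real data: sequence-dependent DCL1 cut-site
choice (jitter is i.i.d.), AGO loading biases, 5'/3' end heterogeneity of
templated products beyond the cut positions, degradation backgrounds, and
genome-scale off-precursor reads.

## Fixture scaffolds

The full precursor sequences are not printed in the source tables, so the
packaged scaffolds are synthetic reconstructions (labelled as such in
their names and docstrings): guide, passenger context, the B3→B1 junction
and the 3' trailer come verbatim from the printed cloning-primer and
small-RNA sequences, laid out in hairpin order (5' arm base→loop, loop,
3' arm loop→base); pads, loop and star-side fillers are neutral synthetic
sequence chosen so that no printed read gains a spurious longer templated
prefix. The test suite verifies that every printed tailed variant
decomposes on these scaffolds into exactly the printed 5GMC/tail split and
block. Conclusions that depend on the unprinted regions (e.g. true B2\*
abundances) are out of reach of these fixtures by construction.

## Problem sizes

All bundled analyses are desk-scale: the fixture tables (27 and 11 unique
variants), simulations at depths 10⁴–10⁵ for recovery properties, mapping
oracles on ≤1-kb references, and target scans over a few dozen 300-nt
transcripts. Deep-library absolute counts (10⁷-read libraries, database-
wide target counts) require the original sequencing data and external EST
databases and are outside the package's reproduction scope.
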