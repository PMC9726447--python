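"""Ancestry painting of a hybrid subgenome by uniquely shared alleles.

Each filtered biallelic SNP is classified: the query (hybrid) strain's site is
assigned to a candidate source population when one of the query's alleles is
carried by at least one of that population's assignment representatives and by
none of the exclusion representatives of any other population.  Runs of two or
more consecutive concordant assignments seed ancestry blocks; block borders
are then drawn at the midpoint between the outermost supporting sites of
adjacent blocks, expanding the blocks to tile each chromosome.  Per-population
totals of expanded block lengths, as percentages of all assigned bp, estimate
the fraction of the subgenome derived from each source population.

Allele sharing is symmetric in REF/ALT: variants are called against one
assembly, so "carries the variant" is meaningful only as "carries a shared
allele", whichever allele that is.  A literal ALT-presence reading is
available via ``alt_presence_only``.

Coordinates: site positions are 1-based; blocks are 0-based half-open.  A raw
block whose outermost 1-based sites are [f..l] occupies [f-1, l); the midpoint
boundary between adjacent blocks is floor((l_left + f_right) / 2) with the
boundary base going to the left block.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from .vcf_io import GenomeIndex, VariantSite, VariantTable

__all__ = [
    "UNASSIGNED",
    "Population",
    "PopulationScheme",
    "SiteAssignment",
    "RawBlock",
    "AncestryBlock",
    "AncestrySummary",
    "classify_site",
    "classify_table",
    "call_blocks",
    "expand_blocks",
    "paint",
    "summarize",
    "percentages_from_bp",
    "summarize_across_strains",
    "write_site_tsv",
    "write_summary_tsv",
]

UNASSIGNED = "UNASSIGNED"

#: reasons a site stays unassigned
QUERY_MISSING = "query_missing"
SHARED_BY_MULTIPLE = "shared_by_multiple"
SHARED_BY_NONE = "shared_by_none"
REPS_MISSING = "reps_missing"


@dataclass(frozen=True)
class Population:
    label: str
    assign_reps: frozenset[str]
    exclude_reps: frozenset[str]

    def __post_init__(self) -> None:
        if not self.label or self.label == UNASSIGNED:
            raise ValueError(f"invalid population label {self.label!r}")
        if not self.assign_reps or not self.exclude_reps:
            raise ValueError(f"population {self.label!r} needs non-empty rep sets")

    @property
    def all_reps(self) -> frozenset[str]:
        return self.assign_reps | self.exclude_reps


@dataclass(frozen=True)
class PopulationScheme:
    """The classification contract: one query strain, >= 2 candidate populations."""

    query: str
    populations: tuple[Population, ...]

    def __post_init__(self) -> None:
        if len(self.populations) < 2:
            raise ValueError("scheme needs at least two candidate populations")
        labels = [p.label for p in self.populations]
        if len(set(labels)) != len(labels):
            raise ValueError("population labels must be unique")
        for pop in self.populations:
            if self.query in pop.all_reps:
                raise ValueError(f"query {self.query!r} cannot be a representative")

    @property
    def labels(self) -> list[str]:
        return [p.label for p in self.populations]

    def validate_roster(self, roster: Sequence[str]) -> None:
        known = set(roster)
        if self.query not in known:
            raise ValueError(f"query sample {self.query!r} not in VCF roster")
        for pop in self.populations:
            missing = pop.all_reps - known
            if missing:
                raise ValueError(
                    f"population {pop.label!r} representatives not in roster: "
                    + ", ".join(sorted(missing))
                )


@dataclass(frozen=True)
class SiteAssignment:
    chrom: str
    pos: int  # 1-based
    label: str  # population label or UNASSIGNED
    reason: str | None = None  # present iff label == UNASSIGNED

    def __post_init__(self) -> None:
        if (self.label == UNASSIGNED) != (self.reason is not None):
            raise ValueError("reason must be present exactly when unassigned")

    @property
    def is_assigned(self) -> bool:
        return self.label != UNASSIGNED


@dataclass(frozen=True)
class RawBlock:
    """Pre-expansion run of concordant sites, spanning its outermost sites (1-based)."""

    chrom: str
    label: str
    first_pos: int
    last_pos: int
    support: int

    def __post_init__(self) -> None:
        if self.first_pos > self.last_pos:
            raise ValueError("block first_pos > last_pos")


@dataclass(frozen=True)
class AncestryBlock:
    chrom: str
    start: int  # 0-based half-open
    end: int
    label: str
    support: int = 0
    outermost: tuple[int, int] | None = None  # 1-based positions of first/last site

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"empty block {self.chrom}:{self.start}-{self.end}")

    @property
    def length(self) -> int:
        return self.end - self.start


def classify_site(
    site: VariantSite,
    scheme: PopulationScheme,
    roster: Sequence[str],
    alt_presence_only: bool = False,
) -> SiteAssignment:
    """Assign one site to the population that uniquely shares a query allele.

    The site is assigned to population P iff some allele of the query is
    carried by >= 1 of P's assign_reps and by none of the exclude_reps of any
    other population.  Ambiguity (>= 2 qualifying populations) and absence of
    any qualifying population yield UNASSIGNED with the matching reason, as do
    a missing query genotype and a population whose representatives are all
    missing.
    """
    idx = {name: i for i, name in enumerate(roster)}
    try:
        carried = {
            name: site.calls[idx[name]].allele_set()
            for name in {scheme.query, *(r for p in scheme.populations for r in p.all_reps)}
        }
    except KeyError as exc:
        raise ValueError(f"scheme sample {exc.args[0]!r} not in roster") from None

    query_alleles = carried[scheme.query]
    if alt_presence_only:
        query_alleles = query_alleles - {0}
    if not query_alleles:
        return SiteAssignment(site.chrom, site.pos, UNASSIGNED, QUERY_MISSING)

    for pop in scheme.populations:
        if all(not carried[r] for r in pop.all_reps):
            return SiteAssignment(site.chrom, site.pos, UNASSIGNED, REPS_MISSING)

    qualifying: set[str] = set()
    for pop in scheme.populations:
        others = [q for q in scheme.populations if q.label != pop.label]
        for allele in query_alleles:
            in_assign = any(allele in carried[r] for r in pop.assign_reps)
            vetoed = any(
                allele in carried[r] for q in others for r in q.exclude_reps
            )
            if in_assign and not vetoed:
                qualifying.add(pop.label)
                break
    if len(qualifying) == 1:
        return SiteAssignment(site.chrom, site.pos, qualifying.pop())
    if len(qualifying) >= 2:
        return SiteAssignment(site.chrom, site.pos, UNASSIGNED, SHARED_BY_MULTIPLE)
    return SiteAssignment(site.chrom, site.pos, UNASSIGNED, SHARED_BY_NONE)


def classify_table(
    table: VariantTable, scheme: PopulationScheme, alt_presence_only: bool = False
) -> list[SiteAssignment]:
    scheme.validate_roster(table.roster)
    return [
        classify_site(site, scheme, table.roster, alt_presence_only)
        for site in table.sites
    ]


def _desert_flags(assignments: Sequence[SiteAssignment], cap: int | None) -> list[bool]:
    """Flag sites inside runs of >= cap consecutive query-missing assignments."""
    flags = [False] * len(assignments)
    if cap is None:
        return flags
    i = 0
    n = len(assignments)
    while i < n:
        if assignments[i].reason == QUERY_MISSING:
            j = i
            while j < n and assignments[j].reason == QUERY_MISSING:
                j += 1
            if j - i >= cap:
                for k in range(i, j):
                    flags[k] = True
            i = j
        else:
            i += 1
    return flags


def call_blocks(
    assignments: Sequence[SiteAssignment],
    min_support: int = 2,
    unassigned_breaks_runs: bool = False,
    missing_run_cap: int | None = None,
) -> list[RawBlock]:
    """Call raw blocks from runs of concordant assignments on one chromosome.

    "Consecutive" means consecutive among population-assigned sites: an
    UNASSIGNED site is transparent (unless ``unassigned_breaks_runs``), but a
    site assigned to a *different* population breaks the run even as a
    singleton.  Runs shorter than ``min_support`` produce no block.  When
    ``missing_run_cap`` is set, runs of at least that many consecutive
    query-missing sites additionally break runs and are emitted as UNASSIGNED
    blocks (no-call deserts), so later expansion cannot paint across them.
    """
    if not assignments:
        return []
    chroms = {a.chrom for a in assignments}
    if len(chroms) > 1:
        raise ValueError("call_blocks expects assignments from a single chromosome")
    if any(b.pos <= a.pos for a, b in zip(assignments, assignments[1:])):
        raise ValueError("assignments must be sorted by position")

    desert = _desert_flags(assignments, missing_run_cap)
    blocks: list[RawBlock] = []
    run_label: str | None = None
    run_pos: list[int] = []

    def close_run() -> None:
        nonlocal run_label, run_pos
        if run_label is not None and len(run_pos) >= min_support:
            blocks.append(
                RawBlock(assignments[0].chrom, run_label, run_pos[0], run_pos[-1], len(run_pos))
            )
        run_label, run_pos = None, []

    i = 0
    n = len(assignments)
    while i < n:
        a = assignments[i]
        if desert[i]:
            close_run()
            j = i
            while j < n and desert[j]:
                j += 1
            blocks.append(
                RawBlock(a.chrom, UNASSIGNED, assignments[i].pos, assignments[j - 1].pos, j - i)
            )
            i = j
            continue
        if a.is_assigned:
            if a.label != run_label:
                close_run()
                run_label = a.label
            run_pos.append(a.pos)
        elif unassigned_breaks_runs:
            close_run()
        i += 1
    close_run()
    blocks.sort(key=lambda b: b.first_pos)
    return blocks


def expand_blocks(
    raw_blocks: Sequence[RawBlock], chrom_length: int, chrom: str | None = None
) -> list[AncestryBlock]:
    """Expand raw blocks outwards to tile [0, chrom_length).

    Borders between adjacent blocks sit at floor((left.last + right.first)/2)
    in 1-based coordinates; the boundary base goes to the left block.  The
    first block extends to 0 and the last to the chromosome end.  Adjacent
    expanded blocks with identical labels are merged.  With no raw blocks the
    whole chromosome is one UNASSIGNED block.
    """
    if not raw_blocks:
        if chrom is None:
            raise ValueError("chrom required when no raw blocks are given")
        return [AncestryBlock(chrom, 0, chrom_length, UNASSIGNED)]
    chroms = {b.chrom for b in raw_blocks}
    if len(chroms) > 1:
        raise ValueError("expand_blocks expects blocks from a single chromosome")
    chrom = raw_blocks[0].chrom
    blocks = sorted(raw_blocks, key=lambda b: b.first_pos)
    for b in blocks:
        if b.first_pos < 1 or b.last_pos > chrom_length:
            raise ValueError(
                f"block {b.first_pos}..{b.last_pos} outside [1, {chrom_length}]"
            )
    for left, right in zip(blocks, blocks[1:]):
        if right.first_pos <= left.last_pos:
            raise ValueError("raw blocks overlap")

    # 0-based half-open boundaries; boundary base (1-based == border) stays left
    borders = [
        (left.last_pos + right.first_pos) // 2 for left, right in zip(blocks, blocks[1:])
    ]
    starts = [0] + borders
    ends = borders + [chrom_length]
    expanded = [
        AncestryBlock(chrom, s, e, b.label, b.support, (b.first_pos, b.last_pos))
        for b, s, e in zip(blocks, starts, ends)
    ]
    # merge same-label neighbours
    merged: list[AncestryBlock] = []
    for blk in expanded:
        if merged and merged[-1].label == blk.label:
            prev = merged[-1]
            outer = (
                prev.outermost[0] if prev.outermost else blk.outermost[0],
                blk.outermost[1] if blk.outermost else prev.outermost[1],
            )
            merged[-1] = AncestryBlock(
                chrom, prev.start, blk.end, blk.label, prev.support + blk.support, outer
            )
        else:
            merged.append(blk)
    return merged


@dataclass
class AncestrySummary:
    """Per-population assigned bp and percentages of total assigned bp."""

    bp_by_pop: dict[str, int]
    unassigned_bp: int
    genome_bp: int

    @property
    def assigned_bp(self) -> int:
        return sum(self.bp_by_pop.values())

    @property
    def percentages(self) -> dict[str, float]:
        return percentages_from_bp(self.bp_by_pop)

    def percent(self, label: str, ndigits: int = 2) -> float:
        return round(self.percentages[label], ndigits)


def percentages_from_bp(bp_by_pop: Mapping[str, int]) -> dict[str, float]:
    """Percentage of total *assigned* bp per population (unassigned excluded)."""
    total = sum(bp_by_pop.values())
    if total == 0:
        return {label: 0.0 for label in bp_by_pop}
    return {label: 100.0 * bp / total for label, bp in bp_by_pop.items()}


def _check_tiling(blocks: Sequence[AncestryBlock], chrom: str, length: int) -> None:
    cursor = 0
    for b in sorted(blocks, key=lambda b: b.start):
        if b.start != cursor:
            raise ValueError(
                f"tiling gap/overlap on {chrom}: block starts at {b.start}, expected {cursor}"
            )
        cursor = b.end
    if cursor != length:
        raise ValueError(f"tiling on {chrom} ends at {cursor}, chromosome length {length}")


def summarize(
    blocks: Iterable[AncestryBlock],
    index: GenomeIndex,
    labels: Sequence[str] | None = None,
) -> AncestrySummary:
    """Aggregate expanded blocks (all chromosomes) into per-population totals.

    Blocks must tile every chromosome of the index exactly; a gap or overlap
    raises.
    """
    by_chrom: dict[str, list[AncestryBlock]] = {name: [] for name in index.names}
    for b in blocks:
        if b.chrom not in by_chrom:
            raise ValueError(f"block on unknown chromosome {b.chrom!r}")
        by_chrom[b.chrom].append(b)
    counts: Counter[str] = Counter()
    for name, length in index.records:
        _check_tiling(by_chrom[name], name, length)
        for b in by_chrom[name]:
            counts[b.label] += b.length
    unassigned = counts.pop(UNASSIGNED, 0)
    if labels is not None:
        bp_by_pop = {lab: counts.get(lab, 0) for lab in labels}
        extra = set(counts) - set(labels)
        if extra:
            raise ValueError(f"blocks carry labels outside the scheme: {sorted(extra)}")
    else:
        bp_by_pop = dict(sorted(counts.items()))
    return AncestrySummary(bp_by_pop, unassigned, index.total_bp)


def summarize_across_strains(summaries: Sequence[AncestrySummary]) -> dict[str, float]:
    """Unweighted mean of per-strain percentages; labels must agree."""
    if not summaries:
        raise ValueError("no summaries to average")
    labels = list(summaries[0].bp_by_pop)
    for s in summaries[1:]:
        if list(s.bp_by_pop) != labels:
            raise ValueError("population labels differ across summaries")
    return {
        lab: sum(s.percentages[lab] for s in summaries) / len(summaries) for lab in labels
    }


@dataclass
class PaintResult:
    assignments: list[SiteAssignment]
    blocks: list[AncestryBlock]
    summary: AncestrySummary


def paint(
    table: VariantTable,
    scheme: PopulationScheme,
    min_support: int = 2,
    missing_run_cap: int | None = 10,
    unassigned_breaks_runs: bool = False,
    alt_presence_only: bool = False,
) -> PaintResult:
    """Classify, call blocks, expand, and summarize in one pass over the genome."""
    assignments = classify_table(table, scheme, alt_presence_only)
    by_chrom: dict[str, list[SiteAssignment]] = {n: [] for n in table.index.names}
    for a in assignments:
        by_chrom[a.chrom].append(a)
    blocks: list[AncestryBlock] = []
    for name, length in table.index.records:
        raw = call_blocks(
            by_chrom[name],
            min_support=min_support,
            unassigned_breaks_runs=unassigned_breaks_runs,
            missing_run_cap=missing_run_cap,
        )
        blocks.extend(expand_blocks(raw, length, chrom=name))
    summary = summarize(blocks, table.index, labels=scheme.labels)
    return PaintResult(assignments, blocks, summary)


def write_site_tsv(assignments: Sequence[SiteAssignment], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("chrom\tpos\tlabel\treason\n")
        for a in assignments:
            fh.write(f"{a.chrom}\t{a.pos}\t{a.label}\t{a.reason or '.'}\n")


def write_summary_tsv(summary: AncestrySummary, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("population\tassigned_bp\tpercent_of_assigned\n")
        for label, bp in summary.bp_by_pop.items():
            fh.write(f"{label}\t{bp}\t{summary.percent(label):.2f}\n")
        fh.write(f"{UNASSIGNED}\t{summary.unassigned_bp}\t.\n")
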