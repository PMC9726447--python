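"""Shared table builders and independent brute-force oracles for the tests.

The oracles deliberately avoid the implementation's code paths: the cluster
oracle scans every possible window start, the expansion oracle assigns every
base to its nearest outermost supporting site, and the classification oracle
restates the uniquely-shared-allele rule with plain set algebra.
"""

from __future__ import annotations

import re

from lagerpaint.painter import RawBlock
from lagerpaint.vcf_io import GenomeIndex, GenotypeCall, VariantSite, VariantTable


def gt(spec: str, dp: int | None = 50, gq: int | None = 99) -> GenotypeCall:
    """'0/0', '0|1', './.' or '.' → GenotypeCall."""
    if spec in (".", "./."):
        return GenotypeCall(None, dp, gq)
    a, b = re.split(r"[/|]", spec)
    return GenotypeCall((int(a), int(b)), dp, gq)


def make_table(roster, rows, chrom_length=10_000, chroms=("chr1",)) -> VariantTable:
    """rows: (chrom, pos, ref, alts, calls) with calls as strings or GenotypeCall."""
    index = GenomeIndex(tuple((c, chrom_length) for c in chroms))
    sites = []
    for chrom, pos, ref, alts, calls in rows:
        calls = tuple(c if isinstance(c, GenotypeCall) else gt(c) for c in calls)
        sites.append(VariantSite(chrom, pos, ref, tuple(alts), calls))
    return VariantTable(tuple(roster), index, tuple(sites))


def cluster_oracle(positions: list[int], size: int, window: int) -> set[int]:
    """Brute force over every window start position."""
    doomed: set[int] = set()
    if not positions:
        return doomed
    for start in range(min(positions), max(positions) + 1):
        members = [p for p in positions if start <= p <= start + window - 1]
        if len(members) >= size:
            doomed.update(members)
    return doomed


def expand_oracle(raw_blocks: list[RawBlock], chrom_length: int) -> list[tuple[int, int, str]]:
    """Per-base nearest-outermost-site assignment (ties go to the left block).

    Returns merged (start, end, label) runs over [0, chrom_length).
    """
    blocks = sorted(raw_blocks, key=lambda b: b.first_pos)
    labels = []
    for base in range(chrom_length):
        pos = base + 1
        best = None
        for bi, blk in enumerate(blocks):
            dist = min(abs(pos - blk.first_pos), abs(pos - blk.last_pos))
            if blk.first_pos <= pos <= blk.last_pos:
                dist = 0
            if best is None or dist < best[0]:
                best = (dist, bi)
        labels.append(blocks[best[1]].label)
    runs: list[tuple[int, int, str]] = []
    start = 0
    for i in range(1, chrom_length + 1):
        if i == chrom_length or labels[i] != labels[start]:
            runs.append((start, i, labels[start]))
            start = i
    return runs


def expand_oracle_fast(raw_blocks, chrom_length: int) -> list[tuple[int, int, str]]:
    """Vectorized per-base nearest-outermost-site oracle (left-wins ties)."""
    import numpy as np

    blocks = sorted(raw_blocks, key=lambda b: b.first_pos)
    pos = np.arange(1, chrom_length + 1)
    dists = np.empty((len(blocks), chrom_length))
    for i, blk in enumerate(blocks):
        d = np.minimum(np.abs(pos - blk.first_pos), np.abs(pos - blk.last_pos))
        d[(pos >= blk.first_pos) & (pos <= blk.last_pos)] = 0
        dists[i] = d
    winner = np.argmin(dists, axis=0)  # argmin takes the first (leftmost) on ties
    runs: list[tuple[int, int, str]] = []
    start = 0
    for i in range(1, chrom_length + 1):
        if i == chrom_length or winner[i] != winner[start]:
            runs.append((start, i, blocks[int(winner[start])].label))
            start = i
    # merge adjacent runs whose block labels coincide
    merged: list[tuple[int, int, str]] = []
    for s, e, lab in runs:
        if merged and merged[-1][2] == lab:
            merged[-1] = (merged[-1][0], e, lab)
        else:
            merged.append((s, e, lab))
    return merged


def classify_oracle(
    query_alleles: frozenset[int], reps: dict[str, frozenset[int]]
) -> str:
    """Uniquely-shared-allele rule over single-representative populations,
    where each population's one rep serves both assignment and exclusion."""
    if not query_alleles:
        return "query_missing"
    if any(not alleles for alleles in reps.values()):
        return "reps_missing"
    qualifying = set()
    for label, alleles in reps.items():
        others = set().union(*(a for lab, a in reps.items() if lab != label))
        if any(a in alleles and a not in others for a in query_alleles):
            qualifying.add(label)
    if len(qualifying) == 1:
        return qualifying.pop()
    return "shared_by_multiple" if qualifying else "shared_by_none"
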