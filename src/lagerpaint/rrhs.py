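"""Random Repeated Haplotype Sampling: pseudo-haplotype SNP alignments.

Diploid genotypes are collapsed to one haplotype per strain by picking one of
the two alleles uniformly at random, independently per sample per site (no
within-chromosome phasing).  Repeating this many times yields a set of SNP
alignments whose downstream trees bracket the phase uncertainty.  Missing
genotypes emit 'N'.

Each iteration draws from an independent RNG substream derived from
(seed, iteration index), so a single iteration's alignment can be regenerated
byte-identically without replaying the others.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .vcf_io import VariantTable, write_alignment

__all__ = [
    "RrhsConfig",
    "resolve_once",
    "generate_alignments",
    "iteration_rng",
    "pairwise_snp_distance",
]


@dataclass(frozen=True)
class RrhsConfig:
    iterations: int = 1000
    seed: int = 0
    missing_char: str = "N"
    format: str = "phylip"

    def __post_init__(self) -> None:
        if self.iterations < 1:
            raise ValueError("iterations must be >= 1")


def iteration_rng(seed: int, iteration: int) -> np.random.Generator:
    """Independent, reproducible substream for one RRHS iteration."""
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(iteration,)))


def resolve_once(
    table: VariantTable, rng: np.random.Generator, missing_char: str = "N"
) -> list[str]:
    """Resolve every genotype to a single base; one alignment row per sample.

    Homozygous calls emit their allele; heterozygous calls emit either allele
    with probability 1/2, independently per sample per site; missing emits
    *missing_char*.
    """
    for site in table.sites:
        if not site.is_snp or not site.is_biallelic:
            raise ValueError(
                f"RRHS requires biallelic SNPs; offending site {site.chrom}:{site.pos}"
            )
    n_samples = len(table.roster)
    n_sites = len(table.sites)
    # one uniform draw per (site, sample); constant-shaped so the stream is
    # independent of genotype content
    picks = rng.integers(0, 2, size=(n_sites, n_samples))
    rows = [[missing_char] * n_sites for _ in range(n_samples)]
    for j, site in enumerate(table.sites):
        bases = (site.ref, site.alts[0])
        for i, call in enumerate(site.calls):
            if call.alleles is None:
                continue
            rows[i][j] = bases[call.alleles[picks[j, i]]]
    return ["".join(r) for r in rows]


def generate_alignments(
    table: VariantTable, cfg: RrhsConfig, outdir: str | Path
) -> list[Path]:
    """Write ``cfg.iterations`` alignment files with deterministic names.

    Fully reproducible from (table, seed): the same seed yields byte-identical
    files.  Returns the written paths in iteration order.
    """
    if len(table.sites) == 0:
        raise ValueError("cannot sample haplotypes from a table with no sites")
    outdir = Path(outdir)
    if not outdir.is_dir():
        raise NotADirectoryError(f"output directory {outdir} does not exist")
    ext = "phy" if cfg.format == "phylip" else "fa"
    width = max(4, len(str(cfg.iterations - 1)))
    paths = []
    for k in range(cfg.iterations):
        rows = resolve_once(table, iteration_rng(cfg.seed, k), cfg.missing_char)
        path = outdir / f"rrhs_{k:0{width}d}.{ext}"
        write_alignment(table.roster, rows, path, format=cfg.format)
        paths.append(path)
    return paths


def pairwise_snp_distance(rows: list[str], missing_char: str = "N") -> np.ndarray:
    """Symmetric matrix of per-pair differing sites, ignoring missing characters."""
    if not rows:
        return np.zeros((0, 0), dtype=int)
    length = len(rows[0])
    if any(len(r) != length for r in rows):
        raise ValueError("ragged alignment rows")
    arr = np.array([list(r) for r in rows])
    valid = arr != missing_char
    n = len(rows)
    dist = np.zeros((n, n), dtype=int)
    for i in range(n):
        for j in range(i + 1, n):
            both = valid[i] & valid[j]
            d = int(np.sum((arr[i] != arr[j]) & both))
            dist[i, j] = dist[j, i] = d
    return dist
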