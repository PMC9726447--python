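"""The site/genotype filter cascade producing the analysis-ready SNP table.

Order is pinned and documented: (1) genotype-level DP/GQ masking, (2) SNP
cluster removal, (3) multiallelic-site removal, (4) missingness removal,
(5) SNP-only selection.  Thresholds follow GATK VariantFiltration semantics:
DP and GQ comparisons are strict (< min), missingness is strict (> max), and
the cluster rule removes every SNP lying in any window of ``cluster_window``
bp (inclusive span) that contains at least ``cluster_size`` SNPs.

Genotypes whose DP or GQ is absent are left unmasked, mirroring how
VariantFiltration skips genotypes lacking the annotation.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from pathlib import Path

from .vcf_io import VariantSite, VariantTable

__all__ = [
    "FilterConfig",
    "FilterReport",
    "mask_low_quality_genotypes",
    "remove_snp_clusters",
    "select_analysis_sites",
    "apply_filters",
]


@dataclass(frozen=True)
class FilterConfig:
    min_depth: int = 15
    min_gq: int = 40
    cluster_size: int = 5
    cluster_window: int = 20
    max_missing_fraction: float = 0.30
    snps_only: bool = True
    biallelic_only: bool = True
    site_level_quality_filter: bool = False  # drop whole sites instead of masking

    def __post_init__(self) -> None:
        for name in ("min_depth", "min_gq", "cluster_size", "cluster_window"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0.0 <= self.max_missing_fraction <= 1.0:
            raise ValueError("max_missing_fraction must lie in [0, 1]")


@dataclass
class FilterReport:
    """Per-stage accounting; input − site-level removals = output."""

    input_sites: int = 0
    genotypes_masked_dp: int = 0
    genotypes_masked_gq: int = 0
    sites_removed_quality: int = 0  # only under site_level_quality_filter
    sites_removed_cluster: int = 0
    sites_removed_multiallelic: int = 0
    sites_removed_missingness: int = 0
    sites_removed_non_snp: int = 0
    output_sites: int = 0
    empty_output: bool = False

    def site_removals(self) -> int:
        return (
            self.sites_removed_quality
            + self.sites_removed_cluster
            + self.sites_removed_multiallelic
            + self.sites_removed_missingness
            + self.sites_removed_non_snp
        )

    def check_conservation(self) -> None:
        if self.input_sites - self.site_removals() != self.output_sites:
            raise AssertionError(f"filter report does not conserve sites: {self}")

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("stage\tcount\n")
            for key, val in asdict(self).items():
                fh.write(f"{key}\t{int(val)}\n")


def _below(value: int | None, threshold: int) -> bool:
    # absent annotations never trigger the filter
    return value is not None and value < threshold


def mask_low_quality_genotypes(
    table: VariantTable, cfg: FilterConfig, report: FilterReport | None = None
) -> VariantTable:
    """Mask any genotype with DP < min_depth or GQ < min_gq to missing."""
    new_sites = []
    for site in table.sites:
        calls = list(site.calls)
        changed = False
        for i, call in enumerate(calls):
            if call.is_missing:
                continue
            dp_bad = _below(call.depth, cfg.min_depth)
            gq_bad = _below(call.quality, cfg.min_gq)
            if dp_bad or gq_bad:
                if report is not None:
                    if dp_bad:
                        report.genotypes_masked_dp += 1
                    if gq_bad:
                        report.genotypes_masked_gq += 1
                calls[i] = call.masked()
                changed = True
        if changed:
            site = VariantSite(
                site.chrom, site.pos, site.ref, site.alts, tuple(calls), site.filter_flags
            )
        new_sites.append(site)
    return table.with_sites(new_sites)


def _cluster_positions(positions: list[int], size: int, window: int) -> set[int]:
    """Positions lying in any window of <= *window* bp holding >= *size* SNPs.

    Inclusive span: pos[j] - pos[i] + 1 <= window.
    """
    doomed: set[int] = set()
    n = len(positions)
    j = 0
    for i in range(n):
        if j < i:
            j = i
        while j + 1 < n and positions[j + 1] - positions[i] + 1 <= window:
            j += 1
        if j - i + 1 >= size:
            doomed.update(positions[i : j + 1])
    return doomed


def remove_snp_clusters(
    table: VariantTable, cfg: FilterConfig, report: FilterReport | None = None
) -> VariantTable:
    """Drop every SNP inside a qualifying cluster window; indels are untouched
    and do not count toward cluster membership."""
    if cfg.cluster_size == 0:
        return table
    doomed: set[tuple[str, int]] = set()
    for chrom in table.index.names:
        snp_pos = [s.pos for s in table.sites_on(chrom) if s.is_snp]
        for pos in _cluster_positions(snp_pos, cfg.cluster_size, cfg.cluster_window):
            doomed.add((chrom, pos))
    kept = [s for s in table.sites if (s.chrom, s.pos) not in doomed]
    if report is not None:
        report.sites_removed_cluster += len(table.sites) - len(kept)
    return table.with_sites(kept)


def select_analysis_sites(
    table: VariantTable, cfg: FilterConfig, report: FilterReport | None = None
) -> tuple[VariantTable, FilterReport]:
    """Apply the site-level exclusions: multiallelic, missingness, non-SNP."""
    if report is None:
        report = FilterReport(input_sites=len(table.sites))
    n_samples = len(table.roster)
    kept = []
    for site in table.sites:
        if cfg.biallelic_only and len(site.alts) > 1:
            report.sites_removed_multiallelic += 1
            continue
        if n_samples and site.n_missing() / n_samples > cfg.max_missing_fraction:
            report.sites_removed_missingness += 1
            continue
        if cfg.snps_only and not site.is_snp:
            report.sites_removed_non_snp += 1
            continue
        kept.append(site)
    out = table.with_sites(kept)
    report.output_sites = len(out.sites)
    report.empty_output = len(out.sites) == 0
    return out, report


def _drop_low_quality_sites(
    table: VariantTable, cfg: FilterConfig, report: FilterReport
) -> VariantTable:
    """Site-level alternative to genotype masking (``site_level_quality_filter``):
    a site is dropped outright if any genotype fails DP/GQ."""
    kept = []
    for site in table.sites:
        bad = any(
            _below(c.depth, cfg.min_depth) or _below(c.quality, cfg.min_gq)
            for c in site.calls
            if not c.is_missing
        )
        if bad:
            report.sites_removed_quality += 1
        else:
            kept.append(site)
    return table.with_sites(kept)


def apply_filters(
    table: VariantTable, cfg: FilterConfig | None = None
) -> tuple[VariantTable, FilterReport]:
    """Run the full cascade in pinned order and return table + report."""
    cfg = cfg or FilterConfig()
    report = FilterReport(input_sites=len(table.sites))
    if cfg.site_level_quality_filter:
        table = _drop_low_quality_sites(table, cfg, report)
    else:
        table = mask_low_quality_genotypes(table, cfg, report)
    table = remove_snp_clusters(table, cfg, report)
    table, report = select_analysis_sites(table, cfg, report)
    report.check_conservation()
    return table, report
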