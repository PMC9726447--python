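"""Synthetic cohorts with known ancestry truth.

Emulates the statistical shape of a diverged-population resequencing panel:
several source populations with private (diagnostic) alleles, two strains per
population, and one hybrid query whose genome is a mosaic of tracts copied
from the source populations, plus optional missingness and genotyping error.
Sites are placed by a Poisson process — the painter consumes site patterns,
not genealogies, so private-allele labelling over Poisson-placed sites is the
minimal sufficient structure.

Everything is deterministic given the seed; the VCF writer is byte-stable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .painter import Population, PopulationScheme
from .vcf_io import GenomeIndex, GenotypeCall, VariantSite, VariantTable, write_vcf

__all__ = [
    "SimConfig",
    "TruthTract",
    "SimResult",
    "default_labels",
    "simulate_populations",
    "simulate_hybrid",
    "simulate",
    "random_tract_spec",
    "truth_bp",
    "write_truth_bed",
]

QUERY_NAME = "hybrid"

#: three-population default mirrors a Holarctic-style scheme
_HOLARCTIC_STYLE = ("Tibet", "Ireland", "NorthCarolina")


def default_labels(n_populations: int) -> tuple[str, ...]:
    if n_populations == 3:
        return _HOLARCTIC_STYLE
    return tuple(f"pop{i + 1}" for i in range(n_populations))


@dataclass(frozen=True)
class TruthTract:
    chrom: str
    start: int  # 0-based half-open
    end: int
    label: str

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class SimConfig:
    seed: int = 0
    n_chromosomes: int = 2
    chrom_length: int = 250_000
    n_populations: int = 3
    strains_per_population: int = 2
    site_density: float = 1 / 200  # diagnostic-scale SNP rate per bp
    private_allele_fraction: float = 0.8
    het_rate: float = 0.02
    missing_rate: float = 0.0
    genotype_error_rate: float = 0.0
    tract_spec: str | tuple[tuple[str, int, int, str], ...] = "random"
    mean_tract_length: int = 50_000
    default_depth: int = 50
    default_gq: int = 99
    degrade: float = 0.0  # fraction of genotypes given sub-threshold DP/GQ

    def __post_init__(self) -> None:
        for name in (
            "site_density",
            "private_allele_fraction",
            "het_rate",
            "missing_rate",
            "genotype_error_rate",
            "degrade",
        ):
            val = getattr(self, name)
            if name == "site_density":
                if val <= 0:
                    raise ValueError("site_density must be > 0")
            elif not 0.0 <= val <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.n_populations < 2 or self.strains_per_population < 1:
            raise ValueError("need >= 2 populations with >= 1 strain each")

    @property
    def labels(self) -> tuple[str, ...]:
        return default_labels(self.n_populations)

    def strains_of(self, label: str) -> list[str]:
        return [f"{label}_{k + 1}" for k in range(self.strains_per_population)]

    @property
    def index(self) -> GenomeIndex:
        return GenomeIndex(
            tuple((f"chr{i + 1}", self.chrom_length) for i in range(self.n_chromosomes))
        )

    def scheme(self) -> PopulationScheme:
        pops = tuple(
            Population(
                label,
                assign_reps=frozenset({self.strains_of(label)[0]}),
                exclude_reps=frozenset(self.strains_of(label)),
            )
            for label in self.labels
        )
        return PopulationScheme(QUERY_NAME, pops)


_BASES = np.array(list("ACGT"))


def _site_genotypes(
    cfg: SimConfig, rng: np.random.Generator
) -> tuple[dict[str, tuple[int, int]], str | None]:
    """Genotypes for all source strains at one site + diagnostic label (or None)."""
    strains = {lab: cfg.strains_of(lab) for lab in cfg.labels}
    gts: dict[str, tuple[int, int]] = {
        s: (0, 0) for members in strains.values() for s in members
    }
    if rng.random() < cfg.private_allele_fraction:
        target = cfg.labels[rng.integers(cfg.n_populations)]
        for s in strains[target]:
            gts[s] = (0, 1) if rng.random() < cfg.het_rate else (1, 1)
        return gts, target
    if rng.random() < cfg.het_rate:
        # population-internal polymorphism: one strain heterozygous
        all_strains = [s for members in strains.values() for s in members]
        gts[all_strains[rng.integers(len(all_strains))]] = (0, 1)
        return gts, None
    # allele shared by >= 2 populations
    k = int(rng.integers(2, cfg.n_populations + 1))
    shared = rng.choice(cfg.n_populations, size=k, replace=False)
    for pi in shared:
        for s in strains[cfg.labels[pi]]:
            gts[s] = (1, 1)
    return gts, None


def _call(cfg: SimConfig, alleles: tuple[int, int] | None, rng: np.random.Generator) -> GenotypeCall:
    dp, gq = cfg.default_depth, cfg.default_gq
    if cfg.degrade and rng.random() < cfg.degrade:
        if rng.random() < 0.5:
            dp = int(rng.integers(1, 15))  # below the depth threshold
        else:
            gq = int(rng.integers(0, 40))  # below the quality threshold
    return GenotypeCall(alleles, dp, gq)


def simulate_populations(
    cfg: SimConfig, rng: np.random.Generator | None = None
) -> tuple[VariantTable, list[str | None]]:
    """Source-population panel (no query) plus the per-site diagnostic-origin map."""
    rng = rng if rng is not None else np.random.default_rng(cfg.seed)
    roster = tuple(s for lab in cfg.labels for s in cfg.strains_of(lab))
    sites: list[VariantSite] = []
    origin: list[str | None] = []
    for chrom, length in cfg.index.records:
        n_sites = int(rng.poisson(cfg.site_density * length))
        if n_sites == 0:
            import warnings

            warnings.warn(f"no sites placed on {chrom}; density too low")
            continue
        n_sites = min(n_sites, length)
        positions = np.sort(rng.choice(length, size=n_sites, replace=False)) + 1
        for pos in positions:
            ref_i = int(rng.integers(4))
            alt_i = int((ref_i + 1 + rng.integers(3)) % 4)
            gts, diag = _site_genotypes(cfg, rng)
            calls = tuple(_call(cfg, gts[s], rng) for s in roster)
            sites.append(
                VariantSite(
                    chrom, int(pos), str(_BASES[ref_i]), (str(_BASES[alt_i]),), calls
                )
            )
            origin.append(diag)
    return VariantTable(roster, cfg.index, tuple(sites)), origin


def random_tract_spec(
    index: GenomeIndex,
    labels: tuple[str, ...],
    rng: np.random.Generator,
    n_tracts: int | None = None,
    mean_tract_length: int = 50_000,
) -> list[TruthTract]:
    """Random ancestry mosaic tiling the genome.

    With ``n_tracts`` set, tracts are apportioned to chromosomes by length and
    split at uniform random breakpoints; otherwise tract lengths are drawn
    exponentially with the given mean.
    """
    tracts: list[TruthTract] = []
    if n_tracts is not None:
        remaining = n_tracts
        for i, (chrom, length) in enumerate(index.records):
            left = len(index.records) - i
            n_here = max(1, int(round(remaining / left)))
            n_here = min(n_here, remaining - (left - 1)) if left > 1 else remaining
            cuts = (
                np.sort(rng.choice(np.arange(1, length), size=n_here - 1, replace=False))
                if n_here > 1
                else np.array([], dtype=int)
            )
            bounds = [0, *cuts.tolist(), length]
            for s, e in zip(bounds, bounds[1:]):
                tracts.append(TruthTract(chrom, s, e, labels[rng.integers(len(labels))]))
            remaining -= n_here
    else:
        for chrom, length in index.records:
            pos = 0
            while pos < length:
                seg = max(1, int(rng.exponential(mean_tract_length)))
                end = min(length, pos + seg)
                tracts.append(TruthTract(chrom, pos, end, labels[rng.integers(len(labels))]))
                pos = end
    return tracts


def _validate_tracts(tracts: list[TruthTract], index: GenomeIndex, labels) -> None:
    known = set(labels)
    for t in tracts:
        if t.label not in known:
            raise ValueError(f"tract references unknown population {t.label!r}")
    for chrom, length in index.records:
        on = sorted((t for t in tracts if t.chrom == chrom), key=lambda t: t.start)
        cursor = 0
        for t in on:
            if t.start != cursor:
                raise ValueError(f"tract spec does not tile {chrom} (gap at {cursor})")
            cursor = t.end
        if cursor != length:
            raise ValueError(f"tract spec does not tile {chrom} (ends at {cursor})")


def simulate_hybrid(
    table: VariantTable,
    cfg: SimConfig,
    rng: np.random.Generator | None = None,
    tracts: list[TruthTract] | None = None,
) -> tuple[VariantTable, list[TruthTract]]:
    """Append the mosaic query to the panel and apply missingness/error noise.

    Within each truth tract the query copies the genotype of one randomly
    chosen strain of the source population; missing_rate then masks genotypes
    and genotype_error_rate flips a random allele, independently per genotype
    across all samples.
    """
    rng = rng if rng is not None else np.random.default_rng(cfg.seed + 1)
    if tracts is None:
        if isinstance(cfg.tract_spec, str):
            if cfg.tract_spec != "random":
                raise ValueError(f"unknown tract_spec {cfg.tract_spec!r}")
            tracts = random_tract_spec(
                table.index, cfg.labels, rng, mean_tract_length=cfg.mean_tract_length
            )
        else:
            tracts = [TruthTract(*t) for t in cfg.tract_spec]
    _validate_tracts(tracts, table.index, cfg.labels)

    donors = {id(t): cfg.strains_of(t.label)[rng.integers(cfg.strains_per_population)] for t in tracts}
    by_chrom: dict[str, list[TruthTract]] = {}
    for t in tracts:
        by_chrom.setdefault(t.chrom, []).append(t)
    for lst in by_chrom.values():
        lst.sort(key=lambda t: t.start)

    roster = table.roster + (QUERY_NAME,)
    new_sites: list[VariantSite] = []
    for site in table.sites:
        tract = next(
            t for t in by_chrom[site.chrom] if t.start <= site.pos - 1 < t.end
        )
        donor_call = table.call(site, donors[id(tract)])
        calls = list(site.calls) + [
            GenotypeCall(donor_call.alleles, cfg.default_depth, cfg.default_gq)
        ]
        # per-genotype noise across all samples
        for i, call in enumerate(calls):
            alleles = call.alleles
            if alleles is not None and cfg.genotype_error_rate and rng.random() < cfg.genotype_error_rate:
                which = int(rng.integers(2))
                flipped = tuple(
                    1 - a if j == which else a for j, a in enumerate(alleles)
                )
                alleles = (min(flipped), max(flipped))
            if cfg.missing_rate and rng.random() < cfg.missing_rate:
                alleles = None
            if alleles is not call.alleles:
                calls[i] = GenotypeCall(alleles, call.depth, call.quality)
        new_sites.append(
            VariantSite(site.chrom, site.pos, site.ref, site.alts, tuple(calls))
        )
    return VariantTable(roster, table.index, tuple(new_sites)), tracts


@dataclass
class SimResult:
    table: VariantTable  # panel + query
    tracts: list[TruthTract]
    scheme: PopulationScheme
    origin: list[str | None]
    config: SimConfig


def simulate(cfg: SimConfig, tracts: list[TruthTract] | None = None) -> SimResult:
    """Full cohort: source panel, mosaic hybrid, scheme — deterministic in seed."""
    rng = np.random.default_rng(cfg.seed)
    panel, origin = simulate_populations(cfg, rng)
    full, tracts = simulate_hybrid(panel, cfg, rng, tracts=tracts)
    return SimResult(full, tracts, cfg.scheme(), origin, cfg)


def truth_bp(tracts: list[TruthTract]) -> dict[str, int]:
    out: dict[str, int] = {}
    for t in tracts:
        out[t.label] = out.get(t.label, 0) + t.length
    return out


def write_truth_bed(tracts: list[TruthTract], path: str | Path) -> None:
    rows = sorted((t.chrom, t.start, t.end, t.label) for t in tracts)
    with open(path, "w") as fh:
        for chrom, start, end, label in rows:
            fh.write(f"{chrom}\t{start}\t{end}\t{label}\n")


def write_sim_outputs(result: SimResult, outdir: str | Path) -> dict[str, Path]:
    """Write sim.vcf, sim.fai, truth.bed and scheme.yaml under *outdir*."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "vcf": outdir / "sim.vcf",
        "fai": outdir / "sim.fai",
        "truth": outdir / "truth.bed",
        "scheme": outdir / "scheme.yaml",
    }
    write_vcf(result.table, paths["vcf"])
    result.config.index.to_tsv(paths["fai"])
    write_truth_bed(result.tracts, paths["truth"])
    scheme_dict = {
        "query": result.scheme.query,
        "populations": [
            {
                "label": p.label,
                "assign_reps": sorted(p.assign_reps),
                "exclude_reps": sorted(p.exclude_reps),
            }
            for p in result.scheme.populations
        ],
    }
    with open(paths["scheme"], "w") as fh:
        yaml.safe_dump(scheme_dict, fh, sort_keys=False)
    return paths
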