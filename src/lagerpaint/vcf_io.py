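"""Reading and writing the file formats the pipeline touches.

VCF comes in through :func:`read_vcf` (pysam-backed); BED, FASTA/relaxed-PHYLIP
alignments and two-column genome indexes (.fai-compatible) go out through small
writers.  Coordinate conventions: VCF positions are 1-based throughout the
variant table; interval types (BED) are 0-based half-open.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pysam

__all__ = [
    "GenomeIndex",
    "GenotypeCall",
    "VariantSite",
    "VariantTable",
    "VcfParseError",
    "read_genome_index",
    "read_vcf",
    "write_vcf",
    "write_bed",
    "read_bed",
    "write_alignment",
]


class VcfParseError(ValueError):
    """Raised for malformed VCF input, naming the offending record."""


@dataclass(frozen=True)
class GenomeIndex:
    """Ordered chromosome names and lengths; order is canonical output order."""

    records: tuple[tuple[str, int], ...]

    def __post_init__(self) -> None:
        names = [n for n, _ in self.records]
        if len(set(names)) != len(names):
            raise ValueError("duplicate chromosome names in genome index")
        for name, length in self.records:
            if not name:
                raise ValueError("empty chromosome name")
            if length < 1:
                raise ValueError(f"chromosome {name!r} has length {length} < 1")

    @property
    def names(self) -> list[str]:
        return [n for n, _ in self.records]

    def length_of(self, chrom: str) -> int:
        for name, length in self.records:
            if name == chrom:
                return length
        raise KeyError(chrom)

    def rank(self, chrom: str) -> int:
        """Position of *chrom* in the canonical order."""
        for i, (name, _) in enumerate(self.records):
            if name == chrom:
                return i
        raise KeyError(chrom)

    @property
    def total_bp(self) -> int:
        return sum(length for _, length in self.records)

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for name, length in self.records:
                fh.write(f"{name}\t{length}\n")


def read_genome_index(path: str | Path) -> GenomeIndex:
    """Load a two-column name/length TSV (first two columns of a samtools .fai)."""
    records = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 2:
                raise ValueError(f"{path}:{lineno}: expected >= 2 tab-separated columns")
            records.append((parts[0], int(parts[1])))
    return GenomeIndex(tuple(records))


@dataclass(frozen=True)
class GenotypeCall:
    """One diploid genotype: allele index pair, read depth and genotype quality.

    ``alleles`` is None when the genotype is missing ("./."); ``depth`` and
    ``quality`` are None when the VCF leaves DP/GQ unset ('.').
    """

    alleles: tuple[int, int] | None = None
    depth: int | None = None
    quality: int | None = None

    def __post_init__(self) -> None:
        if self.alleles is not None:
            if any(a < 0 for a in self.alleles):
                raise ValueError("allele indices must be >= 0 when present")
        if self.depth is not None and self.depth < 0:
            raise ValueError("depth must be >= 0")
        if self.quality is not None and self.quality < 0:
            raise ValueError("genotype quality must be >= 0")

    @property
    def is_missing(self) -> bool:
        return self.alleles is None

    def allele_set(self) -> frozenset[int]:
        """Distinct allele indices carried; empty when missing."""
        return frozenset(self.alleles) if self.alleles is not None else frozenset()

    def masked(self) -> "GenotypeCall":
        """This call with the genotype blanked (depth/quality retained)."""
        return GenotypeCall(None, self.depth, self.quality)


@dataclass(frozen=True)
class VariantSite:
    chrom: str
    pos: int  # 1-based, VCF convention
    ref: str
    alts: tuple[str, ...]
    calls: tuple[GenotypeCall, ...]
    filter_flags: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"position {self.pos} < 1 at {self.chrom}")
        if not self.ref or any(not a for a in self.alts):
            raise ValueError(f"empty allele at {self.chrom}:{self.pos}")
        n_alleles = 1 + len(self.alts)
        for call in self.calls:
            if call.alleles is not None and any(a >= n_alleles for a in call.alleles):
                raise ValueError(
                    f"allele index out of range at {self.chrom}:{self.pos}"
                )
        if self.ref in self.alts:
            raise ValueError(f"ALT equals REF at {self.chrom}:{self.pos}")

    @property
    def is_snp(self) -> bool:
        return len(self.ref) == 1 and all(len(a) == 1 for a in self.alts)

    @property
    def is_biallelic(self) -> bool:
        return len(self.alts) == 1

    def allele(self, idx: int) -> str:
        return self.ref if idx == 0 else self.alts[idx - 1]

    def n_missing(self) -> int:
        return sum(1 for c in self.calls if c.is_missing)


@dataclass
class VariantTable:
    """Ordered multi-sample variant sites — the pipeline's central carrier."""

    roster: tuple[str, ...]
    index: GenomeIndex
    sites: tuple[VariantSite, ...]
    _sample_idx: dict[str, int] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.roster = tuple(self.roster)
        self.sites = tuple(self.sites)
        if len(set(self.roster)) != len(self.roster):
            raise ValueError("duplicate sample names in roster")
        self._sample_idx = {name: i for i, name in enumerate(self.roster)}
        known = set(self.index.names)
        seen: set[tuple[str, int]] = set()
        prev_key: tuple[int, int] | None = None
        for site in self.sites:
            if site.chrom not in known:
                raise ValueError(f"site on chromosome {site.chrom!r} absent from index")
            if len(site.calls) != len(self.roster):
                raise ValueError(
                    f"call count mismatch at {site.chrom}:{site.pos}: "
                    f"{len(site.calls)} calls for {len(self.roster)} samples"
                )
            key = (site.chrom, site.pos)
            if key in seen:
                raise ValueError(f"duplicate site {site.chrom}:{site.pos}")
            seen.add(key)
            sort_key = (self.index.rank(site.chrom), site.pos)
            if prev_key is not None and sort_key < prev_key:
                raise ValueError("sites out of order; sort before constructing the table")
            prev_key = sort_key

    def sample_index(self, name: str) -> int:
        try:
            return self._sample_idx[name]
        except KeyError:
            raise KeyError(f"sample {name!r} not in roster") from None

    def call(self, site: VariantSite, sample: str) -> GenotypeCall:
        return site.calls[self.sample_index(sample)]

    def sites_on(self, chrom: str) -> list[VariantSite]:
        return [s for s in self.sites if s.chrom == chrom]

    def with_sites(self, sites: Iterable[VariantSite]) -> "VariantTable":
        return VariantTable(self.roster, self.index, tuple(sites))

    def __len__(self) -> int:
        return len(self.sites)


def _as_call(sample_rec) -> GenotypeCall:
    gt = sample_rec.get("GT")
    alleles: tuple[int, int] | None
    if gt is None or all(a is None for a in gt):
        alleles = None
    elif any(a is None for a in gt):
        alleles = None  # half-calls treated as missing
    elif len(gt) == 1:
        alleles = (gt[0], gt[0])  # haploid call promoted to homozygous diploid
    else:
        alleles = (gt[0], gt[1])
    dp = sample_rec.get("DP")
    gq = sample_rec.get("GQ")
    return GenotypeCall(
        alleles,
        int(dp) if dp is not None else None,
        int(round(gq)) if gq is not None else None,
    )


def read_vcf(path: str | Path, index: GenomeIndex) -> VariantTable:
    """Parse a VCF v4.x file into a sorted :class:`VariantTable`.

    Genotypes lacking GT (or half-called) are missing; '.' DP/GQ parse as
    missing; phased separators are treated as unphased.  Records are sorted by
    (index chromosome order, position) regardless of file order.
    """
    try:
        vf = pysam.VariantFile(str(path))
    except (ValueError, OSError) as exc:
        raise VcfParseError(f"{path}: malformed VCF header: {exc}") from exc
    roster = tuple(vf.header.samples)
    sites: list[VariantSite] = []
    recno = 0
    try:
        for rec in vf:
            recno += 1
            if rec.alts is None:
                continue  # monomorphic record carries no variant alleles
            calls = tuple(_as_call(rec.samples[s]) for s in roster)
            flags = frozenset(f for f in rec.filter.keys() if f != "PASS")
            sites.append(
                VariantSite(
                    chrom=rec.chrom,
                    pos=rec.pos,
                    ref=rec.ref.upper(),
                    alts=tuple(a.upper() for a in rec.alts),
                    calls=calls,
                    filter_flags=flags,
                )
            )
    except (ValueError, OSError) as exc:
        raise VcfParseError(f"{path}: malformed VCF record #{recno + 1}: {exc}") from exc
    finally:
        vf.close()
    known = set(index.names)
    for site in sites:
        if site.chrom not in known:
            raise VcfParseError(
                f"{path}: site {site.chrom}:{site.pos} on chromosome absent from index"
            )
    sites.sort(key=lambda s: (index.rank(s.chrom), s.pos))
    return VariantTable(roster, index, tuple(sites))


def _fmt_call(call: GenotypeCall) -> str:
    if call.alleles is None:
        gt = "./."
    else:
        gt = f"{call.alleles[0]}/{call.alleles[1]}"
    dp = "." if call.depth is None else str(call.depth)
    gq = "." if call.quality is None else str(call.quality)
    return f"{gt}:{dp}:{gq}"


def write_vcf(table: VariantTable, path: str | Path) -> None:
    """Serialize a table as VCF v4.2 text (GT:DP:GQ), byte-stable for a given table."""
    opener = gzip.open if str(path).endswith(".gz") else open
    with opener(path, "wt") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for name, length in table.index.records:
            fh.write(f"##contig=<ID={name},length={length}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">\n')
        fh.write(
            '##FORMAT=<ID=GQ,Number=1,Type=Integer,Description="Genotype quality">\n'
        )
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(table.roster)
            + "\n"
        )
        for site in table.sites:
            flt = ";".join(sorted(site.filter_flags)) if site.filter_flags else "PASS"
            row = [
                site.chrom,
                str(site.pos),
                ".",
                site.ref,
                ",".join(site.alts),
                ".",
                flt,
                ".",
                "GT:DP:GQ",
            ] + [_fmt_call(c) for c in site.calls]
            fh.write("\t".join(row) + "\n")


def write_bed(blocks: Sequence, path: str | Path) -> None:
    """Write BED4 lines (chrom, 0-based half-open start/end, label), sorted.

    Accepts any records with chrom/start/end/label attributes or 4-tuples.
    """
    rows = []
    for b in blocks:
        if hasattr(b, "chrom"):
            chrom, start, end, label = b.chrom, b.start, b.end, b.label
        else:
            chrom, start, end, label = b
        if start >= end:
            raise ValueError(f"empty or inverted interval {chrom}:{start}-{end}")
        rows.append((chrom, int(start), int(end), str(label)))
    rows.sort()
    with open(path, "w") as fh:
        for chrom, start, end, label in rows:
            fh.write(f"{chrom}\t{start}\t{end}\t{label}\n")


def read_bed(path: str | Path) -> list[tuple[str, int, int, str]]:
    out = []
    with open(path) as fh:
        for line in fh:
            if not line.strip():
                continue
            chrom, start, end, label = line.rstrip("\n").split("\t")[:4]
            out.append((chrom, int(start), int(end), label))
    return out


def write_alignment(
    samples: Sequence[str],
    rows: Sequence[str],
    path: str | Path,
    format: str = "phylip",
) -> None:
    """Write an alignment as FASTA or relaxed PHYLIP ("ntaxa nchar" header).

    All rows must be equal length over the A,C,G,T,N alphabet; sample order is
    preserved.
    """
    if len(samples) != len(rows):
        raise ValueError("sample/row count mismatch")
    if not rows or not rows[0]:
        raise ValueError("empty alignment rejected")
    length = len(rows[0])
    for name, row in zip(samples, rows):
        if len(row) != length:
            raise ValueError(f"ragged alignment row for {name!r}")
        if set(row) - set("ACGTN"):
            raise ValueError(f"invalid characters in row for {name!r}")
    if format == "phylip":
        for name in samples:
            if any(ch.isspace() for ch in name):
                raise ValueError(f"whitespace in name {name!r} is ambiguous in PHYLIP")
        with open(path, "w") as fh:
            fh.write(f"{len(samples)} {length}\n")
            for name, row in zip(samples, rows):
                fh.write(f"{name} {row}\n")
    elif format == "fasta":
        with open(path, "w") as fh:
            for name, row in zip(samples, rows):
                fh.write(f">{name}\n{row}\n")
    else:
        raise ValueError(f"unknown alignment format {format!r}")
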