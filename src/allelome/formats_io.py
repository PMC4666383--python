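"""Input parsing, derived annotations, and result writers.

All BED-derived coordinates are 0-based half-open; VCF positions are
converted from 1-based on read. The SNP name-field dialect is
``"<allele1>|<allele2>"`` with strain1's base first, uppercase.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pysam

__all__ = [
    "SnpRecord",
    "Locus",
    "CrossDesign",
    "ParseError",
    "ValidationError",
    "CATEGORY_COLORS",
    "load_snp_bed",
    "write_snp_bed",
    "snps_from_vcf",
    "load_annotation_bed",
    "write_annotation_bed",
    "load_chrom_sizes",
    "make_tss_windows",
    "make_sliding_windows",
    "write_results_table",
    "write_browser_bed",
]

_BASES = frozenset("ACGT")


class ParseError(ValueError):
    """A line of an input file could not be parsed."""


class ValidationError(ValueError):
    """Parsed input violates a domain invariant."""


@dataclass(frozen=True, order=True)
class SnpRecord:
    """One biallelic SNP position distinguishing the two strains.

    ``allele1`` is the base carried by strain1, ``allele2`` by strain2.
    ``pos`` is 0-based.
    """

    chrom: str
    pos: int
    allele1: str
    allele2: str
    id: str = ""

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValidationError("SNP with empty chrom")
        if self.pos < 0:
            raise ValidationError(f"SNP with negative position {self.pos}")
        if self.allele1 not in _BASES or self.allele2 not in _BASES:
            raise ValidationError(
                f"SNP {self.chrom}:{self.pos}: alleles must be A/C/G/T, "
                f"got {self.allele1!r}|{self.allele2!r}"
            )
        if self.allele1 == self.allele2:
            raise ValidationError(
                f"SNP {self.chrom}:{self.pos}: identical alleles {self.allele1!r}"
            )


@dataclass(frozen=True)
class Locus:
    """A named, stranded set of merged genomic intervals on one chromosome."""

    name: str
    chrom: str
    strand: str
    intervals: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        if self.strand not in {"+", "-", "."}:
            raise ValidationError(f"locus {self.name}: bad strand {self.strand!r}")
        if not self.intervals:
            raise ValidationError(f"locus {self.name}: no intervals")
        prev_end = -1
        for start, end in self.intervals:
            if end <= start:
                raise ValidationError(
                    f"locus {self.name}: empty interval [{start},{end})"
                )
            if start < prev_end:
                raise ValidationError(f"locus {self.name}: intervals overlap")
            prev_end = end

    @property
    def start(self) -> int:
        return self.intervals[0][0]

    @property
    def end(self) -> int:
        return self.intervals[-1][1]

    def contains(self, pos: int) -> bool:
        return any(s <= pos < e for s, e in self.intervals)


@dataclass(frozen=True)
class CrossDesign:
    """Roles of the four samples: two forward-cross and two reverse-cross
    replicates. In the forward cross the mother is strain1, so maternal
    reads carry allele1; in the reverse cross maternal reads carry allele2.
    """

    sample_roles: tuple[tuple[str, int], ...] = (
        ("forward", 1),
        ("forward", 2),
        ("reverse", 1),
        ("reverse", 2),
    )

    def __post_init__(self) -> None:
        if len(self.sample_roles) != 4:
            raise ValidationError("cross design requires exactly four samples")
        dirs = [d for d, _ in self.sample_roles]
        if dirs.count("forward") != 2 or dirs.count("reverse") != 2:
            raise ValidationError(
                "cross design requires two forward and two reverse samples"
            )
        for d, rep in self.sample_roles:
            if rep not in (1, 2):
                raise ValidationError(f"replicate must be 1 or 2, got {rep}")

    def direction(self, sample_index: int) -> str:
        return self.sample_roles[sample_index][0]

    @property
    def mock_inverted_samples(self) -> tuple[int, int]:
        """Indices of replicate 2 of each cross (the samples negated in the
        mock analysis)."""
        return tuple(
            i for i, (_, rep) in enumerate(self.sample_roles) if rep == 2
        )


# ---------------------------------------------------------------------------
# SNP files


def load_snp_bed(path: str | Path) -> list[SnpRecord]:
    """Read a BED4+ SNP file whose name field is "<allele1>|<allele2>".

    Returns records sorted by (chrom, pos). Duplicate positions and
    malformed name fields are hard errors.
    """
    records: list[SnpRecord] = []
    seen: set[tuple[str, int]] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise ParseError(f"{path}:{lineno}: expected ≥4 tab-separated fields")
            chrom, start_s, end_s, name = fields[:4]
            try:
                start, end = int(start_s), int(end_s)
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: non-numeric coordinates") from exc
            if end - start != 1:
                raise ValidationError(
                    f"{path}:{lineno}: SNP interval must have length 1"
                )
            parts = name.split("|")
            if len(parts) != 2 or not all(p in _BASES for p in parts):
                raise ParseError(
                    f"{path}:{lineno}: name field must be '<allele1>|<allele2>' "
                    f"with A/C/G/T alleles, got {name!r}"
                )
            if parts[0] == parts[1]:
                raise ValidationError(f"{path}:{lineno}: identical alleles {name!r}")
            if (chrom, start) in seen:
                raise ValidationError(
                    f"{path}:{lineno}: duplicate SNP position {chrom}:{start}"
                )
            seen.add((chrom, start))
            records.append(SnpRecord(chrom, start, parts[0], parts[1]))
    records.sort()
    return records


def write_snp_bed(snps: Iterable[SnpRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for s in sorted(snps):
            fh.write(f"{s.chrom}\t{s.pos}\t{s.pos + 1}\t{s.allele1}|{s.allele2}\n")


def _load_exclude_intervals(path: str | Path) -> dict[str, list[tuple[int, int]]]:
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            by_chrom.setdefault(f[0], []).append((int(f[1]), int(f[2])))
    for ivs in by_chrom.values():
        ivs.sort()
    return by_chrom


def snps_from_vcf(
    vcf: str | Path,
    strain1: str,
    strain2: str,
    exclude: str | Path | None = None,
    min_gq: int | None = None,
) -> tuple[list[SnpRecord], dict[str, int]]:
    """Extract strain-distinguishing SNPs from a VCF.

    A site is kept when it passes FILTER, both strains are homozygous with
    called genotypes, the two homozygous alleles differ and are single
    bases, both genotypes pass the optional GQ threshold, and the site does
    not overlap an exclusion interval (e.g. annotated pseudogenes).

    Returns the SNP list plus a counter of skip reasons.
    """
    excl = _load_exclude_intervals(exclude) if exclude else {}
    stats = {
        "kept": 0,
        "filtered": 0,
        "not_homozygous": 0,
        "same_allele": 0,
        "not_snv": 0,
        "low_gq": 0,
        "excluded_region": 0,
    }
    records: list[SnpRecord] = []
    with pysam.VariantFile(str(vcf)) as vf:
        samples = list(vf.header.samples)
        for col in (strain1, strain2):
            if col not in samples:
                raise ValidationError(f"VCF has no genotype column {col!r}")
        for rec in vf:
            if rec.filter.keys() not in ([], ["PASS"], ["."]):
                stats["filtered"] += 1
                continue
            alleles1 = rec.samples[strain1].alleles
            alleles2 = rec.samples[strain2].alleles
            if any(a is None for a in alleles1) or any(a is None for a in alleles2):
                stats["not_homozygous"] += 1
                continue
            if len(set(alleles1)) != 1 or len(set(alleles2)) != 1:
                stats["not_homozygous"] += 1
                continue
            a1, a2 = alleles1[0].upper(), alleles2[0].upper()
            if a1 == a2:
                stats["same_allele"] += 1
                continue
            if a1 not in _BASES or a2 not in _BASES:
                stats["not_snv"] += 1
                continue
            if min_gq is not None:
                gqs = (rec.samples[strain1].get("GQ"), rec.samples[strain2].get("GQ"))
                if any(g is None or g < min_gq for g in gqs):
                    stats["low_gq"] += 1
                    continue
            pos0 = rec.pos - 1  # VCF is 1-based
            if any(
                s <= pos0 < e for s, e in excl.get(rec.chrom, ())
            ):
                stats["excluded_region"] += 1
                continue
            records.append(SnpRecord(rec.chrom, pos0, a1, a2, rec.id or ""))
            stats["kept"] += 1
    records.sort()
    return records, stats


# ---------------------------------------------------------------------------
# Annotations


def _merge_intervals(ivs: list[tuple[int, int]]) -> tuple[tuple[int, int], ...]:
    ivs = sorted(ivs)
    merged = [list(ivs[0])]
    for s, e in ivs[1:]:
        if s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return tuple((s, e) for s, e in merged)


def load_annotation_bed(path: str | Path, min_length: int = 0) -> list[Locus]:
    """Read a BED6 annotation and merge same-name rows into single loci.

    Rows shorter than ``min_length`` are dropped before merging. Rows that
    share a name across chromosomes or strands are rejected.
    """
    rows: dict[str, dict] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            if len(f) < 6:
                raise ParseError(f"{path}:{lineno}: expected BED6 (≥6 fields)")
            chrom, start_s, end_s, name, _score, strand = f[:6]
            try:
                start, end = int(start_s), int(end_s)
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: non-numeric coordinates") from exc
            if end <= start:
                raise ValidationError(f"{path}:{lineno}: end ≤ start")
            if strand not in {"+", "-", "."}:
                raise ParseError(f"{path}:{lineno}: bad strand {strand!r}")
            if end - start < min_length:
                continue
            entry = rows.setdefault(
                name, {"chrom": chrom, "strand": strand, "ivs": []}
            )
            if entry["chrom"] != chrom:
                raise ValidationError(
                    f"annotation name {name!r} appears on both "
                    f"{entry['chrom']} and {chrom}"
                )
            if entry["strand"] != strand:
                raise ValidationError(
                    f"annotation name {name!r} appears on both strands"
                )
            entry["ivs"].append((start, end))
    loci = [
        Locus(name, e["chrom"], e["strand"], _merge_intervals(e["ivs"]))
        for name, e in rows.items()
    ]
    loci.sort(key=lambda l: (l.chrom, l.start, l.name))
    return loci


def write_annotation_bed(loci: Iterable[Locus], path: str | Path) -> None:
    """Write loci as BED6, one row per interval (re-loadable/round-trippable)."""
    with open(path, "w") as fh:
        for loc in sorted(loci, key=lambda l: (l.chrom, l.start, l.name)):
            for s, e in loc.intervals:
                fh.write(f"{loc.chrom}\t{s}\t{e}\t{loc.name}\t0\t{loc.strand}\n")


def load_chrom_sizes(path: str | Path) -> dict[str, int]:
    sizes: dict[str, int] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            contig, length = line.split("\t")[:2]
            sizes[contig] = int(length)
    return sizes


def make_tss_windows(loci: Iterable[Locus], flank: int) -> list[Locus]:
    """Windows of ±``flank`` bp around each locus's transcription start site.

    The TSS is the leftmost coordinate for "+" loci and the rightmost for
    "-" loci; isoform rows already merged under one name contribute the TSS
    of the merged span. Windows are clipped at zero.
    """
    out: list[Locus] = []
    for loc in loci:
        if loc.strand not in {"+", "-"}:
            raise ValidationError(
                f"TSS undefined for unstranded locus {loc.name!r}"
            )
        tss = loc.start if loc.strand == "+" else loc.end
        start = max(0, tss - flank)
        end = tss + flank
        out.append(Locus(loc.name, loc.chrom, loc.strand, ((start, end),)))
    out.sort(key=lambda l: (l.chrom, l.start, l.name))
    return out


def make_sliding_windows(
    chrom_sizes: Mapping[str, int], window: int, step: int
) -> list[Locus]:
    """Tile every contig with [k·step, k·step+window) windows clipped at the
    contig end; names are "contig:start-end", strand ".".
    """
    if not (window >= step >= 1):
        raise ValidationError(
            f"require window ≥ step ≥ 1, got window={window} step={step}"
        )
    out: list[Locus] = []
    for contig in sorted(chrom_sizes):
        length = chrom_sizes[contig]
        start = 0
        while start < length:
            end = min(start + window, length)
            out.append(
                Locus(f"{contig}:{start}-{end}", contig, ".", ((start, end),))
            )
            start += step
    return out


# ---------------------------------------------------------------------------
# Result writers

# itemRgb per category, following the conventional colour assignments:
# maternal red, paternal blue, strain1 brown, strain2 turquoise, biallelic
# green, non-informative gray, no-SNP black.
CATEGORY_COLORS = {
    "MAT": "255,0,0",
    "PAT": "0,0,255",
    "STRAIN1": "139,69,19",
    "STRAIN2": "64,224,208",
    "BAE": "0,255,0",
    "NI": "128,128,128",
    "NS": "0,0,0",
}

_RESULT_COLUMNS = [
    "name",
    "chrom",
    "start",
    "end",
    "strand",
    "category",
    "i_score",
    "s_score",
    "allelic_ratio",
    "total_reads_1",
    "total_reads_2",
    "total_reads_3",
    "total_reads_4",
    "snps_covered",
]


def _fmt(value, digits: int = 4) -> str:
    if value is None:
        return "NA"
    if isinstance(value, float):
        if math.isinf(value):
            return "inf"
        return f"{value:.{digits}f}"
    return str(value)


def _sorted_calls(calls):
    return sorted(calls, key=lambda c: (c.locus.chrom, c.locus.start, c.locus.name))


def write_results_table(calls, path: str | Path, header_meta: Mapping | None = None) -> None:
    """Write the per-locus result TSV, deterministically ordered by
    (chrom, start, name). Missing statistics (NS loci) are written as NA.
    """
    with open(path, "w") as fh:
        if header_meta:
            for key in sorted(header_meta):
                fh.write(f"# {key}={header_meta[key]}\n")
        fh.write("\t".join(_RESULT_COLUMNS) + "\n")
        for c in _sorted_calls(calls):
            loc = c.locus
            row = [
                loc.name,
                loc.chrom,
                str(loc.start),
                str(loc.end),
                loc.strand,
                c.category,
                _fmt(c.i_score),
                _fmt(c.s_score),
                _fmt(c.allelic_ratio),
                *(str(t) for t in c.sample_totals),
                str(c.snps_covered),
            ]
            fh.write("\t".join(row) + "\n")


def write_browser_bed(calls, path: str | Path, track_name: str = "allelome") -> None:
    """Write a BED9 genome-browser track, one row per locus span, coloured
    by category; the BED score field is the summary-score magnitude capped
    at 1000."""
    with open(path, "w") as fh:
        fh.write(f'track name="{track_name}" itemRgb="On"\n')
        for c in _sorted_calls(calls):
            loc = c.locus
            score = 0
            summary = c.i_score if c.category in ("MAT", "PAT") else c.s_score
            if summary is not None:
                score = int(round(min(abs(summary), 1000.0)))
            fh.write(
                "\t".join(
                    [
                        loc.chrom,
                        str(loc.start),
                        str(loc.end),
                        f"{loc.name}_{c.category}",
                        str(score),
                        loc.strand,
                        str(loc.start),
                        str(loc.end),
                        CATEGORY_COLORS[c.category],
                    ]
                )
                + "\n"
            )
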