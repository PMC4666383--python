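"""SNP-resolved allele counting from aligned reads.

Every counted fragment contributes to exactly one SNP: each mate is
logically trimmed to its leftmost covered SNP, and a fragment whose mates
resolve to different SNPs is counted only at the leftmost of the two.
Mates covering the same SNP are deduplicated (mate 1's base wins; if the
bases disagree the fragment is counted as "other").
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pysam

from .formats_io import Locus, SnpRecord, ValidationError

__all__ = [
    "SnpSampleCounts",
    "SampleAlleleCounts",
    "intersect_snps_loci",
    "assign_read_to_snp",
    "pileup_alleles",
    "aggregate_locus_counts",
]

STRANDEDNESS_MODES = ("unstranded", "forward", "reverse")


@dataclass
class SnpSampleCounts:
    """Per-SNP, per-sample allele tallies within one locus."""

    snp: SnpRecord
    locus_name: str
    sample_index: int
    n1: int = 0  # reads carrying allele1 (strain1)
    n2: int = 0  # reads carrying allele2 (strain2)
    n_other: int = 0  # any other base, or discordant mate pairs


@dataclass(frozen=True)
class SampleAlleleCounts:
    """Per-locus, per-sample counts summed over SNPs passing minread."""

    locus_name: str
    sample_index: int
    N1: int
    N2: int
    snps_covered: int

    @property
    def total(self) -> int:
        return self.N1 + self.N2


def intersect_snps_loci(
    snps: Sequence[SnpRecord], loci: Iterable[Locus]
) -> dict[str, list[SnpRecord]]:
    """Attach each SNP to every locus whose intervals contain its position.

    A SNP inside two overlapping loci serves both; loci without SNPs map to
    an empty list (they become NS downstream).
    """
    by_chrom: dict[str, list[SnpRecord]] = {}
    for s in snps:
        by_chrom.setdefault(s.chrom, []).append(s)
    for lst in by_chrom.values():
        lst.sort(key=lambda s: s.pos)

    import bisect

    result: dict[str, list[SnpRecord]] = {}
    for loc in loci:
        chrom_snps = by_chrom.get(loc.chrom, [])
        positions = [s.pos for s in chrom_snps]
        hits: list[SnpRecord] = []
        for start, end in loc.intervals:
            lo = bisect.bisect_left(positions, start)
            hi = bisect.bisect_left(positions, end)
            hits.extend(chrom_snps[lo:hi])
        result[loc.name] = hits
    return result


def _ref_to_query(read: pysam.AlignedSegment, ref_pos: int) -> int | None:
    """Query index aligned to ``ref_pos``, or None if the position falls in
    a deletion/intron or outside the read. Walks the CIGAR directly."""
    if read.cigartuples is None:
        return None
    rpos = read.reference_start
    qpos = 0
    for op, length in read.cigartuples:
        if op in (0, 7, 8):  # M, =, X consume both
            if rpos <= ref_pos < rpos + length:
                return qpos + (ref_pos - rpos)
            rpos += length
            qpos += length
        elif op in (2, 3):  # D, N consume reference only
            if rpos <= ref_pos < rpos + length:
                return None
            rpos += length
        elif op in (1, 4):  # I, S consume query only
            qpos += length
        # H, P consume neither
        if rpos > ref_pos:
            return None
    return None


def assign_read_to_snp(
    read: pysam.AlignedSegment,
    snps_in_region: Sequence[SnpRecord],
    min_base_quality: int = 0,
) -> tuple[SnpRecord, str, int] | None:
    """Assign an aligned read to the leftmost SNP its aligned bases cover.

    Positions deleted in the read or spanned by introns do not count as
    covered, nor do bases below ``min_base_quality``. Returns
    (snp, observed base, base quality) or None.
    """
    start, end = read.reference_start, read.reference_end
    if end is None:
        return None
    seq = read.query_sequence
    if seq is None:
        return None
    quals = read.query_qualities
    for snp in snps_in_region:
        if snp.pos < start:
            continue
        if snp.pos >= end:
            break
        qidx = _ref_to_query(read, snp.pos)
        if qidx is None:
            continue
        q = quals[qidx] if quals is not None else 255
        if q < min_base_quality:
            continue
        return snp, seq[qidx].upper(), q
    return None


def _fragment_strand(read: pysam.AlignedSegment) -> str:
    """Strand of the cDNA fragment for a forward-stranded library: the
    orientation of mate 1 (or of the read itself when single-end)."""
    if read.is_paired:
        if read.is_read1:
            return "-" if read.is_reverse else "+"
        return "-" if read.mate_is_reverse else "+"
    return "-" if read.is_reverse else "+"


def _strand_compatible(read: pysam.AlignedSegment, locus: Locus, mode: str) -> bool:
    if mode == "unstranded" or locus.strand == ".":
        return True
    frag = _fragment_strand(read)
    if mode == "reverse":  # dUTP: fragment strand opposite of mate 1
        frag = "+" if frag == "-" else "-"
    return frag == locus.strand


def _read_passes_flags(read: pysam.AlignedSegment, include_duplicates: bool) -> bool:
    if read.is_unmapped or read.is_secondary or read.is_supplementary:
        return False
    if read.is_qcfail:
        return False
    if read.is_duplicate and not include_duplicates:
        return False
    return True


def pileup_alleles(
    bam: str | Path,
    locus_snps: Mapping[str, list[SnpRecord]],
    loci: Iterable[Locus],
    sample_index: int,
    strandedness: str = "unstranded",
    min_base_quality: int = 0,
    include_duplicates: bool = False,
) -> dict[str, list[SnpSampleCounts]]:
    """Count allele-informative fragments at every SNP of every locus.

    Requires a coordinate-sorted, indexed BAM. Returns, per locus name, one
    ``SnpSampleCounts`` per SNP in that locus (zero-count entries included).
    Contigs named in the SNP set but absent from the BAM header produce a
    warning, not an error.
    """
    if strandedness not in STRANDEDNESS_MODES:
        raise ValidationError(f"unknown strandedness mode {strandedness!r}")
    result: dict[str, list[SnpSampleCounts]] = {}
    with pysam.AlignmentFile(str(bam), "rb") as af:
        header_contigs = set(af.references)
        missing: set[str] = set()
        for loc in loci:
            snps = locus_snps.get(loc.name, [])
            counts = [
                SnpSampleCounts(snp, loc.name, sample_index) for snp in snps
            ]
            result[loc.name] = counts
            if not snps:
                continue
            if loc.chrom not in header_contigs:
                missing.add(loc.chrom)
                continue
            by_pos = {c.snp.pos: c for c in counts}
            # fragment name -> (snp_pos, base, is_read1)
            frag_obs: dict[str, tuple[int, str, bool]] = {}
            for start, end in loc.intervals:
                for read in af.fetch(loc.chrom, start, end):
                    if not _read_passes_flags(read, include_duplicates):
                        continue
                    if not _strand_compatible(read, loc, strandedness):
                        continue
                    hit = assign_read_to_snp(read, snps, min_base_quality)
                    if hit is None:
                        continue
                    snp, base, _q = hit
                    name = read.query_name
                    is_r1 = (not read.is_paired) or read.is_read1
                    prev = frag_obs.get(name)
                    if prev is None:
                        frag_obs[name] = (snp.pos, base, is_r1)
                        continue
                    ppos, pbase, p_r1 = prev
                    if snp.pos == ppos:
                        if pbase != base:
                            frag_obs[name] = (ppos, "*", p_r1)  # discordant
                        elif is_r1 and not p_r1:
                            frag_obs[name] = (snp.pos, base, True)
                        # same SNP, same base: keep first (dedup)
                    elif snp.pos < ppos:
                        # fragment counts only at its leftmost SNP
                        frag_obs[name] = (snp.pos, base, is_r1)
            for pos, base, _r1 in frag_obs.values():
                c = by_pos[pos]
                if base == c.snp.allele1:
                    c.n1 += 1
                elif base == c.snp.allele2:
                    c.n2 += 1
                else:
                    c.n_other += 1
        if missing:
            warnings.warn(
                f"contigs absent from BAM header skipped: {sorted(missing)}",
                stacklevel=2,
            )
    return result


def aggregate_locus_counts(
    pileups: Mapping[str, list[SnpSampleCounts]],
    sample_index: int,
    minread: int = 1,
) -> dict[str, SampleAlleleCounts]:
    """Sum per-SNP counts to locus level for one sample.

    A SNP enters the sums only when n1+n2 ≥ ``minread`` in *this* sample, so
    a SNP may be counted in one replicate and excluded in another. Reads
    with non-allelic bases (n_other) never enter N1/N2.
    """
    if minread < 1:
        raise ValidationError(f"minread must be ≥ 1, got {minread}")
    out: dict[str, SampleAlleleCounts] = {}
    for locus_name, counts in pileups.items():
        N1 = N2 = covered = 0
        for c in counts:
            if c.n1 + c.n2 >= minread:
                N1 += c.n1
                N2 += c.n2
                covered += 1
        out[locus_name] = SampleAlleleCounts(
            locus_name, sample_index, N1, N2, covered
        )
    return out
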