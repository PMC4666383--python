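"""Self-contained simulation of reciprocal-cross allele-specific read data.

The generator emits everything a run needs — SNP BED, annotation BED, four
coordinate-sorted indexed BAMs and a ground-truth TSV — on toy contigs,
with known per-locus allelic state. Reads are emitted pre-aligned (one
full-match segment covering exactly one SNP), since alignment is upstream
of this tool; a FASTQ emitter is available for end-to-end demos with an
external aligner.

Per locus, SNP and sample the read total is Poisson(depth_per_snp) and each
read's allele is Bernoulli(true_ratio) for the favored allele. For parental
truth the favored allele maps through the cross direction (forward cross:
maternal = strain1); for strain truth it is the favored strain in every
sample. Per-base sequencing errors substitute a uniformly random other base
at the configured rate.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pysam

from .formats_io import (
    CrossDesign,
    Locus,
    SnpRecord,
    ValidationError,
    write_annotation_bed,
    write_snp_bed,
)

__all__ = [
    "TruthLocus",
    "SimulatedDataset",
    "simulate_cross",
    "simulate_pure_strain_mixing",
    "recovery_truth",
]

_BASES = "ACGT"


@dataclass(frozen=True)
class TruthLocus:
    """Ground truth for one simulated locus."""

    name: str
    true_category: str  # MAT, PAT, STRAIN1, STRAIN2, BAE, NI, NS
    true_ratio: float = 0.5  # probability of the favored allele
    depth_per_snp: float = 30.0  # expected reads per SNP per sample
    n_snps: int = 8
    error_rate: float = 0.0

    def __post_init__(self) -> None:
        if self.true_category == "BAE" and self.true_ratio != 0.5:
            raise ValidationError(f"{self.name}: BAE truth requires ratio 0.5")
        if self.true_category in ("MAT", "PAT", "STRAIN1", "STRAIN2") and not (
            0.5 < self.true_ratio <= 1.0
        ):
            raise ValidationError(f"{self.name}: biased truth requires ratio > 0.5")
        if self.depth_per_snp < 0 or self.n_snps < 0:
            raise ValidationError(f"{self.name}: negative depth or SNP count")
        if not (0.0 <= self.error_rate < 1.0):
            raise ValidationError(f"{self.name}: error rate must be in [0, 1)")


@dataclass
class SimulatedDataset:
    outdir: Path
    bam_paths: tuple[Path, Path, Path, Path]
    snp_bed: Path
    annotation_bed: Path
    truth_tsv: Path
    design: CrossDesign
    truth: tuple[TruthLocus, ...]


def _favored_allele_prob(
    truth: TruthLocus, direction: str
) -> float:
    """Probability that a read carries allele1 (the strain1 base)."""
    cat, r = truth.true_category, truth.true_ratio
    if cat == "STRAIN1":
        return r
    if cat == "STRAIN2":
        return 1.0 - r
    if cat in ("MAT", "PAT"):
        maternal_is_allele1 = direction == "forward"
        favored_maternal = cat == "MAT"
        p_maternal = r if favored_maternal else 1.0 - r
        return p_maternal if maternal_is_allele1 else 1.0 - p_maternal
    return 0.5  # BAE / NI / NS


def _apply_errors(seq: str, rng: np.random.Generator, rate: float) -> str:
    """Substitute a uniformly random different base at each position with
    probability ``rate``."""
    hits = np.nonzero(rng.random(len(seq)) < rate)[0]
    if hits.size == 0:
        return seq
    chars = list(seq)
    offsets = rng.integers(1, 4, size=hits.size)
    for i, off in zip(hits, offsets):
        chars[i] = _BASES[(_BASES.index(chars[i]) + off) % 4]
    return "".join(chars)


def simulate_cross(
    truth: Sequence[TruthLocus],
    outdir: str | Path,
    design: CrossDesign | None = None,
    read_length: int = 50,
    paired: bool = False,
    seed: int = 0,
    contig: str = "chrT",
    emit_fastq: bool = False,
) -> SimulatedDataset:
    """Generate SNPs, annotation, truth table and four sample BAMs.

    Loci are laid out left to right on one toy contig with SNPs spaced
    ``read_length + 10`` apart, so each read covers exactly one SNP. Output
    is deterministic for a given seed (one RNG stream per sample file).
    """
    design = design or CrossDesign()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    spacing = read_length + 10
    margin = read_length + 10
    layout_rng = np.random.default_rng(np.random.SeedSequence([seed, 0]))

    loci: list[Locus] = []
    snps: list[SnpRecord] = []
    snps_by_locus: dict[str, list[SnpRecord]] = {}
    cursor = margin
    for tl in truth:
        span = max(tl.n_snps, 1) * spacing
        start, end = cursor, cursor + span
        loci.append(Locus(tl.name, contig, "+", ((start, end),)))
        locus_snps = []
        for j in range(tl.n_snps):
            pos = start + j * spacing + spacing // 2
            a1 = _BASES[layout_rng.integers(4)]
            a2 = _BASES[(( _BASES.index(a1)) + 1 + layout_rng.integers(3)) % 4]
            snp = SnpRecord(contig, pos, a1, a2)
            locus_snps.append(snp)
            snps.append(snp)
        snps_by_locus[tl.name] = locus_snps
        cursor = end + margin
    contig_len = cursor + margin

    snp_bed = outdir / "snps.bed"
    ann_bed = outdir / "annotation.bed"
    truth_tsv = outdir / "truth.tsv"
    write_snp_bed(snps, snp_bed)
    write_annotation_bed(loci, ann_bed)
    with open(truth_tsv, "w") as fh:
        fh.write(f"# seed={seed}\n")
        fh.write("name\ttrue_category\ttrue_ratio\tdepth_per_snp\tn_snps\terror_rate\n")
        for tl in truth:
            fh.write(
                f"{tl.name}\t{tl.true_category}\t{tl.true_ratio}\t"
                f"{tl.depth_per_snp}\t{tl.n_snps}\t{tl.error_rate}\n"
            )

    header = {
        "HD": {"VN": "1.6", "SO": "coordinate"},
        "SQ": [{"SN": contig, "LN": contig_len}],
    }
    bam_paths = []
    for sample_index, (direction, rep) in enumerate(design.sample_roles):
        rng = np.random.default_rng(
            np.random.SeedSequence([seed, 1 + sample_index])
        )
        # (start, qname, seq, flagset) tuples collected then written sorted
        reads: list[tuple[int, str, str]] = []
        backbone = "A" * read_length
        for tl in truth:
            p_allele1 = _favored_allele_prob(tl, direction)
            for snp_idx, snp in enumerate(snps_by_locus[tl.name]):
                n_reads = rng.poisson(tl.depth_per_snp)
                if n_reads == 0:
                    continue
                lo = max(0, snp.pos - read_length + 1)
                starts = rng.integers(lo, snp.pos + 1, size=n_reads)
                is_a1 = rng.random(n_reads) < p_allele1
                for i in range(n_reads):
                    start = int(starts[i])
                    off = snp.pos - start
                    base = snp.allele1 if is_a1[i] else snp.allele2
                    seq = backbone[:off] + base + backbone[off + 1:]
                    if tl.error_rate > 0:
                        seq = _apply_errors(seq, rng, tl.error_rate)
                    qname = f"{tl.name}_s{snp_idx}_r{i}_{sample_index}"
                    reads.append((start, qname, seq))
        reads.sort(key=lambda r: (r[0], r[1]))

        bam_path = outdir / f"sample{sample_index + 1}_{direction}_{rep}.bam"
        fastq_records = []
        qual = pysam.qualitystring_to_array("I" * read_length)
        cigar = [(0, read_length)]
        with pysam.AlignmentFile(str(bam_path), "wb", header=header) as bf:
            for start, qname, seq in reads:
                mates = ((99, True), (147, False)) if paired else ((0, True),)
                for flag, is_r1 in mates:
                    a = pysam.AlignedSegment(bf.header)
                    a.query_name = qname
                    a.query_sequence = seq
                    a.reference_id = 0
                    a.reference_start = start
                    a.mapping_quality = 60
                    a.cigartuples = cigar
                    a.query_qualities = qual
                    a.flag = flag
                    if paired:
                        a.next_reference_id = 0
                        a.next_reference_start = start
                        a.template_length = read_length if is_r1 else -read_length
                    bf.write(a)
                if emit_fastq:
                    fastq_records.append((qname, seq))
        pysam.index(str(bam_path))
        if emit_fastq:
            with open(bam_path.with_suffix(".fastq"), "w") as fq:
                for qname, seq in fastq_records:
                    fq.write(f"@{qname}\n{seq}\n+\n{'I' * len(seq)}\n")
        bam_paths.append(bam_path)

    return SimulatedDataset(
        outdir,
        tuple(bam_paths),
        snp_bed,
        ann_bed,
        truth_tsv,
        design,
        tuple(truth),
    )


def simulate_pure_strain_mixing(
    n_loci: int,
    depth: float,
    outdir: str | Path,
    seed: int = 0,
    n_strain_biased: int | None = None,
    strain_ratio: float = 0.8,
    n_snps: int = 8,
    error_rate: float = 0.0,
    **kwargs,
) -> SimulatedDataset:
    """Emulate an in-silico mixing experiment: equal aliquots of pure-strain
    reads combined identically into all four mock "cross" samples.

    Every locus has strain-ratio 0.5 (plus a subset with a true strain
    bias, as real mixed-strain data contains), identically in all samples,
    so any imprinted call is a false positive — the imprinted-call fraction
    of informative loci estimates the imprinted FDR. The strain-biased
    subset defaults to 5% of ``n_loci``; it anchors the empirical score
    cutoff the way genuine strain-bias genes do in real data (with no true
    biases anywhere, no cutoff can reach a low FDR target and every locus
    is non-informative). Pass ``n_strain_biased=0`` for a strictly null
    dataset.
    """
    if n_strain_biased is None:
        n_strain_biased = n_loci // 20
    truth = [
        TruthLocus(
            f"null_{i:05d}", "BAE", 0.5, depth, n_snps, error_rate
        )
        for i in range(n_loci)
    ]
    truth += [
        TruthLocus(
            f"strainbias_{i:05d}", "STRAIN1", strain_ratio, depth, n_snps, error_rate
        )
        for i in range(n_strain_biased)
    ]
    return simulate_cross(truth, outdir, seed=seed, **kwargs)


def recovery_truth(
    n_mat: int = 20,
    n_strain: int = 20,
    n_bae: int = 200,
    n_zero_depth: int = 20,
    n_no_snp: int = 10,
    depth: float = 30.0,
    n_snps: int = 8,
    error_rate: float = 0.01,
) -> list[TruthLocus]:
    """The parameter-recovery truth mix: strong maternal loci (ratio 0.95),
    strain1-biased loci (ratio 0.85), a biallelic majority, silent loci
    (depth 0 -> expected NI) and SNP-free loci (expected NS)."""
    truth: list[TruthLocus] = []
    truth += [
        TruthLocus(f"mat_{i:03d}", "MAT", 0.95, depth, n_snps, error_rate)
        for i in range(n_mat)
    ]
    truth += [
        TruthLocus(f"strain1_{i:03d}", "STRAIN1", 0.85, depth, n_snps, error_rate)
        for i in range(n_strain)
    ]
    truth += [
        TruthLocus(f"bae_{i:03d}", "BAE", 0.5, depth, n_snps, error_rate)
        for i in range(n_bae)
    ]
    truth += [
        TruthLocus(f"silent_{i:03d}", "NI", 0.5, 0.0, n_snps, error_rate)
        for i in range(n_zero_depth)
    ]
    truth += [
        TruthLocus(f"nosnp_{i:03d}", "NS", 0.5, depth, 0, error_rate)
        for i in range(n_no_snp)
    ]
    return truth
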