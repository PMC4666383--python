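"""Shared fixtures: hand-built alignment files and session-scoped
simulated datasets (generated at test time, nothing stored on disk)."""

from __future__ import annotations

from pathlib import Path

import pysam
import pytest

import allelome as al

FIXED_SEED = 42


def make_bam(path: Path, reads: list[dict], contigs: dict[str, int] | None = None) -> Path:
    """Write a coordinate-sorted, indexed BAM from read descriptions.

    Each read dict: name, start, seq; optional chrom, flag, cigar (defaults
    to full match), mapq, next_start.
    """
    contigs = contigs or {"chr1": 100_000}
    names = list(contigs)
    header = {
        "HD": {"VN": "1.6", "SO": "coordinate"},
        "SQ": [{"SN": c, "LN": contigs[c]} for c in names],
    }
    segs = []
    for r in reads:
        a = pysam.AlignedSegment(pysam.AlignmentHeader.from_dict(header))
        a.query_name = r["name"]
        a.query_sequence = r["seq"]
        a.reference_id = names.index(r.get("chrom", names[0]))
        a.reference_start = r["start"]
        a.mapping_quality = r.get("mapq", 60)
        a.cigarstring = r.get("cigar", f"{len(r['seq'])}M")
        a.query_qualities = pysam.qualitystring_to_array("I" * len(r["seq"]))
        a.flag = r.get("flag", 0)
        if "next_start" in r:
            a.next_reference_id = a.reference_id
            a.next_reference_start = r["next_start"]
        segs.append(a)
    segs.sort(key=lambda a: (a.reference_id, a.reference_start, a.query_name))
    with pysam.AlignmentFile(str(path), "wb", header=header) as bf:
        for a in segs:
            bf.write(a)
    pysam.index(str(path))
    return path


@pytest.fixture(scope="session")
def recovery_dataset(tmp_path_factory) -> al.SimulatedDataset:
    outdir = tmp_path_factory.mktemp("recovery")
    return al.simulate_cross(al.recovery_truth(), outdir, seed=FIXED_SEED)


@pytest.fixture(scope="session")
def recovery_run(recovery_dataset, tmp_path_factory) -> al.RunResult:
    cfg = al.RunConfig(
        recovery_dataset.snp_bed,
        recovery_dataset.annotation_bed,
        recovery_dataset.bam_paths,
        tmp_path_factory.mktemp("recovery_out"),
    )
    return al.run_pipeline(cfg)


@pytest.fixture(scope="session")
def recovery_truth_map(recovery_dataset) -> dict[str, str]:
    return {t.name: t.true_category for t in recovery_dataset.truth}


@pytest.fixture(scope="session")
def null_run(tmp_path_factory) -> al.RunResult:
    """Pure-null mixing dataset: 2000 biallelic loci, no true bias anywhere."""
    outdir = tmp_path_factory.mktemp("null")
    ds = al.simulate_pure_strain_mixing(
        2000, 30.0, outdir, seed=FIXED_SEED, n_strain_biased=0
    )
    cfg = al.RunConfig(
        ds.snp_bed, ds.annotation_bed, ds.bam_paths, outdir / "out"
    )
    return al.run_pipeline(cfg)


@pytest.fixture(scope="session")
def mixing_run(tmp_path_factory):
    """Strain-mixing dataset with its default strain-biased subset."""
    outdir = tmp_path_factory.mktemp("mixing")
    ds = al.simulate_pure_strain_mixing(2000, 30.0, outdir, seed=FIXED_SEED)
    cfg = al.RunConfig(
        ds.snp_bed, ds.annotation_bed, ds.bam_paths, outdir / "out"
    )
    return ds, al.run_pipeline(cfg)


@pytest.fixture()
def toy_locus() -> al.Locus:
    return al.Locus("GeneA", "chr1", "+", ((1000, 2000),))


@pytest.fixture()
def toy_snps() -> list[al.SnpRecord]:
    return [
        al.SnpRecord("chr1", 1100, "T", "C"),
        al.SnpRecord("chr1", 1500, "A", "G"),
    ]
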