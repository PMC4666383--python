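"""End-to-end run orchestration: load -> intersect -> pileup x4 ->
aggregate -> score -> FDR curve -> cutoff -> categorize -> write outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
import math
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import yaml

from . import categorize as _categorize
from . import counting as _counting
from . import scoring as _scoring
from .formats_io import (
    CrossDesign,
    ValidationError,
    load_annotation_bed,
    load_snp_bed,
    write_browser_bed,
    write_results_table,
)

__all__ = ["RunConfig", "RunResult", "run_pipeline"]

log = logging.getLogger("allelome")


@dataclass
class RunConfig:
    """Validated configuration of one analysis run.

    ``bams`` are ordered (forward,1), (forward,2), (reverse,1), (reverse,2).
    """

    snps: Path
    annotation: Path
    bams: Sequence[Path]
    outdir: Path
    fdr_target_percent: float = 1.0
    ratio_cutoff: float = 0.7
    minread: int = 1
    strandedness: str = "unstranded"
    min_base_quality: int = 0
    min_locus_length: int = 0
    one_sided: bool = False
    include_duplicates: bool = False
    strain1_name: str = "STRAIN1"
    strain2_name: str = "STRAIN2"

    def __post_init__(self) -> None:
        self.snps = Path(self.snps)
        self.annotation = Path(self.annotation)
        self.bams = tuple(Path(b) for b in self.bams)
        self.outdir = Path(self.outdir)
        if len(self.bams) != 4:
            raise ValidationError(
                f"exactly four BAM files are required, got {len(self.bams)}"
            )
        if not (0.0 < self.fdr_target_percent < 100.0):
            raise ValidationError("FDR target must be in (0, 100) percent")
        if not (0.5 < self.ratio_cutoff <= 1.0):
            raise ValidationError("ratio cutoff must be in (0.5, 1]")
        if self.minread < 1:
            raise ValidationError("minread must be ≥ 1")
        if self.strandedness not in _counting.STRANDEDNESS_MODES:
            raise ValidationError(
                f"unknown strandedness mode {self.strandedness!r}"
            )

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        """Load a plain-text (YAML) config file; keyword overrides win."""
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        data.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**data)

    def to_dict(self) -> dict:
        d = {}
        for k, v in self.__dict__.items():
            if isinstance(v, Path):
                v = str(v)
            elif isinstance(v, tuple):
                v = [str(x) for x in v]
            d[k] = v
        return d


@dataclass
class RunResult:
    calls: list
    scores: dict
    curve: list
    score_cutoff: float
    category_tally: dict
    paths: dict
    loci: list = field(default_factory=list)
    counts_by_locus: dict = field(default_factory=dict)
    locus_snps: dict = field(default_factory=dict)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: RunConfig, design: CrossDesign | None = None) -> RunResult:
    """Execute a full analysis and write the result bundle.

    Outputs under ``config.outdir``: results TSV, browser BED, FDR-curve
    TSV, allelic-ratio histogram TSV, and a JSON run log with input
    checksums, configuration, the score cutoff found and category tallies.
    Identical inputs and configuration give identical outputs.
    """
    design = design or CrossDesign()
    config.outdir.mkdir(parents=True, exist_ok=True)

    log.info("loading SNPs from %s", config.snps)
    snps = load_snp_bed(config.snps)
    log.info("loading annotation from %s", config.annotation)
    loci = load_annotation_bed(config.annotation, config.min_locus_length)
    locus_snps = _counting.intersect_snps_loci(snps, loci)

    counts_by_locus: dict[str, list] = {loc.name: [] for loc in loci}
    for i, bam in enumerate(config.bams):
        log.info("pileup sample %d: %s", i + 1, bam)
        pile = _counting.pileup_alleles(
            bam,
            locus_snps,
            loci,
            i,
            strandedness=config.strandedness,
            min_base_quality=config.min_base_quality,
            include_duplicates=config.include_duplicates,
        )
        agg = _counting.aggregate_locus_counts(pile, i, config.minread)
        for name, sc in agg.items():
            counts_by_locus[name].append(sc)

    log.info("scoring %d loci", len(loci))
    scores = _scoring.score_all_loci(counts_by_locus, design, config.one_sided)
    try:
        curve = _scoring.fdr_curve(scores.values())
        cutoff = _scoring.find_score_cutoff(curve, config.fdr_target_percent)
    except ValidationError:
        curve = []
        cutoff = math.inf
    if math.isinf(cutoff):
        log.warning(
            "no score cutoff achieves the %.3g%% FDR target; "
            "no locus will be called allelically biased",
            config.fdr_target_percent,
        )

    calls = _categorize.categorize_all(
        loci,
        scores,
        counts_by_locus,
        locus_snps,
        cutoff,
        config.ratio_cutoff,
        config.one_sided,
    )
    tally = Counter(c.category for c in calls)

    meta = {
        "score_cutoff": f"{cutoff:.6g}",
        "fdr_target_percent": config.fdr_target_percent,
        "ratio_cutoff": config.ratio_cutoff,
        "minread": config.minread,
        "strandedness": config.strandedness,
    }
    paths = {
        "results": config.outdir / "results.tsv",
        "browser_bed": config.outdir / "browser.bed",
        "fdr_curve": config.outdir / "fdr_curve.tsv",
        "ratio_histogram": config.outdir / "ratio_histogram.tsv",
        "run_log": config.outdir / "run_log.json",
    }
    write_results_table(calls, paths["results"], header_meta=meta)
    write_browser_bed(calls, paths["browser_bed"])
    _scoring.write_fdr_curve(curve, paths["fdr_curve"])
    _write_ratio_histogram(calls, paths["ratio_histogram"])
    run_log = {
        "inputs": {
            "snps": {"path": str(config.snps), "sha256": _sha256(config.snps)},
            "annotation": {
                "path": str(config.annotation),
                "sha256": _sha256(config.annotation),
            },
            "bams": [
                {"path": str(b), "sha256": _sha256(b)} for b in config.bams
            ],
        },
        "config": config.to_dict(),
        "score_cutoff": cutoff if math.isfinite(cutoff) else "inf",
        "n_loci": len(loci),
        "n_snps": len(snps),
        "category_tally": dict(sorted(tally.items())),
    }
    with open(paths["run_log"], "w") as fh:
        json.dump(run_log, fh, indent=2, sort_keys=True)
        fh.write("\n")

    return RunResult(
        calls,
        scores,
        curve,
        cutoff,
        dict(tally),
        paths,
        loci,
        counts_by_locus,
        locus_snps,
    )


def _write_ratio_histogram(calls, path: Path, bins: int = 50) -> None:
    """Plot-ready histogram of allelic ratios per category group, mirroring
    the biased-vs-biallelic ratio distributions used to pick the cutoff."""
    import numpy as np

    edges = np.linspace(0.5, 1.0, bins + 1)
    groups = {
        "parental": ("MAT", "PAT"),
        "strain": ("STRAIN1", "STRAIN2"),
        "unbiased": ("BAE", "NI"),
    }
    counts = {g: np.zeros(bins, dtype=int) for g in groups}
    for c in calls:
        if c.allelic_ratio is None:
            continue
        for g, cats in groups.items():
            if c.category in cats:
                idx = min(int((c.allelic_ratio - 0.5) / 0.5 * bins), bins - 1)
                counts[g][idx] += 1
    with open(path, "w") as fh:
        fh.write("bin_start\tbin_end\tparental\tstrain\tunbiased\n")
        for i in range(bins):
            fh.write(
                f"{edges[i]:.4f}\t{edges[i + 1]:.4f}\t"
                f"{counts['parental'][i]}\t{counts['strain'][i]}\t"
                f"{counts['unbiased'][i]}\n"
            )
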