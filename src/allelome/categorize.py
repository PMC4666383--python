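"""Seven-way allelic categorization of loci.

Decision cascade per locus (first match wins):

1. no SNP in the locus                                     -> NS
2. |i_score| over the score cutoff and parental ratio > ratio cutoff -> MAT/PAT
3. |s_score| over the score cutoff and strain ratio > ratio cutoff   -> STRAIN1/2
4. enough coverage that a bias exactly at the ratio cutoff
   would have cleared the score cutoff in every sample     -> BAE
5. otherwise                                               -> NI

The allelic ratio is computed from counts pooled over the four samples and
oriented so it is always ≥ 0.5; it filters statistically significant but
biologically marginal biases out of the biased categories.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

from .counting import SampleAlleleCounts
from .formats_io import CrossDesign, Locus, ValidationError
from .scoring import LocusScores, binomial_score

__all__ = [
    "AllelomeCall",
    "CATEGORIES",
    "allelic_ratio",
    "informative_coverage_test",
    "categorize_locus",
    "categorize_all",
]

CATEGORIES = ("MAT", "PAT", "STRAIN1", "STRAIN2", "BAE", "NI", "NS")


@dataclass(frozen=True)
class AllelomeCall:
    locus: Locus
    category: str
    i_score: float | None
    s_score: float | None
    allelic_ratio: float | None
    sample_totals: tuple[int, int, int, int]
    snps_covered: int
    snps_in_locus: int


def allelic_ratio(a: int, b: int) -> float:
    """Pooled fraction of reads from the favored side: A/(A+B) with A the
    count oriented by the relevant summary-score sign (or simply the larger
    side for unbiased loci), hence always in [0.5, 1]."""
    total = a + b
    if total == 0:
        raise ValidationError("allelic ratio undefined for zero total")
    return a / total


def _oriented_ratio(scores: LocusScores) -> float | None:
    """Ratio for reporting/filtering, oriented per the nonzero summary
    score; unbiased loci use the larger side of the strain pooling."""
    if scores.i_score > 0:
        a, b = scores.mat_total, scores.pat_total
    elif scores.i_score < 0:
        a, b = scores.pat_total, scores.mat_total
    elif scores.s_score > 0:
        a, b = scores.n1_total, scores.n2_total
    elif scores.s_score < 0:
        a, b = scores.n2_total, scores.n1_total
    else:
        a = max(scores.n1_total, scores.n2_total)
        b = min(scores.n1_total, scores.n2_total)
    if a + b == 0:
        return None
    return allelic_ratio(a, b)


def informative_coverage_test(
    sample_totals: Sequence[int],
    ratio_cutoff: float,
    score_cutoff: float,
    one_sided: bool = False,
) -> bool:
    """Could a consistent bias exactly at the ratio cutoff have cleared the
    score cutoff at this locus's coverage?

    For every sample total n, the hypothetical split is
    (ceil(ratio_cutoff * n), remainder) — ceil so the cutoff ratio is at
    least expressible at that depth — and all four hypothetical scores must
    exceed the score cutoff, matching how the cutoff is applied to real
    scores. Loci failing this are non-informative rather than biallelic:
    they never had the coverage to be called biased.
    """
    if not math.isfinite(score_cutoff):
        return False
    for n in sample_totals:
        if n == 0:
            return False
        a = math.ceil(ratio_cutoff * n)
        b = n - a
        if abs(binomial_score(a, b, one_sided)) <= score_cutoff:
            return False
    return True


def categorize_locus(
    locus: Locus,
    scores: LocusScores,
    sample_counts: Sequence[SampleAlleleCounts],
    snps_in_locus: int,
    score_cutoff: float,
    ratio_cutoff: float = 0.7,
    one_sided: bool = False,
) -> AllelomeCall:
    # 0.5 means "no ratio filtering" (every oriented ratio is ≥ 0.5 and the
    # comparison is strict), mirroring sweeps that plot the uncut rate at 0.5
    if not (0.5 <= ratio_cutoff <= 1.0):
        raise ValidationError(
            f"ratio cutoff must be in [0.5, 1], got {ratio_cutoff}"
        )
    totals = tuple(sc.total for sc in sample_counts)
    covered = max(sc.snps_covered for sc in sample_counts)
    if snps_in_locus == 0:
        return AllelomeCall(
            locus, "NS", None, None, None, totals, 0, snps_in_locus
        )
    ratio = _oriented_ratio(scores)
    category = "NI"
    if (
        scores.i_score != 0
        and abs(scores.i_score) > score_cutoff
        and ratio is not None
        and ratio > ratio_cutoff
    ):
        category = "MAT" if scores.i_score > 0 else "PAT"
    elif (
        scores.s_score != 0
        and abs(scores.s_score) > score_cutoff
        and ratio is not None
        and ratio > ratio_cutoff
    ):
        category = "STRAIN1" if scores.s_score > 0 else "STRAIN2"
    elif informative_coverage_test(totals, ratio_cutoff, score_cutoff, one_sided):
        category = "BAE"
    return AllelomeCall(
        locus,
        category,
        scores.i_score,
        scores.s_score,
        ratio,
        totals,
        covered,
        snps_in_locus,
    )


def categorize_all(
    loci: Sequence[Locus],
    scores: Mapping[str, LocusScores],
    counts: Mapping[str, Sequence[SampleAlleleCounts]],
    locus_snps: Mapping[str, Sequence],
    score_cutoff: float,
    ratio_cutoff: float = 0.7,
    one_sided: bool = False,
) -> list[AllelomeCall]:
    """Categorize every locus in the annotation; the calls partition it."""
    return [
        categorize_locus(
            loc,
            scores[loc.name],
            counts[loc.name],
            len(locus_snps.get(loc.name, ())),
            score_cutoff,
            ratio_cutoff,
            one_sided,
        )
        for loc in loci
    ]
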