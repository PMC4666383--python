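"""Signed binomial allelic scores, reciprocal/mock summary scores, and the
empirical FDR cutoff.

The allelic score of a (a, b) allele-count pair is -log10 of the exact
two-sided binomial p-value under a symmetric 1:1 null, signed by the
favored side: with n = a+b and k = max(a, b),

    p = min(1, 2 * P(X >= k)),   X ~ Binomial(n, 1/2)
    score = sign(a - b) * (-log10 p)

Per locus, four per-sample scores are combined into a summary score: the
minimum-magnitude score when all four share a strict sign, otherwise 0.
Parental scores (maternal > 0) map strain counts through the cross
direction; strain scores (strain1 > 0) do not, so for any one sample
|parental| == |strain| and the two summaries are mutually exclusive. The
mock analysis negates one replicate of each cross and re-summarizes,
nulling true biases; the ratio of mock to reciprocal exceedance counts,
x100, is the empirical FDR at each score cutoff.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from scipy.stats import binom

from .counting import SampleAlleleCounts
from .formats_io import CrossDesign, ValidationError

__all__ = [
    "SampleScore",
    "LocusScores",
    "parental_counts",
    "binomial_score",
    "summarize_scores",
    "mock_summarize",
    "score_all_loci",
    "fdr_curve",
    "find_score_cutoff",
]

_LN10 = math.log(10.0)


@dataclass(frozen=True)
class SampleScore:
    locus_name: str
    sample_index: int
    parental_score: float  # maternal > 0, paternal < 0
    strain_score: float  # strain1 > 0, strain2 < 0
    mat_reads: int
    pat_reads: int


@dataclass(frozen=True)
class LocusScores:
    locus_name: str
    sample_scores: tuple[SampleScore, ...]
    i_score: float
    s_score: float
    mock_i_score: float
    mock_s_score: float
    mat_total: int  # ΣMAT over four samples
    pat_total: int
    n1_total: int  # Σ strain1 reads over four samples
    n2_total: int


def parental_counts(N1: int, N2: int, cross_direction: str) -> tuple[int, int]:
    """Map strain-allele counts to (maternal, paternal) counts.

    In the forward cross the mother is strain1; in the reverse cross she is
    strain2.
    """
    if cross_direction == "forward":
        return N1, N2
    if cross_direction == "reverse":
        return N2, N1
    raise ValidationError(f"unknown cross direction {cross_direction!r}")


def binomial_score(a: int, b: int, one_sided: bool = False) -> float:
    """Signed allelic score for allele counts (a, b).

    Exact binomial test against 1:1, computed in log space (stable for
    n up to ~1e7); the default two-sided p doubles the upper tail of the
    majority count, the one-sided variant uses the tail alone.
    """
    if a < 0 or b < 0:
        raise ValidationError(f"negative allele counts ({a}, {b})")
    if a == b:
        return 0.0
    n = a + b
    k = max(a, b)
    # log P(X >= k) = logsf(k-1); accurate in double precision for the
    # ranges tested against direct enumeration elsewhere.
    logp = float(binom.logsf(k - 1, n, 0.5))
    if logp == -math.inf:
        logp = _log_binom_tail(n, k)
    if not one_sided:
        logp += math.log(2.0)
    score = -min(logp, 0.0) / _LN10
    return score if a > b else -score


def _log_binom_tail(n: int, k: int) -> float:
    """log P(X >= k) for X ~ Binomial(n, 1/2) by term-wise log-space
    summation, for tails so extreme the survival function underflows.

    Terms decay geometrically for k well above n/2 (the only regime where
    underflow occurs), so the sum converges in a few dozen terms.
    """
    log_half_n = -n * math.log(2.0)
    lgn = math.lgamma(n + 1)

    def log_term(i: int) -> float:
        return lgn - math.lgamma(i + 1) - math.lgamma(n - i + 1) + log_half_n

    total = log_term(k)
    for i in range(k + 1, n + 1):
        t = log_term(i)
        if t < total - 40.0:  # below double-precision relevance
            break
        total = max(total, t) + math.log1p(math.exp(-abs(total - t)))
    return total


def summarize_scores(scores: Sequence[float]) -> float:
    """Four-sample consistency summary: the minimum-magnitude score when
    all four share a strict sign, else 0 (a zero score breaks consistency).
    """
    if len(scores) != 4:
        raise ValidationError(f"expected four scores, got {len(scores)}")
    if all(s > 0 for s in scores):
        return min(scores)
    if all(s < 0 for s in scores):
        return max(scores)
    return 0.0


def mock_summarize(
    scores: Sequence[float], inverted_samples: Sequence[int]
) -> float:
    """Summary score after negating the designated one-per-cross samples.

    True biases lose sign consistency under the inversion and summarize to
    0; chance-consistent biallelic patterns may gain consistency, which is
    what the empirical FDR measures.
    """
    if len(set(inverted_samples)) != 2:
        raise ValidationError("exactly two samples (one per cross) are inverted")
    flipped = [
        -s if i in inverted_samples else s for i, s in enumerate(scores)
    ]
    return summarize_scores(flipped)


def score_all_loci(
    counts: Mapping[str, Sequence[SampleAlleleCounts]],
    design: CrossDesign,
    one_sided: bool = False,
) -> dict[str, LocusScores]:
    """Compute per-sample and summary scores for every locus.

    ``counts`` maps locus name to the four per-sample aggregated counts in
    design order. The mock inversion set is replicate 2 of each cross.
    """
    inverted = design.mock_inverted_samples
    for d, r in (design.sample_roles[i] for i in inverted):
        if r != 2:
            raise ValidationError("mock inversion must negate replicate 2")
    out: dict[str, LocusScores] = {}
    for locus_name, sample_counts in counts.items():
        if len(sample_counts) != 4:
            raise ValidationError(
                f"locus {locus_name!r}: need counts for all four samples"
            )
        sscores: list[SampleScore] = []
        mat_tot = pat_tot = n1_tot = n2_tot = 0
        for i, sc in enumerate(sample_counts):
            direction = design.direction(i)
            mat, pat = parental_counts(sc.N1, sc.N2, direction)
            strain = binomial_score(sc.N1, sc.N2, one_sided)
            parental = strain if direction == "forward" else -strain
            sscores.append(
                SampleScore(locus_name, i, parental, strain, mat, pat)
            )
            mat_tot += mat
            pat_tot += pat
            n1_tot += sc.N1
            n2_tot += sc.N2
        p = [s.parental_score for s in sscores]
        s = [s.strain_score for s in sscores]
        out[locus_name] = LocusScores(
            locus_name,
            tuple(sscores),
            i_score=summarize_scores(p),
            s_score=summarize_scores(s),
            mock_i_score=mock_summarize(p, inverted),
            mock_s_score=mock_summarize(s, inverted),
            mat_total=mat_tot,
            pat_total=pat_tot,
            n1_total=n1_tot,
            n2_total=n2_tot,
        )
    return out


@dataclass(frozen=True)
class FdrRow:
    cutoff: float
    n_recip: int
    n_mock: int
    fdr_percent: float


def fdr_curve(scores: Iterable[LocusScores]) -> list[FdrRow]:
    """Empirical FDR as a function of the absolute score cutoff.

    Pools the strictly positive |i_score| and |s_score| over all loci (by
    summary-score exclusivity each locus contributes at most one value per
    analysis) for both the reciprocal and mock analyses. A locus exceeds a
    cutoff when its score is strictly greater, so
    FDR(c) = 100 * #{mock > c} / #{reciprocal > c}. Cutoff candidates are
    the distinct observed values of *both* pools: the exceedance counts are
    step functions that drop just past observed values of either pool, and
    in particular the largest mock value is the smallest cutoff with zero
    mock exceedances — omitting mock breakpoints can overshoot the target
    cutoff grossly when the pools are small. Rows where no reciprocal value
    exceeds the cutoff are undefined and dropped.
    """
    recip: list[float] = []
    mock: list[float] = []
    for ls in scores:
        for v in (abs(ls.i_score), abs(ls.s_score)):
            if v > 0:
                recip.append(v)
        for v in (abs(ls.mock_i_score), abs(ls.mock_s_score)):
            if v > 0:
                mock.append(v)
    if not recip:
        raise ValidationError("no allelic candidates; FDR undefined")
    recip.sort()
    mock.sort()
    import bisect

    rows: list[FdrRow] = []
    cutoffs = sorted(set(recip) | set(mock))
    n = len(recip)
    m = len(mock)
    for c in cutoffs:
        n_recip = n - bisect.bisect_right(recip, c)
        n_mock = m - bisect.bisect_right(mock, c)
        if n_recip == 0:
            continue
        rows.append(FdrRow(c, n_recip, n_mock, 100.0 * n_mock / n_recip))
    return rows


def find_score_cutoff(
    curve: Sequence[FdrRow], target_fdr_percent: float = 1.0
) -> float:
    """Smallest cutoff whose empirical FDR is ≤ the target (percent).

    Returns +inf when no cutoff achieves the target; callers must treat the
    sentinel as "no locus passes".
    """
    if not (0.0 < target_fdr_percent < 100.0):
        raise ValidationError(
            f"target FDR must be in (0, 100) percent, got {target_fdr_percent}"
        )
    if not curve:
        raise ValidationError("empty FDR curve")
    for row in curve:
        if row.fdr_percent <= target_fdr_percent:
            return row.cutoff
    return math.inf


def write_fdr_curve(curve: Sequence[FdrRow], path) -> None:
    """Plot-ready TSV of the reciprocal/mock exceedance counts and FDR."""
    with open(path, "w") as fh:
        fh.write("cutoff\tn_recip\tn_mock\tfdr_percent\n")
        for r in curve:
            fh.write(
                f"{r.cutoff:.6g}\t{r.n_recip}\t{r.n_mock}\t{r.fdr_percent:.4f}\n"
            )
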