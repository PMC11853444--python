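"""Cohort-level statistics: paired VAF comparisons, rank tests, survival times.

The paired bone-marrow vs plasma comparison assigns a VAF of 0 to a
mutation detected in one compartment but not the other, so the Wilcoxon
signed-rank test sees the full union of mutations.  Zero-difference pairs
are dropped (standard signed-rank convention), ties get mid-ranks, and the
exact permutation distribution is used for n <= 25 (a dynamic program over
rank sums, which handles mid-ranks); larger n uses the normal approximation
with continuity correction via scipy.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

from .errors import DataError, NotEvaluable
from .variant_io import SubjectRecord, VariantCall


@dataclass(frozen=True)
class PairedVafRecord:
    subject_id: str
    timepoint: object
    gene: str
    variant_key: str
    vaf_bm: float
    vaf_plasma: float

    def __post_init__(self):
        if self.vaf_bm <= 0 and self.vaf_plasma <= 0:
            raise DataError("at least one side of a paired record must be positive")

    @property
    def key(self):
        return (self.subject_id, self.timepoint, self.gene, self.variant_key)


def build_paired_vafs(
    bm_calls: Sequence[VariantCall], plasma_calls: Sequence[VariantCall]
) -> list:
    """Pair BM and plasma VAFs per mutation; the missing side gets 0."""

    def _index(calls, compartment):
        idx = {}
        for c in calls:
            if c.compartment != compartment:
                raise DataError(f"expected only {compartment} calls, got {c.compartment}")
            k = (c.subject_id, c.day, c.gene, c.variant_key)
            if k in idx:
                raise DataError(f"duplicate key within {compartment}: {k}")
            idx[k] = c.vaf
        return idx

    bm = _index(bm_calls, "BM")
    plasma = _index(plasma_calls, "plasma")
    records = []
    for k in sorted(set(bm) | set(plasma), key=str):
        subject_id, day, gene, vkey = k
        records.append(
            PairedVafRecord(
                subject_id=subject_id,
                timepoint=day,
                gene=gene,
                variant_key=vkey,
                vaf_bm=bm.get(k, 0.0),
                vaf_plasma=plasma.get(k, 0.0),
            )
        )
    return records


# ---------------------------------------------------------------------------
# Wilcoxon signed-rank

@dataclass(frozen=True)
class WilcoxonResult:
    statistic: float  # min of the positive/negative rank sums
    p_value: float
    n_used: int  # pairs remaining after zero-difference drop
    method: str  # "exact" or "normal"


def _exact_signed_rank_p(ranks: np.ndarray, w_small: float) -> float:
    """Two-sided exact p under the 2^n sign-flip null, via subset-sum DP.

    Ranks are doubled to integers so mid-ranks (x.5) stay exact.  The
    distribution of W+ is symmetric about half the total rank sum; the
    two-sided p sums both tails at the observed min rank sum.
    """
    doubled = np.rint(2 * ranks).astype(int)
    total = int(doubled.sum())
    counts = np.zeros(total + 1, dtype=float)
    counts[0] = 1.0
    for r in doubled:
        counts[r:] += counts[:-r].copy() if r > 0 else counts.copy()
    counts /= counts.sum()
    w2 = int(round(2 * w_small))
    lower = counts[: w2 + 1].sum()
    upper = counts[total - w2 :].sum()
    return float(min(1.0, lower + upper))


def wilcoxon_signed_rank(x: Sequence[float], y: Sequence[float], exact_max_n: int = 25) -> WilcoxonResult:
    """Wilcoxon matched-pair signed-rank test on paired samples x, y."""
    d = np.asarray(x, float) - np.asarray(y, float)
    d = d[d != 0]
    n = len(d)
    if n == 0:
        raise NotEvaluable("all paired differences are zero")
    ranks = stats.rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    w_minus = float(ranks[d < 0].sum())
    w = min(w_plus, w_minus)
    if n <= exact_max_n:
        p = _exact_signed_rank_p(ranks, w)
        method = "exact"
    else:
        res = stats.wilcoxon(d, zero_method="wilcox", correction=True, method="approx")
        p = float(res.pvalue)
        method = "normal"
    return WilcoxonResult(statistic=w, p_value=p, n_used=n, method=method)


def wilcoxon_matched_pairs(pairs: Sequence[PairedVafRecord], exact_max_n: int = 25) -> WilcoxonResult:
    """Signed-rank test comparing BM vs plasma VAFs over paired records."""
    if not pairs:
        raise NotEvaluable("no paired records")
    return wilcoxon_signed_rank(
        [p.vaf_bm for p in pairs], [p.vaf_plasma for p in pairs], exact_max_n=exact_max_n
    )


# ---------------------------------------------------------------------------
# Kruskal-Wallis and summaries

@dataclass(frozen=True)
class KruskalResult:
    statistic: float
    p_value: float
    df: int
    n: int


def kruskal_wallis(groups: Sequence[Sequence[float]]) -> KruskalResult:
    """Tie-corrected Kruskal-Wallis H with chi-squared p on k-1 df."""
    if len(groups) < 2 or any(len(g) == 0 for g in groups):
        raise NotEvaluable("need at least two non-empty groups")
    n = sum(len(g) for g in groups)
    df = len(groups) - 1
    pooled = np.concatenate([np.asarray(g, float) for g in groups])
    if np.all(pooled == pooled[0]):
        return KruskalResult(statistic=0.0, p_value=1.0, df=df, n=n)
    h, p = stats.kruskal(*groups)
    return KruskalResult(statistic=float(h), p_value=float(p), df=df, n=n)


def median_range(values: Sequence[float]) -> tuple:
    """(median, min, max); even counts take the mean of the central pair."""
    vals = [float(v) for v in values]
    if not vals:
        raise NotEvaluable("median of an empty list")
    return (float(np.median(vals)), min(vals), max(vals))


# ---------------------------------------------------------------------------
# survival bookkeeping

@dataclass(frozen=True)
class SurvivalTimes:
    subject_id: str
    os_days: int
    rfs_days: int
    event_os: bool
    event_rfs: bool


def survival_times(subject: SubjectRecord) -> SurvivalTimes:
    """Overall and relapse-free survival times from day 0.

    OS runs to death (event) or censoring at last follow-up; RFS runs to
    the earlier of relapse or death (event) or the same censoring.
    """
    if (
        subject.relapse_day is not None
        and subject.death_day is not None
        and subject.relapse_day > subject.death_day
    ):
        raise DataError(
            f"subject {subject.subject_id}: relapse_day {subject.relapse_day} "
            f"after death_day {subject.death_day}"
        )
    event_os = subject.death_day is not None
    os_days = subject.death_day if event_os else subject.last_followup_day
    event_rfs = subject.relapse_day is not None or event_os
    if subject.relapse_day is not None:
        rfs_days = subject.relapse_day
    elif event_os:
        rfs_days = subject.death_day
    else:
        rfs_days = subject.last_followup_day
    return SurvivalTimes(
        subject_id=subject.subject_id,
        os_days=int(os_days),
        rfs_days=int(rfs_days),
        event_os=event_os,
        event_rfs=event_rfs,
    )
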