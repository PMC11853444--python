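"""Donor chimerism estimation from cfDNA SNP allele fractions.

Post-transplant plasma cfDNA is a mixture of residual-host and donor-derived
DNA.  At a SNP where recipient and donor genotypes differ (an *informative*
SNP), the observed alt-allele fraction v is a linear mixture

    v = h * g_R + (1 - h) * g_D,

where h is the host fraction and g_R, g_D are the genotype alt-allele
fractions (0, 0.5 or 1).  Inverting per SNP and taking the median of the
per-SNP host-fraction estimates gives a robust mixture estimate; donor
chimerism is 100 * (1 - median h).  For hom<->hom SNPs this reduces to the
median VAF difference from the donor genotype; hom<->het SNPs are rescaled
by the factor 2 the halved genotype distance implies.
"""

from __future__ import annotations

from dataclasses import dataclass
from statistics import median
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

from .errors import DataError, NotEvaluable

GENOTYPE_FRACTIONS = (0.0, 0.5, 1.0)
METHODS = ("cfDNA_NGS", "STR_CD3", "STR_CD15", "CD34")


@dataclass(frozen=True)
class SnpObservation:
    """One chimerism-informative SNP measurement in one plasma sample."""

    snp_id: str
    g_recipient: float
    g_donor: float
    vaf: float  # observed alt fraction, in [0, 1]
    depth: int
    subject_id: str | None = None
    day: object = None

    def __post_init__(self):
        if self.g_recipient not in GENOTYPE_FRACTIONS or self.g_donor not in GENOTYPE_FRACTIONS:
            raise DataError(
                f"genotype fractions must be in {GENOTYPE_FRACTIONS}: "
                f"got g_R={self.g_recipient}, g_D={self.g_donor}"
            )
        if not 0.0 <= self.vaf <= 1.0:
            raise DataError(f"observed SNP VAF {self.vaf} outside [0, 1]")
        if self.depth < 0:
            raise DataError(f"negative depth {self.depth}")

    @property
    def informative(self) -> bool:
        return abs(self.g_recipient - self.g_donor) >= 0.5

    @property
    def pair_class(self) -> str | None:
        """Genotype-pair class: hom<->hom, hom<->het, or None if uninformative."""
        if not self.informative:
            return None
        if abs(self.g_recipient - self.g_donor) == 1.0:
            return "hom_hom"
        return "hom_het"

    @property
    def host_fraction(self) -> float:
        """Per-SNP host-fraction estimate, clamped to [0, 1]."""
        if not self.informative:
            raise NotEvaluable(f"SNP {self.snp_id} is uninformative (g_R == g_D)")
        h = (self.vaf - self.g_donor) / (self.g_recipient - self.g_donor)
        return min(1.0, max(0.0, h))


@dataclass(frozen=True)
class ChimerismEstimate:
    """Donor chimerism (percent) for one subject/day by one method."""

    subject_id: str | None
    day: object
    method: str
    donor_percent: float
    n_informative: int | None = None

    def __post_init__(self):
        if not 0.0 <= self.donor_percent <= 100.0:
            raise DataError(f"donor_percent {self.donor_percent} outside [0, 100]")
        if self.method not in METHODS:
            raise DataError(f"method must be one of {METHODS}, got {self.method!r}")


def select_informative(observations: Sequence[SnpObservation]) -> list:
    """Keep SNPs where recipient and donor genotypes differ."""
    return [o for o in observations if o.informative]


def _weighted_median(values: Sequence[float], weights: Sequence[float]) -> float:
    order = np.argsort(values)
    v = np.asarray(values, float)[order]
    w = np.asarray(weights, float)[order]
    cum = np.cumsum(w)
    total = cum[-1]
    idx = int(np.searchsorted(cum, total / 2.0))
    if cum[idx] == total / 2.0 and idx + 1 < len(v):
        return float((v[idx] + v[idx + 1]) / 2.0)
    return float(v[idx])


def estimate_donor_chimerism(
    observations: Sequence[SnpObservation],
    min_informative: int = 3,
    precision: int = 1,
    depth_weighted: bool = False,
    subject_id: str | None = None,
    day=None,
    method: str = "cfDNA_NGS",
) -> ChimerismEstimate:
    """Estimate donor chimerism from the informative SNPs of one sample.

    Per informative SNP, the host fraction is (v - g_D)/(g_R - g_D) clamped
    to [0, 1]; the sample estimate is the median over SNPs (even counts take
    the mean of the central pair) and donor % = 100 * (1 - median h),
    rounded to ``precision`` decimals.  Raises :class:`NotEvaluable` when
    fewer than ``min_informative`` informative SNPs are present or no SNP
    has any reads.
    """
    informative = select_informative(observations)
    if len(informative) < min_informative:
        raise NotEvaluable(
            f"only {len(informative)} informative SNPs; {min_informative} required"
        )
    if all(o.depth == 0 for o in informative):
        raise NotEvaluable("zero sequencing depth on every informative SNP")

    hs = [o.host_fraction for o in informative]
    if depth_weighted:
        h = _weighted_median(hs, [max(o.depth, 0) for o in informative])
    else:
        h = float(median(hs))
    donor = round(100.0 * (1.0 - h), precision)
    return ChimerismEstimate(
        subject_id=subject_id,
        day=day,
        method=method,
        donor_percent=min(100.0, max(0.0, donor)),
        n_informative=len(informative),
    )


def _series_values(series) -> list:
    """Accept floats or ChimerismEstimates; estimates are ordered by day."""
    vals = list(series)
    if vals and isinstance(vals[0], ChimerismEstimate):
        from .variant_io import day_sort_key

        vals = sorted(vals, key=lambda e: day_sort_key(e.day))
        return [e.donor_percent for e in vals]
    return [float(v) for v in vals]


def chimerism_trend(series, delta: float = 2.0) -> str:
    """Classify a time-ordered chimerism series as falling, rising or stable.

    Falling requires every successive difference <= -delta (percentage
    points); rising requires every difference >= +delta.
    """
    values = _series_values(series)
    if len(values) < 2:
        raise NotEvaluable("trend needs at least two time-ordered estimates")
    diffs = np.diff(values)
    if np.all(diffs <= -delta):
        return "falling"
    if np.all(diffs >= delta):
        return "rising"
    return "stable"


def compare_methods(a: Iterable[ChimerismEstimate], b: Iterable[ChimerismEstimate], min_pairs: int = 3) -> dict:
    """Pearson correlation between two chimerism methods on matched samples.

    Estimates are matched on (subject, day).  Returns per-day and pooled
    correlation reports ``{"r", "p", "n"}``; days with fewer than
    ``min_pairs`` matched pairs (or a constant series) are skipped.
    """
    index_b = {(e.subject_id, e.day): e.donor_percent for e in b}
    pairs = [
        (e.day, e.donor_percent, index_b[(e.subject_id, e.day)])
        for e in a
        if (e.subject_id, e.day) in index_b
    ]
    if len(pairs) < min_pairs:
        raise NotEvaluable(f"only {len(pairs)} matched pairs; {min_pairs} required")

    def _report(xs, ys):
        if np.std(xs) == 0 or np.std(ys) == 0:
            return None
        r, p = stats.pearsonr(xs, ys)
        return {"r": float(r), "p": float(p), "n": len(xs)}

    by_day: dict = {}
    for day, x, y in pairs:
        by_day.setdefault(day, ([], []))
        by_day[day][0].append(x)
        by_day[day][1].append(y)

    per_day = {}
    for day, (xs, ys) in sorted(by_day.items(), key=lambda kv: str(kv[0])):
        if len(xs) >= min_pairs:
            rep = _report(xs, ys)
            if rep is not None:
                per_day[day] = rep
    overall = _report([p[1] for p in pairs], [p[2] for p in pairs])
    return {"by_day": per_day, "overall": overall}
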