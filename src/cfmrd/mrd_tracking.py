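"""Longitudinal MRD aggregation: geometric-mean VAF, trajectories, relapse flags.

Each sample's MRD burden is summarised as the mutation count together with
the geometric mean (GM) of the detected VAFs.  Undetected mutations are
excluded rather than zero-filled: a zero would annihilate the GM and
contradict how clinical reports print these cells.  A sample with zero
detected mutations has no GM and is reported "NE" (not evaluable); a sample
that was never drawn is "ND" (not done) and is skipped, never treated as
negative.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .chimerism import ChimerismEstimate, chimerism_trend
from .errors import DataError, NotEvaluable
from .variant_io import PRE, SubjectRecord, VariantCall, day_sort_key


def geometric_mean_vaf(vafs: Iterable[float], ndigits: int | None = 2) -> float | None:
    """Geometric mean of detected VAFs on the percent scale.

    exp(mean(ln v)); an empty list returns None ("NE"); any value <= 0 is an
    error because zero VAF means *not detected* and must be excluded
    upstream.  ``ndigits=None`` skips the report rounding.
    """
    values = [float(v) for v in vafs]
    if not values:
        return None
    if any(v <= 0 for v in values):
        raise ValueError("geometric mean requires strictly positive VAFs")
    gm = math.exp(sum(math.log(v) for v in values) / len(values))
    return gm if ndigits is None else round(gm, ndigits)


@dataclass(frozen=True)
class MrdSample:
    """Per subject/day/compartment MRD aggregate."""

    subject_id: str
    day: object
    compartment: str
    n_mutations: int | None
    gm_vaf: float | None
    not_done: bool = False
    gene_level: bool = True  # False for aggregate-only cells without per-gene identities

    def __post_init__(self):
        if self.not_done:
            if self.n_mutations is not None or self.gm_vaf is not None:
                raise DataError("an ND sample carries no count or GM")
        else:
            if self.n_mutations is None or self.n_mutations < 0:
                raise DataError("evaluable sample needs a non-negative mutation count")
            if (self.gm_vaf is None) != (self.n_mutations == 0):
                raise DataError("gm_vaf must be absent exactly when n_mutations == 0")
            if self.gm_vaf is not None and self.gm_vaf <= 0:
                raise DataError("gm_vaf must be positive when present")

    @property
    def status(self) -> str:
        if self.not_done:
            return "ND"
        return "NE" if self.n_mutations == 0 else "ok"


@dataclass
class MutationTrajectory:
    """All MRD samples and per-variant VAF series for one subject."""

    subject_id: str
    samples: list = field(default_factory=list)
    # (gene, variant_key) -> {(compartment, day): vaf}
    variant_series: dict = field(default_factory=dict)

    def __post_init__(self):
        self.samples.sort(key=lambda s: (day_sort_key(s.day), s.compartment))

    def sample(self, day, compartment) -> MrdSample | None:
        for s in self.samples:
            if s.day == day and s.compartment == compartment:
                return s
        return None

    def plasma_samples(self, post_only: bool = False, evaluable_only: bool = False) -> list:
        out = [s for s in self.samples if s.compartment == "plasma"]
        if post_only:
            out = [s for s in out if s.day != PRE]
        if evaluable_only:
            out = [s for s in out if not s.not_done]
        return out

    def genes_at(self, day, compartment) -> set:
        return {
            gene
            for (gene, vkey), series in self.variant_series.items()
            if (compartment, day) in series
        }

    def last_evaluable_plasma(self, gene_level: bool = True) -> MrdSample | None:
        candidates = [
            s
            for s in self.plasma_samples(post_only=True, evaluable_only=True)
            if (s.gene_level or not gene_level)
        ]
        return candidates[-1] if candidates else None


def build_trajectory(
    calls: Sequence[VariantCall],
    subject: SubjectRecord,
    timepoints: Iterable | None = None,
) -> MutationTrajectory:
    """Assemble a subject's trajectory from somatic-filtered calls.

    ``timepoints`` (or ``subject.timepoints_available``) lists the
    (compartment, day) pairs that were actually sampled; pairs without any
    call become zero-mutation ("NE") samples, and sampled pairs absent from
    the list are marked ND.  With neither given, the sampled set is the set
    of pairs observed in the calls.
    """
    mine = [c for c in calls if c.subject_id == subject.subject_id]
    observed = {(c.compartment, c.day) for c in mine}
    if timepoints is not None:
        available = set(timepoints)
    elif subject.timepoints_available is not None:
        available = set(subject.timepoints_available)
    else:
        available = observed
    stray = observed - available
    if stray:
        raise DataError(
            f"subject {subject.subject_id}: calls at unsampled timepoints {sorted(map(str, stray))}"
        )

    samples = []
    for comp, day in available:
        # a zero VAF means "not detected" and does not count as a detection
        vafs = [c.vaf for c in mine if c.compartment == comp and c.day == day and c.vaf > 0]
        n = len(vafs)
        samples.append(
            MrdSample(
                subject_id=subject.subject_id,
                day=day,
                compartment=comp,
                n_mutations=n,
                gm_vaf=geometric_mean_vaf(vafs),
            )
        )

    series: dict = {}
    for c in mine:
        series.setdefault((c.gene, c.variant_key), {})[(c.compartment, c.day)] = c.vaf
    return MutationTrajectory(subject_id=subject.subject_id, samples=samples, variant_series=series)


# ---------------------------------------------------------------------------
# clearance

CLEARANCE_STATUSES = ("never_present", "cleared_pre", "cleared_post", "persistent")


@dataclass
class ClearanceReport:
    subject_id: str
    per_gene: dict
    subset_status: str
    first_clearance_day: object = None
    last_evaluable_day: object = None


def detect_clearance(
    trajectory: MutationTrajectory,
    gene_subset="all",
    adverse_at_diagnosis: bool | None = None,
) -> ClearanceReport:
    """Classify clearance/persistence of plasma mutations for one subject.

    Judged on plasma cfDNA: *persistent* means detected at the last
    evaluable gene-resolved plasma timepoint (ND timepoints are skipped,
    they never count as clearance); *cleared_post* means detected in
    pre-transplant plasma but not at that last timepoint; *cleared_pre*
    (subset level) means never detected in plasma although present at
    diagnosis per subject metadata; *never_present* otherwise.
    """
    post = [
        s
        for s in trajectory.plasma_samples(post_only=True, evaluable_only=True)
        if s.gene_level
    ]
    if not post:
        raise NotEvaluable(
            f"subject {trajectory.subject_id}: no evaluable post-transplant plasma sample"
        )
    last_day = post[-1].day
    post_days = [s.day for s in post]

    plasma_genes = {
        gene
        for (gene, vkey), series in trajectory.variant_series.items()
        if any(comp == "plasma" for comp, _ in series)
    }
    observed = plasma_genes if gene_subset == "all" else set(gene_subset)

    def _gene_days(gene):
        days = set()
        for (g, vkey), series in trajectory.variant_series.items():
            if g == gene:
                days |= {d for comp, d in series if comp == "plasma"}
        return days

    per_gene = {}
    for gene in sorted(observed):
        days = _gene_days(gene)
        present_last = last_day in days
        present_pre = PRE in days
        if present_last:
            status = "persistent"
        elif present_pre or (days & set(post_days)):
            status = "cleared_post"
        else:
            status = "never_present"
        per_gene[gene] = status

    # subset viewed as a composite marker
    if gene_subset == "all":
        subset_days = set().union(*(_gene_days(g) for g in observed)) if observed else set()
    else:
        subset_days = set().union(*(_gene_days(g) for g in gene_subset)) if gene_subset else set()
    if last_day in subset_days:
        subset_status = "persistent"
        first_clearance = None
    elif subset_days:
        subset_status = "cleared_post"
        first_clearance = next((d for d in post_days if d not in subset_days), None)
    elif adverse_at_diagnosis:
        subset_status = "cleared_pre"
        first_clearance = PRE
    else:
        subset_status = "never_present"
        first_clearance = None

    return ClearanceReport(
        subject_id=trajectory.subject_id,
        per_gene=per_gene,
        subset_status=subset_status,
        first_clearance_day=first_clearance,
        last_evaluable_day=last_day,
    )


# ---------------------------------------------------------------------------
# relapse flagging

@dataclass
class RelapseFlag:
    subject_id: str
    flagged: bool
    evidence: list = field(default_factory=list)


def flag_impending_relapse(
    trajectory: MutationTrajectory,
    chimerism: Sequence[ChimerismEstimate],
    fold_rise: float = 3.0,
    count_rise: int = 3,
    trend_delta: float = 2.0,
) -> RelapseFlag:
    """Flag a subject whose MRD rises while cfDNA donor chimerism falls.

    Between consecutive evaluable post-transplant plasma samples, an MRD
    trigger is a GM rise of at least ``fold_rise`` or a mutation-count rise
    of at least ``count_rise``; the flag fires only when cfDNA chimerism is
    also falling (every successive drop >= ``trend_delta`` points) across
    the same span.
    """
    post = trajectory.plasma_samples(post_only=True, evaluable_only=True)
    if len(post) < 2:
        raise NotEvaluable("relapse flag needs at least two post-transplant plasma samples")
    chi = sorted(
        (e for e in chimerism if e.method == "cfDNA_NGS"), key=lambda e: day_sort_key(e.day)
    )

    evidence = []
    for s1, s2 in zip(post, post[1:]):
        gm_fold = None
        if s1.gm_vaf and s2.gm_vaf:
            gm_fold = s2.gm_vaf / s1.gm_vaf
        dn = None
        if s1.n_mutations is not None and s2.n_mutations is not None:
            dn = s2.n_mutations - s1.n_mutations
        mrd_trigger = (gm_fold is not None and gm_fold >= fold_rise) or (
            dn is not None and dn >= count_rise
        )
        if not mrd_trigger:
            continue
        span = [e for e in chi if day_sort_key(s1.day) <= day_sort_key(e.day) <= day_sort_key(s2.day)]
        falling = False
        if len(span) >= 2:
            try:
                falling = chimerism_trend(span, delta=trend_delta) == "falling"
            except NotEvaluable:
                falling = False
        if falling:
            evidence.append(
                {
                    "from_day": s1.day,
                    "to_day": s2.day,
                    "gm_fold": gm_fold,
                    "count_rise": dn,
                    "chimerism": [e.donor_percent for e in span],
                }
            )
    return RelapseFlag(trajectory.subject_id, flagged=bool(evidence), evidence=evidence)


def trajectory_report_rows(trajectory: MutationTrajectory) -> list:
    """Rows mirroring the printed "count/GM" cells with ND/NE markers."""
    rows = []
    for s in trajectory.samples:
        if s.not_done:
            cell = "ND"
        elif s.n_mutations == 0:
            cell = "0/NE"
        else:
            cell = f"{s.n_mutations}/{s.gm_vaf:.2f}"
        rows.append(
            {
                "subject_id": s.subject_id,
                "day": s.day,
                "compartment": s.compartment,
                "cell": cell,
                "status": s.status,
                "gene_level": s.gene_level,
            }
        )
    return rows
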