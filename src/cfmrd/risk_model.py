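"""Adverse-risk mutation classification and relapse contingency summaries.

The adverse-risk gene list follows the ELN / Pethema Registry / NCRI
classifications for myeloid malignancies.  FLT3 internal tandem
duplications are a distinct marker ("FLT3-ITD") and do not make FLT3 point
mutations adverse.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from typing import Iterable, Sequence

import yaml

from .errors import DataError, NotEvaluable
from .mrd_tracking import MutationTrajectory, detect_clearance
from .variant_io import PRE, SubjectRecord

GROUPS = (
    "no_adverse_ever",
    "mrd_negative_pre",
    "cleared_pre",
    "cleared_post",
    "persistent_adverse",
    "not_evaluable",
)

CLEARED_OR_NEGATIVE = ("mrd_negative_pre", "cleared_pre", "cleared_post")


@dataclass(frozen=True)
class RiskGeneSet:
    adverse: frozenset
    source_label: str = "ELN / Pethema / NCRI adverse-risk gene list"

    def __post_init__(self):
        if not self.adverse:
            raise DataError("adverse gene set must be non-empty")
        if any(g != g.upper() for g in self.adverse):
            raise DataError("adverse gene symbols must be uppercase")


def load_risk_gene_set(path=None) -> RiskGeneSet:
    """Load the adverse-risk gene set from YAML (default: packaged list)."""
    if path is None:
        text = resources.files("cfmrd.data").joinpath("risk_genes.yaml").read_text()
    else:
        with open(path) as fh:
            text = fh.read()
    doc = yaml.safe_load(text)
    return RiskGeneSet(
        adverse=frozenset(str(g).upper() for g in doc["adverse"]),
        source_label=str(doc.get("source_label", "custom")),
    )


def classify_gene(gene: str, risk_set: RiskGeneSet | None = None) -> str:
    """"adverse" or "other"; case-insensitive, ITD-aware exact membership."""
    rs = risk_set or load_risk_gene_set()
    return "adverse" if gene.strip().upper() in rs.adverse else "other"


@dataclass(frozen=True)
class SubjectRiskClassification:
    subject_id: str
    had_adverse_pre: bool
    group: str
    relapsed_12mo: bool
    excluded_reason: str | None = None

    def __post_init__(self):
        if self.group not in GROUPS:
            raise DataError(f"unknown group {self.group!r}")
        if (self.group == "not_evaluable") != (self.excluded_reason is not None):
            raise DataError("not_evaluable requires an excluded_reason (and only then)")


def classify_subject(
    trajectory: MutationTrajectory,
    subject: SubjectRecord,
    risk_set: RiskGeneSet | None = None,
) -> SubjectRiskClassification:
    """Assign a subject to a clearance/persistence group for the adverse set.

    Persistence is judged on plasma cfDNA at the last evaluable
    gene-resolved post-transplant timepoint.  A subject without any such
    sample (for instance death before the day-84 draw, with ND sampling) is
    not_evaluable.  Diagnosis-era adverse status comes from subject
    metadata because diagnosis-time panels are not part of the dataset.
    """
    rs = risk_set or load_risk_gene_set()
    relapsed = subject.relapse_day is not None and subject.relapse_day <= 365

    pre_genes = set()
    for (gene, vkey), series in trajectory.variant_series.items():
        if any(day == PRE for comp, day in series):
            pre_genes.add(gene.upper())
    had_adverse_pre = subject.adverse_at_diagnosis or bool(pre_genes & rs.adverse)

    if not had_adverse_pre:
        return SubjectRiskClassification(
            subject.subject_id, had_adverse_pre=False, group="no_adverse_ever", relapsed_12mo=relapsed
        )

    try:
        report = detect_clearance(
            trajectory,
            gene_subset={g for g in rs.adverse},
            adverse_at_diagnosis=subject.adverse_at_diagnosis,
        )
    except NotEvaluable as exc:
        return SubjectRiskClassification(
            subject.subject_id,
            had_adverse_pre=True,
            group="not_evaluable",
            relapsed_12mo=relapsed,
            excluded_reason=str(exc),
        )

    if report.subset_status == "persistent":
        group = "persistent_adverse"
    elif report.subset_status == "cleared_post":
        group = "cleared_post"
    else:
        # adverse never seen in plasma: MRD-negative if the pre-transplant
        # staging samples were entirely mutation-free, otherwise cleared_pre
        pre_samples = [s for s in trajectory.samples if s.day == PRE and not s.not_done]
        mrd_negative = bool(pre_samples) and all(s.n_mutations == 0 for s in pre_samples)
        group = "mrd_negative_pre" if mrd_negative else "cleared_pre"

    return SubjectRiskClassification(
        subject.subject_id, had_adverse_pre=True, group=group, relapsed_12mo=relapsed
    )


@dataclass
class RelapseSummary:
    by_group: dict  # group -> {"n", "relapses", "fraction"}
    pooled: dict  # 2x2: persistent vs cleared-or-negative by relapse yes/no
    n_evaluable: int


def summarize_relapse_by_group(classifications: Sequence[SubjectRiskClassification]) -> RelapseSummary:
    """Per-group relapse counts plus the pooled persistent-vs-cleared 2x2 table."""
    if not any(c.group != "not_evaluable" for c in classifications):
        raise NotEvaluable("no evaluable classifications")
    by_group = {}
    for g in GROUPS:
        members = [c for c in classifications if c.group == g]
        relapses = sum(c.relapsed_12mo for c in members)
        by_group[g] = {
            "n": len(members),
            "relapses": relapses,
            "fraction": (relapses / len(members)) if members else None,
        }
    persistent = [c for c in classifications if c.group == "persistent_adverse"]
    cleared = [c for c in classifications if c.group in CLEARED_OR_NEGATIVE]
    pooled = {
        "persistent_adverse": {
            "relapse": sum(c.relapsed_12mo for c in persistent),
            "no_relapse": sum(not c.relapsed_12mo for c in persistent),
        },
        "cleared_or_negative": {
            "relapse": sum(c.relapsed_12mo for c in cleared),
            "no_relapse": sum(not c.relapsed_12mo for c in cleared),
        },
    }
    n_evaluable = sum(c.group != "not_evaluable" for c in classifications)
    return RelapseSummary(by_group=by_group, pooled=pooled, n_evaluable=n_evaluable)
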