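"""Reading, validation and origin annotation of somatic-variant tables.

Variant allele fractions (VAFs) are carried on the percent scale (0-100)
throughout, matching how clinical NGS reports print them.  The "pre"
sentinel marks pre-transplant samples (baseline plasma and the staging bone
marrow); day 0 is the completion of the stem-cell infusion, so every
numbered day is post-transplant.
"""

from __future__ import annotations

import io
import logging
import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .errors import DataError, SchemaError

log = logging.getLogger(__name__)

PRE = "pre"
COMPARTMENTS = ("BM", "plasma")
ORIGINS = ("somatic", "host_germline", "donor_germline", "donor_transmitted")

#: default VAF bands (percent) that mark a pre-transplant call as presumed
#: host germline: heterozygous around 50%, homozygous above 90%.
DEFAULT_GERMLINE_BANDS = ((40.0, 60.0), (90.0, 100.0))

_SLASH_DECIMAL = re.compile(r"^(\d+)/(\d+)$")


def normalize_vaf_token(token) -> float:
    """Convert a printed VAF token to a float.

    A "/" between digits is read as a decimal point: clinical tables
    occasionally carry a typographic slash in the decimal position
    (e.g. "0/73" for 0.73).  The substitution is logged.
    """
    if isinstance(token, (int, float)):
        return float(token)
    s = str(token).strip()
    m = _SLASH_DECIMAL.match(s)
    if m:
        fixed = f"{m.group(1)}.{m.group(2)}"
        log.warning("VAF token %r normalized to %s (slash read as decimal point)", s, fixed)
        s = fixed
    return float(s)


def _parse_day(token):
    if isinstance(token, int):
        return token
    s = str(token).strip()
    if s.lower() == PRE:
        return PRE
    return int(s)


def day_sort_key(day) -> int:
    """Sort key placing the pre-transplant sentinel before all numbered days."""
    return -1 if day == PRE else int(day)


@dataclass(frozen=True)
class VariantCall:
    """One somatic/germline variant observation in one sample."""

    subject_id: str
    day: object  # int >= 0 or the "pre" sentinel
    compartment: str
    gene: str
    variant_key: str
    vaf: float
    origin: str = "somatic"

    def __post_init__(self):
        if self.day != PRE and (not isinstance(self.day, int) or self.day < 0):
            raise DataError(f"day must be 'pre' or a non-negative integer, got {self.day!r}")
        if self.compartment not in COMPARTMENTS:
            raise DataError(f"compartment must be one of {COMPARTMENTS}, got {self.compartment!r}")
        if not 0.0 <= self.vaf <= 100.0:
            raise DataError(f"VAF {self.vaf} outside [0, 100] for {self.gene}")
        if self.origin not in ORIGINS:
            raise DataError(f"origin must be one of {ORIGINS}, got {self.origin!r}")

    @property
    def key(self):
        return (self.subject_id, self.day, self.compartment, self.gene, self.variant_key)


@dataclass(frozen=True)
class SubjectRecord:
    """Clinical course of one transplanted subject."""

    subject_id: str
    diagnosis: str = ""
    relapse_day: int | None = None
    death_day: int | None = None
    last_followup_day: int = 365
    consolidation_start_day: int | None = None
    adverse_at_diagnosis: bool = True
    timepoints_available: frozenset | None = None  # {(compartment, day), ...}
    status_note: str = ""

    def __post_init__(self):
        if self.death_day is not None and self.death_day > self.last_followup_day:
            raise DataError(
                f"subject {self.subject_id}: death_day {self.death_day} after "
                f"last_followup_day {self.last_followup_day}"
            )

    @property
    def relapse(self) -> bool:
        return self.relapse_day is not None


@dataclass
class CohortDataset:
    """In-memory container tying subjects, variants and SNP observations together."""

    subjects: list = field(default_factory=list)
    variants: list = field(default_factory=list)
    snp_observations: list = field(default_factory=list)
    cellular_chimerism: list = field(default_factory=list)
    mrd_table: pd.DataFrame | None = None  # aggregate count/GM cells, when available

    def subject(self, subject_id: str) -> SubjectRecord:
        for s in self.subjects:
            if s.subject_id == subject_id:
                return s
        raise KeyError(subject_id)

    def subject_ids(self) -> list:
        return [s.subject_id for s in self.subjects]

    def validate(self) -> None:
        ids = set(self.subject_ids())
        if len(ids) != len(self.subjects):
            raise DataError("duplicate subject_id in subject list")
        seen = set()
        for v in self.variants:
            if v.subject_id not in ids:
                raise DataError(f"variant references unknown subject {v.subject_id!r}")
            if v.key in seen:
                raise DataError(f"duplicate variant key {v.key}")
            seen.add(v.key)


# ---------------------------------------------------------------------------
# tabular IO

_REQUIRED_VARIANT_COLUMNS = ("subject_id", "day", "compartment", "gene", "vaf")


def parse_variant_table(source) -> list:
    """Read a variant TSV (or DataFrame) into validated :class:`VariantCall` rows.

    Required columns: subject_id, day, compartment, gene, vaf.  Optional:
    variant_key (defaults to the gene symbol) and origin (defaults to
    somatic).  Rows failing validation are reported with their row numbers.
    """
    if isinstance(source, pd.DataFrame):
        df = source.copy()
    else:
        df = pd.read_csv(source, sep="\t", dtype=str)
    missing = [c for c in _REQUIRED_VARIANT_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"variant table missing required column(s): {', '.join(missing)}")

    calls, problems = [], []
    for idx, row in df.iterrows():
        rowno = idx + 2  # 1-based, counting the header line
        try:
            gene = str(row["gene"]).strip()
            vkey = row.get("variant_key")
            vkey = gene if vkey is None or (isinstance(vkey, float) and pd.isna(vkey)) or str(vkey).strip() == "" else str(vkey).strip()
            origin = row.get("origin")
            origin = "somatic" if origin is None or (isinstance(origin, float) and pd.isna(origin)) or str(origin).strip() == "" else str(origin).strip()
            calls.append(
                VariantCall(
                    subject_id=str(row["subject_id"]).strip(),
                    day=_parse_day(row["day"]),
                    compartment=str(row["compartment"]).strip(),
                    gene=gene,
                    variant_key=vkey,
                    vaf=normalize_vaf_token(row["vaf"]),
                    origin=origin,
                )
            )
        except (DataError, ValueError) as exc:
            problems.append(f"row {rowno}: {exc}")
    if problems:
        raise DataError("invalid variant rows:\n" + "\n".join(problems))

    seen = set()
    for c in calls:
        if c.key in seen:
            raise DataError(f"duplicate variant key {c.key}")
        seen.add(c.key)
    return calls


def write_variant_table(calls: Iterable[VariantCall], path_or_buf) -> None:
    """Write calls as the same TSV format :func:`parse_variant_table` consumes."""
    rows = [
        {
            "subject_id": c.subject_id,
            "day": c.day,
            "compartment": c.compartment,
            "gene": c.gene,
            "variant_key": c.variant_key,
            "vaf": repr(c.vaf),
            "origin": c.origin,
        }
        for c in calls
    ]
    df = pd.DataFrame(rows, columns=["subject_id", "day", "compartment", "gene", "variant_key", "vaf", "origin"])
    df.to_csv(path_or_buf, sep="\t", index=False)


_TP_SPLIT = re.compile(r"[;,]")


def _parse_timepoints(token) -> frozenset | None:
    if token is None or (isinstance(token, float) and pd.isna(token)) or str(token).strip() == "":
        return None
    pairs = []
    for item in _TP_SPLIT.split(str(token)):
        comp, day = item.strip().split(":")
        pairs.append((comp, _parse_day(day)))
    return frozenset(pairs)


def _fmt_timepoints(tp: frozenset | None) -> str:
    if tp is None:
        return ""
    return ";".join(f"{c}:{d}" for c, d in sorted(tp, key=lambda p: (p[0], day_sort_key(p[1]))))


def parse_subject_sheet(source) -> list:
    """Read the subject sheet CSV into :class:`SubjectRecord` rows."""
    if isinstance(source, pd.DataFrame):
        df = source.copy()
    else:
        df = pd.read_csv(source, dtype=str)
    if "subject_id" not in df.columns:
        raise SchemaError("subject sheet missing required column: subject_id")

    def _int_or_none(v):
        if v is None or (isinstance(v, float) and pd.isna(v)) or str(v).strip() == "":
            return None
        return int(float(v))

    def _str(v, default=""):
        if v is None or (isinstance(v, float) and pd.isna(v)):
            return default
        return str(v)

    subjects = []
    for _, row in df.iterrows():
        adverse = _str(row.get("adverse_at_diagnosis"), "true").strip().lower() in ("1", "true", "yes", "y")
        subjects.append(
            SubjectRecord(
                subject_id=_str(row["subject_id"]).strip(),
                diagnosis=_str(row.get("diagnosis")).strip(),
                relapse_day=_int_or_none(row.get("relapse_day")),
                death_day=_int_or_none(row.get("death_day")),
                last_followup_day=_int_or_none(row.get("last_followup_day")) or 365,
                consolidation_start_day=_int_or_none(row.get("consolidation_start_day")),
                adverse_at_diagnosis=adverse,
                timepoints_available=_parse_timepoints(row.get("timepoints_available")),
                status_note=_str(row.get("status_note")).strip(),
            )
        )
    return subjects


def write_subject_sheet(subjects: Iterable[SubjectRecord], path_or_buf) -> None:
    rows = [
        {
            "subject_id": s.subject_id,
            "diagnosis": s.diagnosis,
            "relapse_day": s.relapse_day,
            "death_day": s.death_day,
            "last_followup_day": s.last_followup_day,
            "consolidation_start_day": s.consolidation_start_day,
            "adverse_at_diagnosis": str(s.adverse_at_diagnosis).lower(),
            "timepoints_available": _fmt_timepoints(s.timepoints_available),
            "status_note": s.status_note,
        }
        for s in subjects
    ]
    pd.DataFrame(rows).to_csv(path_or_buf, index=False)


# ---------------------------------------------------------------------------
# origin handling

def filter_somatic(calls: Sequence[VariantCall]) -> list:
    """Keep only calls of somatic origin; order preserved, idempotent."""
    return [c for c in calls if c.origin == "somatic"]


def annotate_origin(
    calls: Sequence[VariantCall],
    germline_vaf_band: tuple = DEFAULT_GERMLINE_BANDS,
    require_pre_presence: bool = True,
    donor_percent: Mapping | None = None,
    donor_tolerance: float = 5.0,
) -> list:
    """Infer a variant origin label for every call.

    The label is a heuristic standing in for the clinical judgement the
    printed tables already encode (the study reports which subjects carried
    germline or donor-transmitted variants but not the detection rule):

    * host_germline - the pre-transplant VAF falls inside a germline band
      (default around 50% or above 90%) in every pre-transplant compartment
      sampled for that variant;
    * donor_transmitted - absent pre-transplant, present at every
      post-transplant timepoint the subject was sampled at, and (when a
      donor-fraction series is supplied) tracking half the concurrent donor
      cfDNA fraction, as a heterozygous donor variant riding on engraftment;
    * somatic - everything else.

    ``donor_percent`` maps ``(subject_id, day) -> donor %`` from chimerism
    estimation; without it the donor-transmission VAF check is skipped and
    only the presence pattern is required.
    """
    by_subject: dict = {}
    for c in calls:
        by_subject.setdefault(c.subject_id, []).append(c)

    out = []
    for subject_id, subj_calls in by_subject.items():
        post_days = sorted({c.day for c in subj_calls if c.day != PRE}, key=day_sort_key)
        has_pre = any(c.day == PRE for c in subj_calls)
        if not has_pre and require_pre_presence:
            log.warning(
                "subject %s has no pre-transplant sample; host-germline rule skipped",
                subject_id,
            )

        by_variant: dict = {}
        for c in subj_calls:
            by_variant.setdefault((c.gene, c.variant_key), []).append(c)

        labels = {}
        for vkey, vcalls in by_variant.items():
            pre_vafs = [c.vaf for c in vcalls if c.day == PRE]
            obs_post_days = {c.day for c in vcalls if c.day != PRE}
            label = "somatic"
            if has_pre and pre_vafs and all(
                any(lo <= v <= hi for lo, hi in germline_vaf_band) for v in pre_vafs
            ):
                label = "host_germline"
            elif not pre_vafs and post_days and obs_post_days == set(post_days):
                ok = True
                if donor_percent is not None:
                    for c in vcalls:
                        expected = donor_percent.get((subject_id, c.day))
                        if expected is None or abs(c.vaf - expected / 2.0) > donor_tolerance:
                            ok = False
                            break
                else:
                    ok = False  # presence pattern alone is too weak without a donor series
                if ok:
                    label = "donor_transmitted"
            labels[vkey] = label

        for c in subj_calls:
            out.append(replace(c, origin=labels[(c.gene, c.variant_key)]))

    order = {id(c): i for i, c in enumerate(calls)}
    # restore input order (grouping above reorders across subjects)
    remap = {c.key: c for c in out}
    return [remap[c.key] for c in calls]


# ---------------------------------------------------------------------------
# minimal VCF subset for SNP genotype input

def read_snp_vcf(path, recipient_sample: str, donor_sample: str, plasma_sample: str) -> list:
    """Read chimerism-informative SNP observations from a small VCF.

    Recipient and donor genotypes come from per-sample GT; the plasma
    observation comes from the plasma sample's AD field (ref,alt allele
    depths).  Records with missing genotypes are skipped.
    """
    import pysam

    from .chimerism import SnpObservation

    obs = []
    with pysam.VariantFile(str(path)) as vf:
        for rec in vf:
            try:
                g_r = _gt_fraction(rec.samples[recipient_sample])
                g_d = _gt_fraction(rec.samples[donor_sample])
            except (KeyError, TypeError):
                continue
            if g_r is None or g_d is None:
                continue
            ad = rec.samples[plasma_sample].get("AD")
            if ad is None or any(a is None for a in ad):
                continue
            depth = int(sum(ad))
            vaf = (ad[1] / depth) if depth > 0 else 0.0
            obs.append(
                SnpObservation(
                    snp_id=rec.id or f"{rec.chrom}:{rec.pos}",
                    g_recipient=g_r,
                    g_donor=g_d,
                    vaf=vaf,
                    depth=depth,
                )
            )
    return obs


def _gt_fraction(sample) -> float | None:
    gt = sample.get("GT")
    if gt is None or any(a is None for a in gt):
        return None
    return sum(1 for a in gt if a == 1) / len(gt)


def read_snp_table(source) -> list:
    """Read SNP observations from TSV: snp_id, recipient_gt, donor_gt, observed_vaf, depth.

    Genotypes use the VCF "0/0, 0/1, 1/1" notation.  Optional subject_id and
    day columns attach the observation to a sample.
    """
    from .chimerism import SnpObservation

    if isinstance(source, pd.DataFrame):
        df = source.copy()
    else:
        df = pd.read_csv(source, sep="\t", dtype=str)
    required = ("snp_id", "recipient_gt", "donor_gt", "observed_vaf", "depth")
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"SNP table missing required column(s): {', '.join(missing)}")

    def _gt(token):
        alleles = re.split(r"[/|]", str(token).strip())
        return sum(1 for a in alleles if a == "1") / len(alleles)

    obs = []
    for _, row in df.iterrows():
        subject = row.get("subject_id")
        day = row.get("day")
        obs.append(
            SnpObservation(
                snp_id=str(row["snp_id"]),
                g_recipient=_gt(row["recipient_gt"]),
                g_donor=_gt(row["donor_gt"]),
                vaf=float(row["observed_vaf"]),
                depth=int(float(row["depth"])),
                subject_id=None if subject is None or pd.isna(subject) else str(subject),
                day=None if day is None or pd.isna(day) else _parse_day(day),
            )
        )
    return obs


def write_snp_table(observations, path_or_buf) -> None:
    def _gt_token(g):
        return {0.0: "0/0", 0.5: "0/1", 1.0: "1/1"}[float(g)]

    rows = [
        {
            "subject_id": o.subject_id,
            "day": o.day,
            "snp_id": o.snp_id,
            "recipient_gt": _gt_token(o.g_recipient),
            "donor_gt": _gt_token(o.g_donor),
            "observed_vaf": repr(o.vaf),
            "depth": o.depth,
        }
        for o in observations
    ]
    pd.DataFrame(rows, columns=["subject_id", "day", "snp_id", "recipient_gt", "donor_gt", "observed_vaf", "depth"]).to_csv(
        path_or_buf, sep="\t", index=False
    )
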