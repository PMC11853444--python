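"""Orchestration: simulate / analyze / report, and the in-study reproduction.

`analyze_cohort` runs the full analysis stack over a dataset (somatic
filtering, trajectories, chimerism, risk classification, relapse flags,
cohort statistics); `run_analysis` writes the resulting report bundle with
a reproducible manifest.  `compute_study_targets` recomputes, from the
packaged fixtures alone, every headline quantity of the source study that
the fixtures can support; `reproduce_paper` tabulates them against the
printed values.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .chimerism import ChimerismEstimate, estimate_donor_chimerism
from .cohort_stats import (
    build_paired_vafs,
    kruskal_wallis,
    median_range,
    survival_times,
    wilcoxon_matched_pairs,
)
from .errors import ConfigError, NotEvaluable
from .fixtures import discrepancy_report, fixture_trajectories, load_paper_fixture
from .mrd_tracking import (
    MutationTrajectory,
    build_trajectory,
    flag_impending_relapse,
    geometric_mean_vaf,
    trajectory_report_rows,
)
from .risk_model import (
    CLEARED_OR_NEGATIVE,
    RiskGeneSet,
    classify_subject,
    load_risk_gene_set,
    summarize_relapse_by_group,
)
from .variant_io import PRE, CohortDataset, filter_somatic

log = logging.getLogger(__name__)


@dataclass
class RunConfig:
    lod: float = 0.02
    germline_bands: tuple = ((40.0, 60.0), (90.0, 100.0))
    min_informative: int = 3
    fold_rise: float = 3.0
    count_rise: int = 3
    trend_delta: float = 2.0
    risk_set: RiskGeneSet | None = None
    seed: int | None = None

    def __post_init__(self):
        if self.fold_rise <= 0 or self.count_rise <= 0 or self.trend_delta <= 0:
            raise ConfigError("relapse-flag thresholds must be positive")
        if self.min_informative < 1:
            raise ConfigError("min_informative must be >= 1")


@dataclass
class AnalysisResults:
    trajectories: dict  # subject_id -> MutationTrajectory
    chimerism: list  # ChimerismEstimate
    classifications: list
    summary: object  # RelapseSummary
    relapse_flags: list
    stats: dict


def analyze_cohort(dataset: CohortDataset, config: RunConfig | None = None) -> AnalysisResults:
    """Run the analysis stack over a cohort dataset."""
    cfg = config or RunConfig()
    risk_set = cfg.risk_set or load_risk_gene_set()
    somatic = filter_somatic(dataset.variants)

    if dataset.mrd_table is not None:
        trajectories = fixture_trajectories(dataset)
    else:
        trajectories = {
            s.subject_id: build_trajectory(somatic, s) for s in dataset.subjects
        }

    chimerism = []
    by_sample: dict = {}
    for o in dataset.snp_observations:
        by_sample.setdefault((o.subject_id, o.day), []).append(o)
    for (sid, day), obs in sorted(by_sample.items(), key=lambda kv: (kv[0][0], str(kv[0][1]))):
        try:
            chimerism.append(
                estimate_donor_chimerism(
                    obs, min_informative=cfg.min_informative, subject_id=sid, day=day
                )
            )
        except NotEvaluable as exc:
            log.warning("chimerism %s day %s: %s", sid, day, exc)

    classifications = [
        classify_subject(trajectories[s.subject_id], s, risk_set) for s in dataset.subjects
    ]
    summary = summarize_relapse_by_group(classifications)

    relapse_flags = []
    for s in dataset.subjects:
        chi = [e for e in chimerism if e.subject_id == s.subject_id]
        try:
            relapse_flags.append(
                flag_impending_relapse(
                    trajectories[s.subject_id],
                    chi,
                    fold_rise=cfg.fold_rise,
                    count_rise=cfg.count_rise,
                    trend_delta=cfg.trend_delta,
                )
            )
        except NotEvaluable:
            pass

    stats = _cohort_statistics(dataset, somatic)
    return AnalysisResults(
        trajectories=trajectories,
        chimerism=chimerism,
        classifications=classifications,
        summary=summary,
        relapse_flags=relapse_flags,
        stats=stats,
    )


def _cohort_statistics(dataset: CohortDataset, somatic) -> dict:
    """Pre-transplant BM-vs-plasma comparisons plus survival bookkeeping."""
    stats: dict = {}
    bm_pre = [c for c in somatic if c.compartment == "BM" and c.day == PRE]
    pl_pre = [c for c in somatic if c.compartment == "plasma" and c.day == PRE]
    if bm_pre or pl_pre:
        counts_bm, counts_pl = [], []
        for s in dataset.subjects:
            counts_bm.append(sum(c.subject_id == s.subject_id for c in bm_pre))
            counts_pl.append(sum(c.subject_id == s.subject_id for c in pl_pre))
        try:
            kw = kruskal_wallis([counts_bm, counts_pl])
            stats["pre_mutation_counts"] = {
                "bm_total": int(np.sum(counts_bm)),
                "plasma_total": int(np.sum(counts_pl)),
                "kruskal_h": kw.statistic,
                "p": kw.p_value,
            }
        except NotEvaluable:
            pass
        try:
            pairs = build_paired_vafs(bm_pre, pl_pre)
            wil = wilcoxon_matched_pairs(pairs)
            stats["pre_vaf_paired"] = {
                "n_pairs": len(pairs),
                "n_used": wil.n_used,
                "statistic": wil.statistic,
                "p": wil.p_value,
                "median_bm": median_range([c.vaf for c in bm_pre])[0] if bm_pre else None,
                "median_plasma": median_range([c.vaf for c in pl_pre])[0] if pl_pre else None,
            }
        except NotEvaluable:
            pass
    surv = [survival_times(s) for s in dataset.subjects]
    stats["survival"] = [asdict(s) for s in surv]
    relapse_days = [s.relapse_day for s in dataset.subjects if s.relapse_day is not None]
    if relapse_days:
        med, lo, hi = median_range(relapse_days)
        stats["relapse_days"] = {"median": med, "min": lo, "max": hi, "n": len(relapse_days)}
    return stats


def run_analysis(dataset: CohortDataset, out_dir, config: RunConfig | None = None) -> AnalysisResults:
    """Analyze a dataset and write the report bundle under ``out_dir``."""
    cfg = config or RunConfig()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    results = analyze_cohort(dataset, cfg)

    rows = []
    for traj in results.trajectories.values():
        rows.extend(trajectory_report_rows(traj))
    pd.DataFrame(rows).to_csv(out / "trajectory_report.tsv", sep="\t", index=False)

    pd.DataFrame(
        [
            {
                "subject_id": e.subject_id,
                "day": e.day,
                "method": e.method,
                "donor_percent": e.donor_percent,
                "n_informative": e.n_informative,
            }
            for e in results.chimerism
        ]
    ).to_csv(out / "chimerism_report.tsv", sep="\t", index=False)

    pd.DataFrame([asdict(c) for c in results.classifications]).to_csv(
        out / "classification_report.tsv", sep="\t", index=False
    )
    with open(out / "stats.json", "w") as fh:
        json.dump(results.stats, fh, indent=2, sort_keys=True, default=str)

    cfg_doc = {
        "lod": cfg.lod,
        "germline_bands": [list(b) for b in cfg.germline_bands],
        "min_informative": cfg.min_informative,
        "fold_rise": cfg.fold_rise,
        "count_rise": cfg.count_rise,
        "trend_delta": cfg.trend_delta,
        "risk_set": sorted((cfg.risk_set or load_risk_gene_set()).adverse),
        "seed": cfg.seed,
    }
    manifest = {
        "package_version": __version__,
        "config": cfg_doc,
        "config_sha256": hashlib.sha256(
            json.dumps(cfg_doc, sort_keys=True).encode()
        ).hexdigest(),
        "n_subjects": len(dataset.subjects),
        "n_variants": len(dataset.variants),
        "seed": cfg.seed,
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return results


# ---------------------------------------------------------------------------
# in-study reproduction

def compute_study_targets() -> dict:
    """Recompute the study's headline quantities from the packaged fixtures.

    Every value is computed at call time from the fixture tables — GMs from
    the per-gene VAF lists, counts and medians from the day-84 columns, the
    risk contingency from the classification stack — never copied from the
    printed aggregates.
    """
    ds = load_paper_fixture()
    somatic = filter_somatic(ds.variants)

    def _vafs(sid, day, comp):
        return [
            c.vaf for c in somatic if c.subject_id == sid and c.day == day and c.compartment == comp
        ]

    targets: dict = {}
    gm_cells = {
        "t1": ("002", PRE, "plasma"),
        "t2": ("010", 84, "plasma"),
        "t3": ("019", PRE, "plasma"),
        "t4": ("019", PRE, "BM"),
    }
    for tid, (sid, day, comp) in gm_cells.items():
        vafs = _vafs(sid, day, comp)
        targets[tid] = {"value": geometric_mean_vaf(vafs), "n": len(vafs)}

    d84_bm = [c.vaf for c in somatic if c.day == 84 and c.compartment == "BM"]
    d84_pl = [c.vaf for c in somatic if c.day == 84 and c.compartment == "plasma"]
    targets["t5"] = {"value": len(d84_bm), "n": len(ds.subjects)}
    targets["t6"] = {"value": len(d84_pl), "n": len(ds.subjects)}
    targets["t7"] = {"value": float(np.median(d84_pl)), "n": len(d84_pl)}

    trajectories = fixture_trajectories(ds)
    risk_set = load_risk_gene_set()
    classifications = [
        classify_subject(trajectories[s.subject_id], s, risk_set) for s in ds.subjects
    ]
    persistent = [c for c in classifications if c.group == "persistent_adverse"]
    cleared = [c for c in classifications if c.group in CLEARED_OR_NEGATIVE]
    n_evaluable = sum(c.group != "not_evaluable" for c in classifications)
    targets["t8"] = {"value": len(persistent), "n": n_evaluable}
    targets["t9"] = {"value": sum(c.relapsed_12mo for c in persistent), "n": len(persistent)}
    targets["t10"] = {"value": sum(c.relapsed_12mo for c in cleared), "n": len(cleared)}

    relapse_days = [s.relapse_day for s in ds.subjects if s.relapse_day is not None]
    targets["t11"] = {"value": median_range(relapse_days)[0], "n": len(relapse_days)}

    post_days = (28, 56, 84)
    clean = 0
    for s in ds.subjects:
        cells = ds.mrd_table[
            (ds.mrd_table["subject_id"] == s.subject_id)
            & (ds.mrd_table["compartment"] == "plasma")
            & (ds.mrd_table["day"].isin(post_days))
            & (ds.mrd_table["status"] == "ok")
        ]
        if len(cells) == len(post_days) and (cells["n_mutations"] == 0).all():
            clean += 1
    targets["t12"] = {"value": clean, "n": len(ds.subjects)}
    return targets


#: printed values the reproduction table compares against
PRINTED_TARGETS = {
    "t1": ("GM VAF, subject 002 pre-transplant cfDNA (%)", 42.72, 0.05),
    "t2": ("GM VAF, subject 010 day-84 cfDNA (%)", 33.48, 0.05),
    "t3": ("GM VAF, subject 019 pre-transplant cfDNA (%)", 9.43, 0.05),
    "t4": ("GM VAF, subject 019 pre-transplant BM (%)", 5.79, 0.05),
    "t5": ("mutations detected, day-84 BM", 36, 0),
    "t6": ("mutations detected, day-84 cfDNA", 36, 0),
    "t7": ("median day-84 cfDNA VAF (%)", 0.39, 0.005),
    "t8": ("subjects with persistent adverse-risk mutations at day 84", 9, 0),
    "t9": ("relapses within 12 months among the persistent group", 6, 0),
    "t10": ("relapses among the cleared/MRD-negative group", 0, 0),
    "t11": ("median relapse day", 153, 0),
    "t12": ("subjects mutation-free at all three post-transplant plasma draws", 1, 0),
}


def reproduce_paper() -> pd.DataFrame:
    """Target-by-target comparison of recomputed vs printed study values."""
    computed = compute_study_targets()
    rows = []
    for tid, (desc, printed, tol) in PRINTED_TARGETS.items():
        value = computed[tid]["value"]
        rows.append(
            {
                "target": tid,
                "description": desc,
                "computed": value,
                "printed": printed,
                "n": computed[tid]["n"],
                "pass": abs(value - printed) <= tol,
            }
        )
    return pd.DataFrame(rows)


def plot_relapse_by_group(summary, path) -> None:
    """Grouped-bar chart of relapse vs non-relapse counts per risk group."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    groups = [g for g, row in summary.by_group.items() if row["n"] > 0]
    relapses = [summary.by_group[g]["relapses"] for g in groups]
    others = [summary.by_group[g]["n"] - summary.by_group[g]["relapses"] for g in groups]
    x = np.arange(len(groups))
    fig, ax = plt.subplots(figsize=(8, 4))
    ax.bar(x - 0.2, relapses, width=0.4, label="relapse <= 12 mo", color="#b2182b")
    ax.bar(x + 0.2, others, width=0.4, label="no relapse", color="#2166ac")
    ax.set_xticks(x)
    ax.set_xticklabels(groups, rotation=30, ha="right")
    ax.set_ylabel("subjects")
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
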