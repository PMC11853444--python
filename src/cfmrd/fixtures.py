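"""Packaged in-study fixtures: the printed mutation tables as data.

Two tables are shipped: the per-sample ``count/GM`` aggregate cells
(including the day-28/56 plasma draws, for which no per-gene identities
were printed) and the per-gene VAF lists at the pre-transplant and day-84
timepoints.  The tables are kept exactly as printed; the handful of cells
where they disagree with each other are surfaced by
:func:`discrepancy_report` rather than silently reconciled.
"""

from __future__ import annotations

from importlib import resources
from io import StringIO

import pandas as pd

from .mrd_tracking import MrdSample, MutationTrajectory, geometric_mean_vaf
from .variant_io import (
    PRE,
    CohortDataset,
    SubjectRecord,
    _parse_day,
    parse_subject_sheet,
    parse_variant_table,
)

#: |recomputed - printed| GM tolerance attributable to the 2-decimal
#: rounding of the printed per-gene inputs
GM_TOLERANCE = 0.05


def _read_packaged(name: str) -> str:
    return resources.files("cfmrd.data").joinpath(name).read_text()


def load_mrd_table() -> pd.DataFrame:
    """The printed aggregate cells: one row per (subject, day, compartment)."""
    df = pd.read_csv(StringIO(_read_packaged("table2_mrd.tsv")), sep="\t", dtype=str)
    df["day"] = df["day"].map(_parse_day)
    df["n_mutations"] = pd.to_numeric(df["n_mutations"], errors="coerce").astype("Int64")
    df["gm_vaf"] = pd.to_numeric(df["gm_vaf"], errors="coerce")
    df["gene_level"] = df["gene_level"].astype(int).astype(bool)
    return df


def load_paper_fixture() -> CohortDataset:
    """The 20-subject study cohort as a validated :class:`CohortDataset`.

    Subject ``timepoints_available`` lists the gene-resolved samples
    (pre-transplant BM/plasma and day-84 BM/plasma, minus the not-done
    cells); the full aggregate series lives in ``dataset.mrd_table``.
    """
    variants = parse_variant_table(StringIO(_read_packaged("table3_variants.tsv")))
    subjects = parse_subject_sheet(StringIO(_read_packaged("subjects.csv")))
    mrd = load_mrd_table()

    available: dict = {}
    for _, row in mrd.iterrows():
        if row["gene_level"] and row["status"] == "ok":
            available.setdefault(row["subject_id"], set()).add((row["compartment"], row["day"]))
    subjects = [
        SubjectRecord(
            **{
                **s.__dict__,
                "timepoints_available": frozenset(available.get(s.subject_id, set())),
            }
        )
        for s in subjects
    ]

    dataset = CohortDataset(subjects=subjects, variants=variants, mrd_table=mrd)
    dataset.validate()
    return dataset


def fixture_trajectories(dataset: CohortDataset) -> dict:
    """Per-subject trajectories merging aggregate cells and per-gene series.

    MRD samples carry the printed counts/GMs; the day-28/56 plasma samples
    have ``gene_level=False`` because only their aggregates were printed.
    Variant series come from the per-gene table.
    """
    if dataset.mrd_table is None:
        raise ValueError("dataset has no aggregate MRD table")
    trajectories = {}
    for subject in dataset.subjects:
        sid = subject.subject_id
        samples = []
        for _, row in dataset.mrd_table[dataset.mrd_table["subject_id"] == sid].iterrows():
            if row["status"] == "ND":
                samples.append(
                    MrdSample(sid, row["day"], row["compartment"], None, None, not_done=True,
                              gene_level=bool(row["gene_level"]))
                )
            else:
                n = int(row["n_mutations"])
                gm = None if pd.isna(row["gm_vaf"]) else float(row["gm_vaf"])
                samples.append(
                    MrdSample(sid, row["day"], row["compartment"], n, gm,
                              gene_level=bool(row["gene_level"]))
                )
        series: dict = {}
        for c in dataset.variants:
            if c.subject_id == sid:
                series.setdefault((c.gene, c.variant_key), {})[(c.compartment, c.day)] = c.vaf
        trajectories[sid] = MutationTrajectory(subject_id=sid, samples=samples, variant_series=series)
    return trajectories


def discrepancy_report(dataset: CohortDataset) -> pd.DataFrame:
    """Cells where the printed aggregates and the per-gene lists disagree.

    For every gene-resolved evaluable cell, the mutation count and GM are
    recomputed from the per-gene VAFs and compared against the printed
    aggregate; mismatched counts, and GMs differing by more than
    :data:`GM_TOLERANCE` at matching counts, are listed.
    """
    if dataset.mrd_table is None:
        raise ValueError("dataset has no aggregate MRD table")
    rows = []
    for _, row in dataset.mrd_table.iterrows():
        if not row["gene_level"] or row["status"] != "ok":
            continue
        sid, day, comp = row["subject_id"], row["day"], row["compartment"]
        vafs = [
            c.vaf
            for c in dataset.variants
            if c.subject_id == sid and c.day == day and c.compartment == comp and c.vaf > 0
        ]
        n_obs = len(vafs)
        gm_obs = geometric_mean_vaf(vafs)
        n_printed = int(row["n_mutations"])
        gm_printed = None if pd.isna(row["gm_vaf"]) else float(row["gm_vaf"])
        if n_obs != n_printed:
            kind = "count"
        elif gm_printed is not None and gm_obs is not None and abs(gm_obs - gm_printed) > GM_TOLERANCE:
            kind = "gm"
        else:
            continue
        rows.append(
            {
                "subject_id": sid,
                "day": day,
                "compartment": comp,
                "printed_n": n_printed,
                "recomputed_n": n_obs,
                "printed_gm": gm_printed,
                "recomputed_gm": gm_obs,
                "kind": kind,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "subject_id", "day", "compartment", "printed_n", "recomputed_n",
            "printed_gm", "recomputed_gm", "kind",
        ],
    )
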