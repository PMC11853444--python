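"""Synthetic transplant cohorts with ground truth for recovery testing.

The generator emulates the study design the analysis assumes: plasma
sampled at baseline (emitted with the "pre" sentinel) and at days 28/56/84
after graft infusion; 16 biallelic SNPs genotyped in donor and recipient
under Hardy-Weinberg; a residual-host fraction h(t) that decays
exponentially from 1 toward an engrafted floor, and regrows exponentially
after a programmed onset day in relapsing subjects; somatic clones whose
expected plasma VAF is CCF x tumor fraction / 2 under a heterozygous
single-clone approximation; and binomial read sampling at configurable
depth with a reporting limit of detection.

All randomness flows from one seed; each subject draws from a counter-keyed
substream so subject k is invariant to the cohort size.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field, replace
from typing import Sequence

import numpy as np

from .chimerism import SnpObservation
from .errors import ConfigError
from .variant_io import PRE, CohortDataset, SubjectRecord, VariantCall

ADVERSE_GENE_POOL = (
    "ASXL1", "BCOR", "EZH2", "FLT3-ITD", "RUNX1", "SETBP1", "SF3B1",
    "SRSF2", "STAG2", "TP53", "U2AF1", "ZRSR2", "WT1",
)
OTHER_GENE_POOL = (
    "DNMT3A", "TET2", "IDH1", "IDH2", "NRAS", "KRAS", "PPM1D", "CBL",
    "KMT2D", "NOTCH1", "PDGFRB", "CALR", "MPL",
)
GERMLINE_GENE_POOL = ("HFE", "ATM", "CHEK2", "MUTYH")


@dataclass(frozen=True)
class SimulationConfig:
    seed: int
    n_subjects: int = 20
    n_snps: int = 16
    snp_allele_freq: float = 0.5
    depth: int = 5000
    timepoints: tuple = (0, 28, 56, 84)
    relapse_fraction: float = 0.3
    clearance_halflife_days: float = 10.0
    regrowth_doubling_days: float = 14.0
    relapse_onset_day: int = 40
    adverse_gene_prob: float = 0.6
    mutations_min: int = 1
    mutations_max: int = 9
    baseline_vaf_min: float = 0.2
    baseline_vaf_max: float = 50.0
    host_fraction_engrafted: float = 0.05
    lod: float = 0.02  # percent; smallest VAF the report prints
    host_germline_prob: float = 0.3
    donor_transmitted_prob: float = 0.15

    def validate(self) -> None:
        fractions = {
            "snp_allele_freq": self.snp_allele_freq,
            "relapse_fraction": self.relapse_fraction,
            "adverse_gene_prob": self.adverse_gene_prob,
            "host_fraction_engrafted": self.host_fraction_engrafted,
            "host_germline_prob": self.host_germline_prob,
            "donor_transmitted_prob": self.donor_transmitted_prob,
        }
        for name, v in fractions.items():
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name} must be in [0, 1], got {v}")
        if self.depth <= 0:
            raise ConfigError("depth must be positive")
        if self.n_subjects <= 0 or self.n_snps <= 0:
            raise ConfigError("n_subjects and n_snps must be positive")
        if list(self.timepoints) != sorted(set(self.timepoints)):
            raise ConfigError("timepoints must be strictly increasing")
        if self.clearance_halflife_days <= 0 or self.regrowth_doubling_days <= 0:
            raise ConfigError("halflife and doubling time must be positive")
        if not 0 < self.mutations_min <= self.mutations_max:
            raise ConfigError("mutations_min/max must satisfy 0 < min <= max")
        if not 0 < self.baseline_vaf_min <= self.baseline_vaf_max <= 100:
            raise ConfigError("baseline VAF range must satisfy 0 < min <= max <= 100")


@dataclass
class SubjectTruth:
    subject_id: str
    relapse: bool
    relapse_day: int | None
    host_fraction: dict  # day -> h(t)
    tumor_fraction: dict  # day -> tumor-derived host fraction


@dataclass
class VariantTruth:
    subject_id: str
    gene: str
    variant_key: str
    origin: str
    adverse: bool
    expected_vaf: dict  # day -> percent


@dataclass
class GroundTruth:
    config: SimulationConfig
    subjects: dict = field(default_factory=dict)  # subject_id -> SubjectTruth
    variants: list = field(default_factory=list)

    def to_json(self) -> str:
        doc = {
            "config": asdict(self.config),
            "subjects": {k: asdict(v) for k, v in self.subjects.items()},
            "variants": [asdict(v) for v in self.variants],
        }
        return json.dumps(doc, indent=2, sort_keys=True)


def _hw_genotype(rng: np.random.Generator, p: float) -> float:
    probs = ((1 - p) ** 2, 2 * p * (1 - p), p**2)
    return float(rng.choice((0.0, 0.5, 1.0), p=probs))


def _decay(t: float, halflife: float) -> float:
    return 2.0 ** (-t / halflife)


def simulate_cohort(config: SimulationConfig) -> tuple:
    """Generate a cohort dataset plus full ground truth.

    Deterministic for a fixed config: identical configs produce identical
    datasets byte for byte when serialized.
    """
    config.validate()
    days = tuple(int(d) for d in config.timepoints)
    post_days = [d for d in days if d > 0]

    subjects, variants, snp_obs = [], [], []
    truth = GroundTruth(config=config)

    for k in range(config.n_subjects):
        sid = f"S{k + 1:03d}"
        rng = np.random.default_rng([config.seed % (2**31), k])

        relapse = bool(rng.random() < config.relapse_fraction)
        # tumor fraction regains its baseline after onset/halflife further doublings
        programmed_relapse_day = (
            int(
                round(
                    config.relapse_onset_day
                    + config.regrowth_doubling_days
                    * (config.relapse_onset_day / config.clearance_halflife_days)
                )
            )
            if relapse
            else None
        )

        # genotypes under Hardy-Weinberg, independent for donor and recipient
        g_r = [_hw_genotype(rng, config.snp_allele_freq) for _ in range(config.n_snps)]
        g_d = [_hw_genotype(rng, config.snp_allele_freq) for _ in range(config.n_snps)]

        # somatic clones
        n_mut = int(rng.integers(config.mutations_min, config.mutations_max + 1))
        v0 = rng.uniform(config.baseline_vaf_min, config.baseline_vaf_max, size=n_mut)
        f_tum0 = min(0.95, 2.0 * float(v0.max()) / 100.0)
        ccf = (2.0 * v0 / 100.0) / f_tum0  # largest clone has CCF 1

        def tumor_fraction(t: float) -> float:
            level = _decay(t, config.clearance_halflife_days)
            if relapse and t > config.relapse_onset_day:
                regrow = _decay(config.relapse_onset_day, config.clearance_halflife_days) * 2.0 ** (
                    (t - config.relapse_onset_day) / config.regrowth_doubling_days
                )
                level = max(level, regrow)
            return min(0.95, f_tum0 * level)

        def host_fraction(t: float) -> float:
            background = config.host_fraction_engrafted + (
                1.0 - config.host_fraction_engrafted - f_tum0
            ) * _decay(t, config.clearance_halflife_days)
            return min(1.0, background + tumor_fraction(t))

        genes, adverse_flags = [], []
        for j in range(n_mut):
            adverse = bool(rng.random() < config.adverse_gene_prob)
            pool = ADVERSE_GENE_POOL if adverse else OTHER_GENE_POOL
            genes.append(str(rng.choice(pool)))
            adverse_flags.append(adverse)

        plant_germline = bool(rng.random() < config.host_germline_prob)
        plant_donor = bool(rng.random() < config.donor_transmitted_prob)
        germline_gene = str(rng.choice(GERMLINE_GENE_POOL)) if plant_germline else None
        donor_gene = str(rng.choice(GERMLINE_GENE_POOL)) if plant_donor else None

        # expected VAF trajectories (percent)
        variant_specs = []  # (gene, variant_key, origin, adverse, {day: expected})
        name_counts: dict = {}
        for j, gene in enumerate(genes):
            name_counts[gene] = name_counts.get(gene, 0) + 1
            vkey = f"{gene}_m{name_counts[gene]}"
            expected = {d: float(ccf[j] * tumor_fraction(d) / 2.0 * 100.0) for d in days}
            variant_specs.append((gene, vkey, "somatic", adverse_flags[j], expected))
        if germline_gene is not None:
            expected = {d: float(50.0 * host_fraction(d)) for d in days}
            variant_specs.append((germline_gene, f"{germline_gene}_g1", "host_germline", False, expected))
        if donor_gene is not None:
            expected = {d: float(50.0 * (1.0 - host_fraction(d))) for d in days}
            variant_specs.append((donor_gene, f"{donor_gene}_d1", "donor_transmitted", False, expected))

        # observed variant table with binomial read noise and LOD reporting cut
        for gene, vkey, origin, adverse, expected in variant_specs:
            for d in days:
                p = min(1.0, max(0.0, expected[d] / 100.0))
                alt = int(rng.binomial(config.depth, p))
                obs = 100.0 * alt / config.depth
                if obs < config.lod:
                    continue
                variants.append(
                    VariantCall(
                        subject_id=sid,
                        day=PRE if d == 0 else d,
                        compartment="plasma",
                        gene=gene,
                        variant_key=vkey,
                        vaf=obs,
                        origin=origin,
                    )
                )
            truth.variants.append(
                VariantTruth(
                    subject_id=sid,
                    gene=gene,
                    variant_key=vkey,
                    origin=origin,
                    adverse=adverse,
                    expected_vaf=expected,
                )
            )

        # SNP observations on the post-transplant chimerism draws
        for d in post_days:
            h = host_fraction(d)
            for i in range(config.n_snps):
                e = h * g_r[i] + (1.0 - h) * g_d[i]
                alt = int(rng.binomial(config.depth, min(1.0, max(0.0, e))))
                snp_obs.append(
                    SnpObservation(
                        snp_id=f"snp{i + 1:02d}",
                        g_recipient=g_r[i],
                        g_donor=g_d[i],
                        vaf=alt / config.depth,
                        depth=config.depth,
                        subject_id=sid,
                        day=d,
                    )
                )

        adverse_any = any(a for a in adverse_flags)
        subjects.append(
            SubjectRecord(
                subject_id=sid,
                diagnosis="simulated myeloid malignancy",
                relapse_day=programmed_relapse_day,
                death_day=None,
                last_followup_day=365,
                consolidation_start_day=None,
                adverse_at_diagnosis=adverse_any,
                timepoints_available=frozenset(
                    ("plasma", PRE if d == 0 else d) for d in days
                ),
            )
        )
        truth.subjects[sid] = SubjectTruth(
            subject_id=sid,
            relapse=relapse,
            relapse_day=programmed_relapse_day,
            host_fraction={d: host_fraction(d) for d in days},
            tumor_fraction={d: tumor_fraction(d) for d in days},
        )

    dataset = CohortDataset(subjects=subjects, variants=variants, snp_observations=snp_obs)
    dataset.validate()
    return dataset, truth


# ---------------------------------------------------------------------------
# recovery metrics

@dataclass
class RecoveryReport:
    chimerism_mae: float | None
    chimerism_n: int
    clearance_confusion: dict  # {"tp", "fp", "fn", "tn"} on adverse persistence
    relapse_sensitivity: float | None
    relapse_lead_times: dict  # subject -> days between first flag and programmed relapse


def recovery_report(dataset: CohortDataset, truth: GroundTruth, estimates) -> RecoveryReport:
    """Score analysis outputs against the generator's ground truth.

    ``estimates`` is an :class:`~cfmrd.pipeline.AnalysisResults` (or any
    object with ``chimerism``, ``classifications`` and ``relapse_flags``
    attributes keyed by the dataset's subject ids).
    """
    ids = set(truth.subjects)

    errors = []
    for est in estimates.chimerism:
        if est.subject_id not in ids:
            raise KeyError(f"chimerism estimate for unknown subject {est.subject_id}")
        h = truth.subjects[est.subject_id].host_fraction[est.day]
        errors.append(abs(est.donor_percent - 100.0 * (1.0 - h)))
    mae = float(np.mean(errors)) if errors else None

    last_day = max(d for d in truth.config.timepoints)
    persists = {}
    for sid in ids:
        adverse_vafs = [
            v.expected_vaf[last_day]
            for v in truth.variants
            if v.subject_id == sid and v.adverse and v.origin == "somatic"
        ]
        persists[sid] = any(v >= truth.config.lod for v in adverse_vafs)
    confusion = {"tp": 0, "fp": 0, "fn": 0, "tn": 0}
    for c in estimates.classifications:
        if c.subject_id not in ids:
            raise KeyError(f"classification for unknown subject {c.subject_id}")
        if c.group == "not_evaluable":
            continue
        called = c.group == "persistent_adverse"
        actual = persists[c.subject_id]
        key = ("tp" if actual else "fp") if called else ("fn" if actual else "tn")
        confusion[key] += 1

    flags = {f.subject_id: f for f in estimates.relapse_flags}
    relapsers = [sid for sid, st in truth.subjects.items() if st.relapse]
    lead_times = {}
    hits = 0
    for sid in relapsers:
        flag = flags.get(sid)
        if flag is not None and flag.flagged:
            first_day = min(ev["to_day"] for ev in flag.evidence)
            rd = truth.subjects[sid].relapse_day
            if rd is not None:
                lead_times[sid] = rd - first_day
                if first_day <= rd:
                    hits += 1
            else:
                hits += 1
    sensitivity = hits / len(relapsers) if relapsers else None
    return RecoveryReport(
        chimerism_mae=mae,
        chimerism_n=len(errors),
        clearance_confusion=confusion,
        relapse_sensitivity=sensitivity,
        relapse_lead_times=lead_times,
    )
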