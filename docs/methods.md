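# Methods

`cfmrd` implements a surveillance analysis for patients with myeloid
malignancies after allogeneic hematopoietic stem-cell transplantation
(HSCT), built on two measurements taken from the same plasma cell-free DNA
(cfDNA) NGS panel: somatic-variant allele fractions (MRD tracking) and SNP
allele fractions (donor chimerism). Day 0 is the completion of the graft
infusion; samples are drawn at baseline ("pre", before conditioning) and at
days 28, 56 and 84.

## MRD aggregation

Each sample is summarised as the number of detected somatic mutations and
the geometric mean (GM) of their VAFs (percent scale):

    GM = exp( (1/n) * sum_i ln v_i )

Undetected mutations are *excluded*, never zero-filled — a zero would
annihilate the GM, and the printed clinical reports behave the same way. A
sample with zero detections has no GM ("NE", not evaluable); a sample never
drawn is "ND" (not done) and is skipped in all downstream rules, never
treated as negative. GMs are reported to 2 decimals; comparisons use a
±0.05 tolerance because the per-gene inputs are themselves printed to 2
decimals.

Presumed germline variants of host origin and donor-transmitted variants
are excluded before aggregation. The clinical source data encode only the
outcome of that judgement, so `annotate_origin` provides an explicit,
configurable heuristic: a variant is called host-germline when its
pre-transplant VAF lies in [40, 60] or [90, 100] percent (heterozygous /
homozygous bands) in every pre-transplant compartment sampled; it is called
donor-transmitted when it is absent pre-transplant, present at every
post-transplant timepoint, and tracks half the concurrent donor cfDNA
fraction (a heterozygous donor variant riding on engraftment) within a
5-point tolerance. The donor-transmission check requires a donor-fraction
series; without one, only the germline/somatic rules apply. Subjects with
no pre-transplant sample skip the germline rule with a logged warning.

## Donor chimerism from SNP allele fractions

Post-transplant plasma cfDNA is a host/donor mixture. At a biallelic SNP
with recipient genotype fraction g_R and donor genotype fraction g_D (each
0, 1/2 or 1), the expected alt fraction is the linear mixture

    v = h * g_R + (1 - h) * g_D,

with h the residual host fraction. Only *informative* SNPs (g_R ≠ g_D)
carry signal. Per informative SNP the host fraction is inverted as
ĥ_i = clamp((v_i − g_D)/(g_R − g_D), 0, 1); the sample estimate is the
median of the ĥ_i (mean of the central pair at even counts) and donor
chimerism is 100·(1 − median ĥ), rounded to 1 decimal. For hom↔hom SNPs
this is exactly the median VAF difference from the donor genotype; hom↔het
SNPs are rescaled by the factor 2 their halved genotype distance implies.
Formalising the published "median VAF difference" rule as a per-SNP mixture
inversion was a design choice: it makes the rule genotype-aware while
reproducing the simple behaviour on fully informative SNPs. Clamping is
applied per SNP *before* the median so a single noisy SNP cannot contribute
an out-of-range value. Samples with fewer than `min_informative` (default
3) informative SNPs are not evaluable rather than guessed. An optional
depth-weighted median exists behind a flag; the default estimator is
unweighted. With 16 panel SNPs and both genomes at allele frequency 0.5,
10 SNPs are informative on average (enumeration of Hardy–Weinberg genotype
pairs: P = 0.625).

Series are classified falling/rising/stable with a threshold of δ = 2
percentage points on every successive difference (the source study shows
trends only graphically; δ is configurable). Cross-method agreement
(cfDNA vs STR-based cellular chimerism) is reported as Pearson r per
nominal day on matched (subject, day) pairs, requiring ≥ 3 pairs.

## Clearance, persistence and relapse risk

Adverse risk-defining genes follow the ELN / Pethema / NCRI lists: ASXL1,
BCOR, EZH2, FLT3-ITD, RUNX1, SETBP1, SF3B1, SRSF2, STAG2, TP53, U2AF1,
ZRSR2, WT1 (packaged as editable YAML). FLT3-ITD is a distinct marker;
FLT3 point mutations are not adverse. WT1 is retained exactly as the
clinical source used it even though some schemes treat it differently.

Subjects are classified on plasma cfDNA at the **last evaluable
gene-resolved post-transplant timepoint** (day 84 when available — the only
post-transplant timepoint with per-gene identities in the packaged data):

* `persistent_adverse` — an adverse gene detected there;
* `cleared_post` — adverse genes in pre-transplant plasma but none at the
  last evaluable timepoint (ND timepoints never count as clearance);
* `cleared_pre` — adverse at diagnosis (subject metadata) but never in
  plasma, with mutation-positive staging samples;
* `mrd_negative_pre` — as above but with entirely mutation-free staging;
* `no_adverse_ever`, `not_evaluable` (e.g. death before the day-84 draw)
  complete the partition.

Diagnosis-era adverse status comes from subject metadata because
diagnosis-time panels are not part of the dataset. On the packaged cohort
this reproduces the published contingency: 9 persistent subjects of whom 6
relapsed within 12 months, and 0 relapses among the 9 cleared/negative
subjects, with 1 subject not evaluable.

An *impending relapse flag* fires between consecutive evaluable plasma
samples when the GM rises ≥ R-fold (default 3) or the mutation count rises
by ≥ C (default 3), **and** cfDNA chimerism is falling (δ = 2) across the
same span. The thresholds are configurable; the source describes the
pattern qualitatively ("dramatic rise … with a fall in donor chimerism").

## Statistics

* Wilcoxon matched-pair signed-rank for BM-vs-plasma VAFs, with a 0
  assigned to a mutation missing from one compartment. Zero differences
  are dropped, tied |differences| get mid-ranks, and the exact permutation
  distribution is used for n ≤ 25 via a subset-sum dynamic program (which
  handles mid-ranks exactly); larger n uses the normal approximation with
  continuity correction. The implementation is cross-checked against a
  brute-force 2^n enumeration and against scipy on tie-free inputs.
* Kruskal–Wallis (tie-corrected, chi-squared p) compares per-subject
  mutation counts between compartments; degenerate all-equal input returns
  H = 0, p = 1.
* Continuous summaries are medians with ranges; overall survival runs from
  day 0 to death, relapse-free survival to the earlier of relapse or death,
  both censored at last follow-up (12-month study horizon). No
  Kaplan–Meier or regression modelling is attempted, and no
  multiple-testing correction is applied — the analysis reports a handful
  of descriptive tests.

The published pre-transplant significance levels (p < 0.0001 for counts,
p = 0.02 for paired VAFs) were computed on complete mutation lists (92
plasma vs 61 marrow mutations) that are not part of the printed per-gene
tables, so they are not reproduction targets here; the package verifies
the *direction* of both effects on the packaged data (92 vs 60 mutation
rows; paired VAF medians 7.79% marrow vs 3.02% plasma).

## Packaged cohort data

The 20-subject cohort ships as two plain-text tables: the per-sample
aggregate `count/GM` cells (including day-28/56 plasma draws, for which no
per-gene identities were published) and the per-gene VAF lists at the pre
and day-84 timepoints. Cells are kept exactly as printed. The printed VAF
lists are typographically concatenated; the packaged segmentation was
chosen to reproduce the printed GMs where possible and is documented in
the repository history. A `discrepancy_report` lists the 13 cells where
the two printed tables contradict each other (10 count mismatches, 3 GM
mismatches at matching counts); the fixture-integrity test pins this set
so any fixture edit that changes it fails loudly. Aggregate-only cells
carry `gene_level=False` and are excluded from gene-level rules such as
persistence classification. Germline variants were already excluded from
the printed aggregates, so the packaged variants are all somatic and the
origin-annotation rules are exercised on synthetic data instead.

## Synthetic cohorts

The generator emulates the study's design with full ground truth:

* **Genotypes**: donor and recipient drawn independently per SNP under
  Hardy–Weinberg at allele frequency 0.5 (16 SNPs, configurable).
* **Host fraction**: h(t) = h_eng + (1 − h_eng − f_tum(0))·2^(−t/T½) +
  f_tum(t), decaying from 1 at day 0 toward an engrafted floor h_eng =
  0.05 with half-life T½ = 10 days; relapsing subjects additionally regrow
  the tumor fraction with doubling time 14 days from onset day 40. The
  programmed relapse day is when the tumor fraction regains its baseline
  (day 96 under defaults, within the published relapse range).
* **Somatic clones**: expected plasma VAF = CCF × tumor fraction / 2
  (heterozygous single-clone approximation); baseline VAFs uniform on
  0.2–50%, 1–9 mutations per subject, 60% adverse-risk genes — magnitudes
  chosen to mimic the printed tables.
* **Planted germline / donor-transmitted variants** at 50·h(t) and
  50·(1 − h(t)) percent respectively, for origin-annotation recovery.
* **Noise**: per-variant and per-SNP alt reads ~ Binomial(depth, expected
  fraction) at depth 5,000 (configurable); variants observed below the
  0.02% reporting limit are omitted from the emitted table (the smallest
  printed VAF is 0.03%).
* **Determinism**: one master seed; each subject uses a counter-keyed
  substream, so subject k's data are invariant to cohort size, and
  identical configs serialize byte-identically.

What the generator does **not** model: multi-clone phylogenies,
copy-number-driven VAF distortion, GC/fragment-length cfDNA biology, and
any real coupling between marrow disease burden and cfDNA tumor fraction
(the linear coupling is an assumption). Passing recovery tests therefore
demonstrate correctness of the estimators under the stated generative
model, not clinical performance on real cfDNA.

## Numerical choices and problem sizes

VAFs are carried on the percent scale throughout; fractions appear only
inside the chimerism mixture algebra and the simulator. A "/" between
digits in a numeric VAF field is read as a decimal point (two printed cells
carry a typographic slash) and logged. Timepoint alignment maps samples
within ±14 days to the nominal day, ties to the earlier day. Recovery
benchmarks use 200 simulated mixtures at depth 5,000 (mean absolute
chimerism error ≈ 0.3 points, bound at 2), 25–30-subject cohorts for
relapse-flag sensitivity, and depths 500/5,000/50,000 for the
monotone-difficulty check; these sizes make every test and the full
reproduction run in seconds on one CPU while leaving the binomial noise
clearly visible at the shallow end.
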