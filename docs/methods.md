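# Methods

`mitoburden` analyses mitochondrial whole-genome variant calls from matched
triplet cohorts: one patient sequenced at two clinical visits (V1, V2) and
one healthy control (HC) matched to the patient on sex and age (maximum
difference five years). This note documents the models, the numerical
choices, and what the synthetic cohorts do and do not establish.

## Coordinate system and regions

All positions are 1-based inclusive on the circular 16,569-bp revised
Cambridge Reference Sequence (rCRS, NC_012920.1), matching m.-notation and
every mtDNA database. The bundled annotation (`data/rcrs_regions.tsv`)
lists the 13 protein loci, 22 tRNAs, 2 rRNAs and the D-loop (which wraps
the origin: 16024–16569 plus 1–576, 1,122 bp). Macro regions group loci
into OxPhos Complex I/III/IV/V, tRNA, rRNA, D-loop and **Other**, the
complement macro: any position claimed by two loci (e.g. the
MT-ATP8/MT-ATP6 overlap, tRNAs encoded on opposite strands) or by none
(intergenic spacers). This makes the macro partition total and disjoint by
construction, so macro sizes always sum to 16,569 and no variant is
double-counted. A locus's *size* still counts every position it claims,
overlaps included; a variant inside an overlap is booked under Other only.
The loader rejects tables whose unannotated runs exceed 50 bp (the real
intergenic spacers are at most 31 bp), which catches omitted loci.

## Consensus variant acceptance

Variants are called twice: by a read-level mutserve-based pipeline (PCP)
and by the sequencing vendor's caller (TSS), whose limit of detection is a
10% variant level (VL, the fraction of mtDNA molecules carrying the
alternate allele). Acceptance rules:

* VL ≥ 10%: kept only with a matching TSS call (dual-caller consensus);
* VL < 10% without TSS support: kept only when all four read-level
  reliability indicators pass (normalized coverage ≥ 0.5, coverage ratio in
  [0.5, 2.0], mean reported NUMT count ≤ 1.0, distance to amplicon edge
  ≥ 5 bp) **and** the variant appears in a curated allow-list of previously
  reported mtDNA variants;
* TSS-only variants are never accepted.

The indicator thresholds are this package's defaults and are configurable;
upstream pipelines publish their own calibrations. Variant identity is the
pair (position, alt allele) with indels left-aligned and trimmed; the
reference allele comes from the rCRS. VLs are fractions internally and
percentages (two decimals) in reports. Sample-level sequencing QC flags
samples with mean coverage < 1,500 reads/bp or coverage uniformity < 85%
for resequencing.

## Burden scores

Protein variants carry two in-silico pathogenicity scores, MutPred and
APOGEE, both on [0, 1]; the *deleterious score* is their mean and a variant
is *deleterious* when that mean strictly exceeds 0.5. Variants missing
either score are excluded from the flag and from burden sums, never
imputed. tRNA variants carry the raw MitoTIP score instead; a tRNA variant
is called likely pathogenic above 12.66, the public quartile boundary used
by MITOMAP. Per sample:

* cumulative deleterious burden = Σ VL × deleterious score over scored
  protein variants. By default the sum runs over **all** scored protein
  variants (`burden_scope: all_scored`); restricting to flagged variants is
  available (`deleterious_only`) since the defining phrase admits both
  readings, and with scores above 0.5 the two differ only by the
  sub-threshold terms.
* cumulative MitoTIP score = Σ VL × MitoTIP over tRNA variants.

Per (sample, region): the adjusted mutational rate is Σ VL divided by
region size in bp; the adjusted deleterious and MitoTIP rates use
VL × score numerators. All scores are non-negative, additive over disjoint
variant sets, and invariant to variant order.

## Cross-sectional statistics (patient V1 vs matched HC)

Carrier prevalence per region is compared with the discordant-pair
machinery: b = pairs where only the patient qualifies, c = pairs where only
the control does; discordant prevalences are b/N and c/N. McNemar's test is
exact (two-sided binomial tail of b against Binomial(b+c, ½), doubled and
capped at 1) for b + c < 25 and continuity-corrected chi-square otherwise;
b + c = 0 gives p = 1. Quantitative region rates are compared with paired
t-tests; by default the rate is computed from *pair-discordant variants
only* (present in exactly one member, matched by position and alt), the
reading we adopt for "discordant rates"; an all-variants switch is
provided. Zero-variance paired differences are reported as degenerate
(p = 1 with zero mean, p = 0 with a constant non-zero shift) instead of
propagating NaN.

Each analysis batch is one false-discovery-rate family adjusted with
Benjamini–Hochberg step-up: per-locus prevalence, per-locus rates,
macro-region prevalence, macro-region rates, the deleterious-variant
versions of each, per-variant McNemar (one test per observed (pos, alt)),
and the haplogroup battery.

Haplogroup effects on per-sample summaries (variant count, deleterious
count, burden, cumulative MitoTIP) use Kruskal–Wallis over haplogroups with
at least three samples. In the pipeline the p-value comes from a seeded
permutation distribution of the H statistic (2,000 permutations) rather
than the chi-square approximation: with rare European haplogroups
contributing groups of 3–5 samples and heavily tied sparse scores, the
asymptotic test is measurably anticonservative, which a 200-replicate null
calibration of the family-wise false-positive rate confirmed. Categorical
independence (haplogroup × subject type, haplogroup × diagnostic
evolution, medication change × evolution) uses Fisher's exact test with
Monte Carlo simulation over fixed-margin tables (default 100,000 seeded
draws, the simulate-p-value approach of R's `fisher.test`).

Covariate checks per metric: linear regression on age (Kendall rank
correlation for counts), two-sample t by sex, and carrier-status × sex via
chi-square plus two-proportion z.

### Matched-design power

`dupont_paired_power` gives the exact power of the paired McNemar
comparison: each pair is case-only discordant with probability p₁₀,
control-only with p₀₁, concordant otherwise; power is the exact trinomial
probability that the two-sided test rejects at level α (reject iff
p ≤ α). The implementation enumerates the number of discordant pairs and
the conditional binomial split, and is validated against a 100,000-replicate
simulation of the 20-pair pilot design (discordances 0.45/0.10) within
±0.01. Because the exact test is conservative, size at the null sits below
the nominal level.

## Longitudinal dynamics

Within each patient, visit tables are matched by (position, alt) into
trajectories: **transient** variants appear at exactly one visit,
**persistent** variants at both, with ΔVL = VL(V2) − VL(V1). The partition
is total: transient_v + persistent counts reproduce each visit's variant
count exactly. The transient proportion of a visit divides by that visit's
variant count (a union-denominator reading is switchable); subjects with no
variants at a visit are censored, as is the mean transient VL when no
transient variants exist — missing values are always censored, never
imputed. ΔVL is tested against zero with one-sample t-tests, pooled over
variants and on per-subject means. Transient and persistent variants are
contrasted variable-by-variable (VL, the four reliability indicators,
deleterious score, MitoTIP) with two-sample t-tests in one FDR family;
variables absent for every variant are censored from the family. For
between-subject analyses a patient is one data point: the mean of the two
visits.

Diagnostic-evolution groupings (CIS–CIS, CIS–RRMS, RRMS–RRMS) are tested
with batch Kruskal–Wallis per clinical and per WGS variable, in two modes —
the mean of the visits and the V2 − V1 change — each mode one FDR family.
NEDA-3 requires zero relapses, zero gadolinium-enhancing lesions, no
new/enlarging T2 lesions, and no EDSS worsening; any missing component
leaves the classification absent rather than false. EDSS worsening uses the
field-standard confirmed-progression thresholds: ≥ 1.5 from baseline 0,
≥ 1.0 from baselines up to 5.5, ≥ 0.5 above (configurable). Annualized
relapse rate uses a 365.25-day year.

## Synthetic cohorts

The generator emulates the study's data at the caller-output level (no
reads); its defaults are the package's stated conditions:

* **Haplogroups** drawn from a European mix (H 0.40, HV 0.03, U 0.15,
  K 0.08, J 0.09, T 0.09, V 0.05, W 0.04, X 0.03, I 0.04). Each haplogroup
  has a fixed pool of 80 candidate defining variants (seeded by the
  haplogroup name, so clades are stable across cohorts); a sample draws its
  backbone homoplasmies (VL = 1) from its clade's pool with counts
  Normal(5, 2) for H, (7, 2) for HV, (11, 3) for V and ≈ (25–32, 4)
  elsewhere — reproducing the bimodal variant-count distribution driven by
  distance from the rCRS (itself haplogroup H).
* **Pathogenicity structure**: backbone protein variants draw
  MutPred/APOGEE from Beta(6, 4) in J/T, Beta(2, 8) in H/HV and
  Beta(1.5, 8) elsewhere, so deleterious carriers are a minority
  concentrated in J/T; tRNA variants draw MitoTIP from Normal(8, 2) in
  K/U, Normal(3, 1.5) in H/HV, Normal(5, 2) elsewhere, clipped to [0, 12]
  (below the pathogenicity threshold).
* **Private heteroplasmies**: Poisson(3) per subject, VL ~ Beta(1, 12)
  floored at 0.02 (the caller's limit of detection), placing most below
  the 10% consensus threshold so the rescue path is exercised. Each is
  transient with probability 0.30 (assigned to a random visit, VL scaled
  by 0.5 and floored at 0.02 — transient variants sit stochastically
  lower); persistent VLs drift by Normal(0, 0.01) between visits.
* **Caller echo**: TSS repeats each PCP variant, dropping sub-10%-VL
  variants with probability 0.05 and adding a TSS-only artifact to half
  the samples; 5% of low-VL variants draw failing reliability indicators
  and 10% are absent from the curated allow-list, so every branch of the
  consensus filter is visited.
* **Clinical records** use the observed diagnostic-evolution mix
  (CIS–CIS 0.23, CIS–RRMS 0.13, RRMS–RRMS 0.64), ages 19–56, 66% female,
  EDSS 0–4, and realistic lesion/OCT ranges; values are plausible, with no
  claim of distributional fidelity. RRMS–RRMS subjects draw more T2
  lesions by default, the one clinical group effect built in.

One master seed spawns an independent substream per triplet, so adding
triplets never perturbs existing samples and identical configurations are
byte-identical on disk. A ground-truth ledger records every variant's
category (backbone / persistent / transient / injected), true scores, and
expected post-filter fate, enabling exact recovery checks: a noise-free
configuration is recovered perfectly, and burden reconstruction is exact to
1e-12.

`null_config` builds fully exchangeable cohorts — one shared variant pool
(haplogroup labels carry no information), no transient asymmetry — under
which every comparison family holds its null; the test suite uses 200 such
replicates to confirm per-family false-positive control. `inject_effect`
raises the deleterious-carrier prevalence of one group in one macro region
by a chosen delta (each non-carrier gains, with the matching probability,
one persistent mid-VL deleterious variant), reproducing the pilot's
Complex I configuration; the power study samples carrier statuses from the
same independent-Bernoulli model, so its empirical rejection rate is
directly comparable to the exact enumeration.

### What the synthetic cohorts do not show

They start at caller output: alignment artifacts, NUMT contamination
patterns, strand bias and batch effects are summarized by four idealized
indicator variables, and the curated allow-list is simulated rather than a
real database snapshot. Haplogroup pools are random positions, not real
phylogenetic markers; clinical variables are independent of the mtDNA
variables except where an effect is injected. Passing tests therefore
establish the correctness of the *computations* — filtering logic,
arithmetic, statistical calibration, recovery of known structure — not the
biological conclusions one would draw from real cohorts.

## Problem sizes

The default cohort is 61 triplets (183 samples), analyzed end-to-end in a
few seconds. The suite's calibration studies use 200 null replicates at 61
triplets, 500 power replicates at 61 pairs, and structure checks at ≥ 200
samples, chosen to keep Monte-Carlo error well below the margins they are
compared against.
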