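# mitoburden

Analysis of mitochondrial DNA (mtDNA) whole-genome variant calls for
matched triplet cohorts — one patient sequenced at two clinical visits
(V1, V2) plus one healthy control (HC) matched on sex and age. The package
was built for studies of mtDNA heteroplasmy in immune cells of people with
multiple sclerosis, but the machinery applies to any paired mtDNA design
that starts from caller output.

It provides, as a library plus a small CLI:

* **Consensus variant filtering** across two callers: a variant with
  variant level (VL) ≥ 10% is accepted only when both callers report it;
  sub-10% variants from the sensitive caller alone are rescued only when
  four read-level reliability indicators pass and the variant appears in a
  curated allow-list.
* **Region-aware burden scores** on the circular rCRS (NC_012920.1):
  cumulative deleterious burden Σ VL·s with s = mean(MutPred, APOGEE),
  cumulative MitoTIP Σ VL·MitoTIP over tRNA variants, and per-region
  adjusted rates Σ VL / region size (per bp) over loci and OxPhos
  macro regions.
* **Paired cross-sectional statistics**: discordant carrier prevalences
  with exact McNemar tests, paired t-tests on discordant region rates,
  haplogroup Kruskal–Wallis (seeded permutation reference), Fisher's exact
  test with Monte Carlo simulation, Benjamini–Hochberg FDR per analysis
  family, and the exact power of the matched design by trinomial
  enumeration over discordant-pair counts.
* **Longitudinal dynamics**: per-subject partition of variants into
  transient (one visit) and persistent (both visits, with ΔVL drift),
  transient-vs-persistent contrasts, NEDA-3 classification, and
  diagnostic-evolution batteries.
* **A seeded synthetic-cohort generator** with a ground-truth ledger:
  European haplogroup structure with clade-defining homoplasmies, low-VL
  private heteroplasmies, transient/persistent dynamics, dual-caller echo
  with dropout, clinical records, and injectable group effects — so the
  whole pipeline is testable without any restricted data.

See `docs/methods.md` for the full model description and design choices.

## Worked example

```sh
mitoburden simulate --n-triplets 61 --seed 7 --out cohort/
mitoburden run --in cohort/ --out report/ --seed 1
```

The first command writes 183 samples (61 triplets) in the pipeline's input
dialects: per-sample PCP variant tables (`pcp/*.tsv`), vendor-caller VCFs
(`tss/*.vcf`), a sample sheet, score tables, a curated allow-list, the
clinical table, and `ground_truth.tsv`. The second runs
ingest → score → cross-sectional → longitudinal and writes the report
bundle (`burden_per_sample.tsv`, `burden_per_region.tsv`,
`cross_sectional_tests.tsv`, `longitudinal_tests.tsv`,
`subject_metrics.tsv`, `summary.json`). Reruns with the same inputs and
seed are byte-identical.

The same analysis from Python:

```python
import mitoburden as mb

cohort = mb.simulate_cohort(mb.SimConfig(n_triplets=61, seed=7))
out = mb.analyze_cohort(cohort, mb.RunConfig(seed=1))

sig = [r for r in out["cross_sectional"]["results"]
       if r.p_fdr is not None and r.p_fdr < 0.05]
print(len(out["cross_sectional"]["results"]), "tests,",
      len(sig), "significant after FDR")
print("haplogroup families:",
      [f"{r.unit}: H={r.statistic:.1f}, p_fdr={r.p_fdr:.2e}"
       for r in sig if r.family == "haplogroup"])
```

prints

```
1188 tests, 4 significant after FDR
haplogroup families: ['n_variants: H=94.8, p_fdr=5.00e-04',
'n_deleterious: H=113.7, p_fdr=5.00e-04',
'cumulative_deleterious_burden: H=106.0, p_fdr=5.00e-04',
'cumulative_mitotip: H=86.4, p_fdr=5.00e-04']
```

— the generator's haplogroup structure (H/HV carry few variants; J/T carry
the deleterious burden; K/U the MitoTIP load) is detected, while the
patient-vs-control comparisons stay null, since no group effect was
injected. The permutation p-values floor at 1/(n_perm + 1).

`mcnemar_exact(9, 2)` — the pilot's Complex I discordance of 9 vs 2 in 20
pairs — gives p = 0.0654, and
`dupont_paired_power(61, 0.44, 0.09)` ≈ 0.97: the full design is well
powered for the pilot's effect size.

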