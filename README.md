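# hepadx

Gene-panel exome diagnostics for chronic liver disease: tiered variant
filtering, ACMG-AMP classification, inheritance-mode genotype matching,
a high-MAF known-pathogenic allowlist, and case-control enrichment
statistics — exercised end to end on synthetic three-cohort fixtures
with planted truth.

## The problem

Exome sequencing against a curated panel of genes for Mendelian
hepatobiliary disorders can yield a molecular diagnosis in patients with
chronic liver disease (CLD), but a naive search for "previously reported
pathogenic" variants finds candidates in ~20% of *any* cohort — including
healthy controls — because reference databases contain entries with
allele frequencies far too high to cause rare monogenic disease.
`hepadx` implements the filtering cascade that separates real diagnoses
from this noise, for cohort-scale analysis from Python:

1. **Genotype quality gates** — DP > 9, VQSR = PASS, Qual > 49, QD ≥ 2,
   GQ ≥ 20, MQ ≥ 40, alternate-read fraction > 0.25.
2. **Candidate categories** — ClinVar P/LP and/or HGMD DM without
   conflicting evidence, plus novel protein-truncating variants (PTVs)
   with a high-confidence LOFTEE prediction; global gnomAD AF < 1%.
3. **Inheritance-aware frequency gate** — maximum MAF over 8 ancestry
   subpopulations × {ExAC, gnomAD}: ≤ 10⁻⁴ for dominant, ≤ 10⁻³ for
   recessive disorders.
4. **ACMG-AMP combination** — evidence tags (PVS1, PS1–4, PM1–6, PP1–5,
   BA1, BS1–4, BP1–7) combined by the guideline rules into
   pathogenic / likely pathogenic / VUS / likely benign / benign.
5. **Inheritance matching** — dominant heterozygous; recessive
   homozygous or unphased compound-heterozygous (a single heterozygote
   in a recessive gene is a carrier, not a diagnosis); X-linked
   hemizygous.
6. **Tier-2 rescue** — re-screen under relaxed quality thresholds
   (DP ≥ 4, GQ ≥ 10, Qual ≥ 30, QD ≥ 1, alt fraction > 0.20, VQSR not
   required) restricted to variants lost to strict quality alone.
7. **Allowlist** — well-established pathogenic alleles with MAF above
   the gates (HFE C282Y/H63D, SERPINA1 Pi\*Z/Pi\*S) diagnosed by
   genotype pattern, plus frequency-exempt recessive alleles
   (ABCB4 Ala934Thr, CPT2 Lys414fs).

Carrier enrichment is tested with the Wald odds ratio
OR = ad/(bc), CI = exp(ln OR ± z₀.₀₂₅·√(1/a+1/b+1/c+1/d)), and Pearson's
χ² (Yates-corrected for 2×2 tables).

Because the real cohorts and the manually curated panel are not
distributable, a first-class synthetic-data module generates the three
study cohorts (HC n=7856, CKD n=2187, CLD n=758) with planted truth:
tier-1 carriers (51/25/24), 16 tier-2 rescue variants in 14 CLD
patients, allowlist genotypes, and misannotated common decoys producing
the ~20% naive candidate rate. The pipeline must recover the planted
truth set exactly.

## Worked example

```python
from hepadx import GeneratorConfig, generate_panel, generate_cohort, run_pipeline

cfg = GeneratorConfig()                  # default study-scale conditions
panel = generate_panel(cfg, seed=1)      # 502 genes: 363 AR, 15 XLR, 61 AD, 1 XLD, 62 AD/AR
data = generate_cohort(cfg, panel, seed=1)
result = run_pipeline(data.calls, data.sites, data.manifest, panel, data.acmg_tags)
print(result.stage_counts)
```

prints

```
           n  naive  tier1  tier2  allowlist  diagnosed
cohort
HC      7856   1567     51      0          0         51
CKD     2187    416     25      0          0         25
CLD      758    159     24     14          5         43
```

Reading the CLD row: 159/758 samples (21.0%) carry a naive candidate
(mostly decoys); the subpopulation-MAF gate plus inheritance matching
leaves 24 tier-1 diagnoses (3.17%, vs 0.65% in healthy controls —
OR 5.00, 95% CI 3.06–8.18, Yates χ² p = 4.55e−12); tier-2 rescue adds 14
patients and the allowlist genotypes (1 homozygous C282Y, 1 H63D with a
second truncating HFE allele, 3 Pi ZZ) add 5 more, for 43/758 = 5.7%
diagnosed. The emitted call set equals the generator's planted truth
exactly.

The `examples/` directory has one short script per capability (panel
summaries and the constraint ANOVA, candidate screening, ACMG-AMP
combination, the full cascade, enrichment statistics). A thin CLI wraps
the same library calls:

```bash
hepadx run-all --seed 42 --outdir out/
hepadx simulate --seed 1 --outdir fixture/
hepadx diagnose --panel fixture/panel.tsv --variants fixture/variants.tsv \
    --manifest fixture/manifest.tsv --acmg fixture/acmg_tags.tsv --out dx/
```

## Layout

- `src/hepadx/panel.py` — panel loading/validation, composition summaries, constraint ANOVA
- `src/hepadx/variants.py` — manifest/variant-table IO, variant-key normalisation, filter configs, subpopulation MAF
- `src/hepadx/screen.py` — quality gates, candidate categories, frequency gates, cohort screen
- `src/hepadx/acmg.py` — ACMG-AMP evidence combination
- `src/hepadx/diagnose.py` — inheritance matching, tier-2 rescue, allowlist, pipeline
- `src/hepadx/stats.py` — prevalence, odds ratios, chi-square, subgroup tables
- `src/hepadx/simulate.py` — synthetic cohort generator with planted truth
- `src/hepadx/report.py`, `src/hepadx/cli.py` — reporting and the CLI
- `docs/methods.md` — models, assumptions, parameter choices, limitations
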