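# Methods

## Scope and model

`hepadx` models a gene-panel diagnostic screen of exome data for
Mendelian liver disease. The unit of analysis is a cohort: a sample
manifest, per-sample genotype calls with quality metrics, and per-site
annotations (consequence, ClinVar/HGMD status, LOFTEE flag, CADD,
global and subpopulation allele frequencies). A diagnosis is a
sample-level call: one gene, one or two variant keys, a genotype
configuration consistent with the gene's inheritance mode, a stage
(tier-1 strict / tier-2 rescue / allowlist), and an ACMG-AMP class
restricted to pathogenic or likely pathogenic.

Cohort-scale collections are pandas DataFrames with fixed schemas
rather than lists of record objects; the screen is fully vectorised and
a 10,801-sample cohort with ~0.5M genotype rows screens in seconds.
Record classes (`PanelGene`, `FilterConfig`, `GeneratorConfig`,
`DiagnosticCall`, `Allowlist`) carry the validated scalar structures.

## Filtering cascade

**Quality gates.** The strict regime is DP > 9, VQSR = PASS, Qual > 49,
QD ≥ 2, GQ ≥ 20, MQ ≥ 40, alternate-read fraction > 0.25. Integer
thresholds are stored as inclusive lower bounds (`min_dp=10`,
`min_qual=50`), which reproduces the mixed strict/inclusive operators
exactly on integer-valued metrics with a single comparison form and
keeps threshold tightening monotone (a property test asserts that
tightening any one threshold never enlarges the pass set). The
alternate-read-fraction bound is strict (`> 0.25`) in every regime. The
relaxed tier-2 regime (DP ≥ 4, GQ ≥ 10, Qual ≥ 30, QD ≥ 1, MQ ≥ 40, alt
fraction > 0.20, VQSR not required) is a package default — the rescue
regime in the source analysis is described only qualitatively — chosen
so the strict-pass set is provably a subset of the relaxed-pass set;
every field is configurable, and `tier2_rescue` rejects any relaxed
config that is stricter than the strict config in any field or that
alters a frequency gate.

**Candidate categories.** ClinVar P/LP + HGMD DM → `both`; ClinVar P/LP
alone → `clinvar_only`; HGMD DM with ClinVar neither P/LP nor
conflicting → `hgmd_only`; a ClinVar "conflicting" record blocks
candidacy even against HGMD DM (conflict within either database
excludes). Variants absent from both databases qualify only as
`novel_ptv`: protein-truncating consequence with a high-confidence
LOFTEE prediction. Only consequences with at least moderate predicted
effect (ptv, missense, splice_region, inframe) enter candidacy.

**Frequency gates.** Global gnomAD AF < 1% (strict), then the maximum
AF over 8 ancestry subpopulations (AFR, AMR, ASJ, FIN, NFE, EAS, SAS,
OTH) in each of ExAC and gnomAD — 16 entries, missing = 0 — compared
inclusively against 10⁻⁴ (dominant context) or 10⁻³ (recessive
context). Dual-mode (AD_AR) genes are evaluated under both contexts and
keep per-context flags: a variant surviving only the recessive context
contributes only to biallelic configurations downstream.

## ACMG-AMP combination

Only the combination algebra is computed; evidence-tag assignment is an
input (clinically it is analyst consensus). The engine implements the
guideline combining table: Pathogenic for PVS1 with (≥1 PS, ≥2 PM,
PM+PP, or ≥2 PP), ≥2 PS, or 1 PS with (≥3 PM, 2 PM + ≥2 PP, or
1 PM + ≥4 PP); Likely pathogenic for PVS1+1 PM, 1 PS + 1–2 PM,
1 PS + ≥2 PP, ≥3 PM, 2 PM + ≥2 PP, or 1 PM + ≥4 PP; Benign for BA1 or
≥2 BS; Likely benign for 1 BS + 1 BP or ≥2 BP; any simultaneous firing
of a pathogenic-side and a benign-side rule yields VUS, as does
insufficient evidence. The engine is checked against an independently
transcribed rule table on 10,000 random tag sets. Variants with no tag
annotation classify as VUS and can never produce a call.

## Inheritance matching

Per sample × gene over P/LP variants passing the relevant context
gates: AD/XLD (and the AD_AR dominant context, tried first) call a
`dominant_het` on the best variant; AR (and the AD_AR recessive
context) call `homozygous` on a hom-alt variant, else `compound_het` on
two distinct heterozygotes with `phase_known=False` (an option excludes
unphased pairs); XLR calls `hemizygous` for males (hemi or hom-alt
encoded) and `homozygous` for females; single heterozygotes in
recessive genes are carriers, never calls. Ties break deterministically
by classification rank, then lower maximum-subpopulation MAF, then
lexicographic variant key; a compound-het pair takes the weaker of its
two alleles' classes.

**Tier-2 rescue** re-screens under the relaxed quality regime with
frequency and category gates unchanged, and emits only configurations
that include at least one variant failing strict quality, skipping
sample × gene pairs already diagnosed at tier-1. A mixed pair (one
strict-passing het plus one rescued het) is therefore a valid tier-2
compound heterozygote.

**Allowlist.** Four high-MAF established pathogenic alleles are
excluded from tier-1/2 matching and handled by genotype pattern:
homozygous HFE C282Y, C282Y-or-H63D with a second HFE P/LP or
high-confidence truncating allele, and SERPINA1 Pi ZZ are diagnostic;
homozygous H63D, compound C282Y/H63D, Pi MZ/MS/SS and Pi Z/Pi S are
tallied as carrier states (the compound C282Y/H63D genotype is
non-diagnostic by default because clinical confirmation, which is out
of scope, decides those cases). Two further alleles (ABCB4 Ala934Thr,
CPT2 Lys414fs) are exempt from the subpopulation-MAF gate but flow
through ordinary recessive matching. Pattern matching applies the
strict genotype-quality gates; the regime is configurable. The
"second HFE allele" rule requires LOFTEE high confidence for
truncating candidates, mirroring the novel-PTV rule.

## Statistics

Carrier prevalence is per-cohort samples with ≥1 call in a requested
tier set. Enrichment uses the Wald odds ratio OR = ad/(bc) with
CI = exp(ln OR ± z·SE), SE = √(1/a+1/b+1/c+1/d); zero cells are an
error unless the Haldane–Anscombe +0.5 correction is requested.
Chi-square tests are Pearson with expected counts from the margins,
Yates-corrected automatically for 2×2 tables only — this pair of
choices (the default behaviour of R's `chisq.test`) reproduces both the
2×2 carrier-table p (4.55e−12) and the 6×2 primary-diagnosis subgroup p
(6.48e−19). The headline comparison is CLD vs HC as a 2×2; a 3×2
overall test across all cohorts is also emitted. No multiple-testing
correction is applied by default. Subgroup tables contrast diagnosed vs
undiagnosed CLD samples over sex, age group, race/ethnicity or primary
diagnosis; implementation is scipy (`chi2_contingency`, `f_oneway`)
behind the module surface, with first-principles sum-of-squares and
expected-count oracles in the tests.

The panel constraint ANOVA compares pLI or missense Z across
dominant-only (AD ∪ XLD), recessive-only (AR ∪ XLR) and dual-mode
groups, excluding missing scores listwise; a two-group
dominant-vs-recessive contrast is available since the headline contrast
is between those two groups while three groups are displayed.

## Synthetic cohorts: what is emulated and what is not

The generator is a pure function of (config, seed) and plants, per the
default `GeneratorConfig`: cohort sizes 7856/2187/758; tier-1 carriers
51/25/24 with genotype configurations drawn to match their gene's mode
(PTV fraction 78/112 among planted P/LP variants; planted tags
{PVS1, PM2} or {PVS1, PM2, PP5} for PTVs, {PS1, PM2} or {PS1, PS3, PM2}
for known missense — combining to LP or P); 16 tier-2 variants in 14
CLD samples (12 single-variant configurations and 2 compound-het pairs),
each degraded in exactly one randomly chosen quality metric into the
strict-fail/relaxed-pass band; allowlist genotypes per the configured
per-cohort category counts (diagnostic genotypes — 1 homozygous C282Y,
1 H63D + truncating HFE allele, 3 Pi ZZ — in CLD only, carrier
genotypes in all cohorts); and enough decoy carriers to reach naive
candidate counts of 1567/416/159 (≈20/19/21% of each cohort). Decoy
sites have global AF in (0.002, 0.0095) and one subpopulation AF in
(0.005, 0.05), so they survive the global 1% gate and die at the
inheritance gate — the two-stage collapse of the naive excess. Planted
AD_AR recessive configurations carry subpopulation MAF in
(10⁻⁴, 10⁻³] so they survive only the recessive context and the
recovered configuration equals the planted one. CLD metadata is
assigned from diagnosed/undiagnosed marginals so subgroup tables
reproduce the planted clinical-covariate association; other cohorts get
uninformative metadata. Background variation is 50 benign panel-gene
variants per sample (≈0.5M rows — large enough to exercise the gates at
realistic scale, small enough for desk-scale runs) that pass quality
but can never be candidates. Generation-time assertions verify the
planting invariants (tier-1 passes strict; tier-2 falls in the rescue
band; decoys fail the recessive MAF gate).

Not emulated: haplotype/LD structure and phasing, read-level data,
real gene identities (symbols are LIVG0001… except the four allowlist
genes, which keep their real symbols because the genotype rules name
them), sequencing-artifact blacklists, CNVs and mosaicism. Passing the
planted-truth tests therefore demonstrates the correctness of the
filtering, classification and matching logic under the modelled
conditions — not performance on real exomes, where evidence assignment
and annotation quality dominate.

## Numerical and design notes

- Variant keys are 1-based `chrom:pos:ref:alt`, normalised to minimal
  representation (shared suffix then prefix trimming); multi-allelic
  records are rejected and must be decomposed upstream.
- Allele frequencies absent from a database are 0 ("novel"), which is
  what admits novel PTVs through the frequency gates.
- Degenerate statistics: an ANOVA with zero variance everywhere reports
  F = 0, p = 1; chi-square rejects zero margins; prevalence of an empty
  cohort is flagged missing.
- Percent formatting: one decimal for diagnostic rates, integers for
  panel-composition percents; raw fractions are retained internally.
- Report JSON is validated by a shipped pydantic schema
  (`hepadx.report.ReportSummary`; `summary_schema()` exports JSON
  Schema).
- The tests and the acceptance script run the full-size default fixture
  (10,801 samples, ~0.5M genotype rows, a few seconds per seed); the
  unit-test fixture uses a 130-sample desk-scale configuration with the
  same structure.

## Known limitations

- ACMG-AMP tag assignment is not automated; the pipeline's diagnostic
  yield on real data is bounded by the quality of the supplied tags.
- Compound heterozygotes are unphased by default; with phase-aware
  callers the `include_unphased=False` option gives conservative calls.
- The allowlist genotype rules are genotype-driven defaults; clinical
  chart concordance, which decides borderline genotypes in practice, is
  out of scope.
- The Wald CI is asymptotic; with very sparse tables prefer the
  Haldane-corrected OR or an exact test (not provided).
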