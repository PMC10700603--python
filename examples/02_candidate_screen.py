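"""Tier-1 screening: the naive candidate excess and its collapse.

Generates a small three-cohort fixture, screens it with the strict
quality gates, and shows how the global-AF candidate search produces an
implausibly high carrier rate (misannotated common 'pathogenic' decoys)
that the inheritance-aware subpopulation-MAF gate removes.
"""

from hepadx import GeneratorConfig, generate_cohort, generate_panel, screen_cohort

cfg = GeneratorConfig(
    cohort_sizes={"HC": 200, "CKD": 50, "CLD": 100},
    tier1_carriers={"HC": 2, "CKD": 1, "CLD": 3},
    naive_carriers={"HC": 40, "CKD": 10, "CLD": 21},
    tier2_n_variants=2,
    tier2_n_samples=2,
    allowlist_planted={"HC": {}, "CKD": {}, "CLD": {}},
    background_per_sample=10,
    n_background_sites=300,
    panel_composition={"AR": 20, "XLR": 2, "AD": 5, "XLD": 1, "AD_AR": 4},
)
panel = generate_panel(cfg, seed=2)
data = generate_cohort(cfg, panel, seed=2)
res = screen_cohort(data.calls, data.sites, panel)

cohort_of = dict(zip(data.manifest["sample_id"], data.manifest["cohort"]))
for stage in ("naive", "tier1"):
    carriers = res.carriers(stage)
    by = carriers.map(cohort_of).value_counts()
    print(f"{stage:>6} carriers:", {k: int(v) for k, v in by.items()})
print("candidate categories:", res.category_counts)
# naive carriers >> tier-1 carriers: the decoys survive the 1% global AF
# gate but fail the dominant 1e-4 / recessive 1e-3 subpopulation gates.
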