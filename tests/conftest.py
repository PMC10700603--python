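import pytest

from hepadx import GeneratorConfig, generate_cohort, generate_panel, run_pipeline


def small_generator_config() -> GeneratorConfig:
    """Desk-scale cohorts exercising every pipeline stage."""
    return GeneratorConfig(
        cohort_sizes={"HC": 60, "CKD": 30, "CLD": 40},
        tier1_carriers={"HC": 3, "CKD": 2, "CLD": 3},
        naive_carriers={"HC": 12, "CKD": 6, "CLD": 8},
        tier2_n_variants=3,
        tier2_n_samples=2,
        allowlist_planted={
            "HC": {"Pi MS": 2, "Compound C282Y/H63D": 1},
            "CKD": {},
            "CLD": {"Homozygous C282Y": 1, "Pi ZZ": 1, "Pi MZ": 2},
        },
        n_decoy_sites=5,
        background_per_sample=5,
        n_background_sites=120,
        panel_composition={"AR": 20, "XLR": 2, "AD": 5, "XLD": 1, "AD_AR": 4},
    )


@pytest.fixture(scope="session")
def small_cfg():
    return small_generator_config()


@pytest.fixture(scope="session")
def small_fixture(small_cfg):
    """(panel, cohort data) for the desk-scale configuration."""
    panel = generate_panel(small_cfg, seed=5)
    data = generate_cohort(small_cfg, panel, seed=5)
    return panel, data


@pytest.fixture(scope="session")
def default_panel():
    """The default 502-gene synthetic panel."""
    return generate_panel(GeneratorConfig(), seed=1)


@pytest.fixture(scope="session")
def default_run():
    """One full-size default fixture with its pipeline result (seed 11)."""
    cfg = GeneratorConfig()
    panel = generate_panel(cfg, seed=11)
    data = generate_cohort(cfg, panel, seed=11)
    result = run_pipeline(data.calls, data.sites, data.manifest, panel, data.acmg_tags)
    return cfg, panel, data, result


def truth_tuples(truth):
    return {
        (t["sample_id"], t["gene"], t["tier"], t["configuration"], tuple(sorted(t["variant_keys"])))
        for t in truth
    }


def call_tuples(calls):
    return {
        (c.sample_id, c.gene, c.tier, c.configuration, tuple(sorted(c.variant_keys)))
        for c in calls
    }
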