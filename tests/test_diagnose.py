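"""Inheritance matching, tier-2 rescue, allowlist genotypes, full pipeline."""

import pandas as pd
import pytest

from hepadx.diagnose import (
    DEFAULT_ALLOWLIST,
    ConfigError,
    DiagnosticCall,
    allowlist_diagnose,
    match_inheritance,
    run_pipeline,
    tier2_rescue,
)
from hepadx.panel import PanelGene
from hepadx.variants import RELAXED_FILTERS, STRICT_FILTERS
from conftest import call_tuples, truth_tuples

AR_GENE = PanelGene("LIVGT01", "2", "AR")
AD_GENE = PanelGene("LIVGT02", "3", "AD")
XLR_GENE = PanelGene("LIVGT03", "X", "XLR")
DUAL_GENE = PanelGene("LIVGT04", "5", "AD_AR")

MALE = {"sample_id": "S1", "sex": "male"}
FEMALE = {"sample_id": "S2", "sex": "female"}


def q(rows):
    return pd.DataFrame(
        rows,
        columns=["variant_key", "zygosity", "classification", "max_subpop_maf", "dominant_ok", "recessive_ok"],
    )


class TestMatchInheritance:
    def test_single_het_in_recessive_gene_is_carrier_not_call(self):
        rows = q([("2:10:A:T", "het", "pathogenic", 0.0, True, True)])
        assert match_inheritance(MALE, AR_GENE, rows) is None

    def test_two_distinct_hets_make_unphased_compound_het(self):
        rows = q(
            [
                ("2:10:A:T", "het", "likely_pathogenic", 0.0, True, True),
                ("2:20:G:C", "het", "likely_pathogenic", 0.0, True, True),
            ]
        )
        call = match_inheritance(MALE, AR_GENE, rows)
        assert call.configuration == "compound_het"
        assert call.phase_known is False
        assert call.variant_keys == ("2:10:A:T", "2:20:G:C")

    def test_unphased_pairs_can_be_excluded(self):
        rows = q(
            [
                ("2:10:A:T", "het", "pathogenic", 0.0, True, True),
                ("2:20:G:C", "het", "pathogenic", 0.0, True, True),
            ]
        )
        assert match_inheritance(MALE, AR_GENE, rows, include_unphased=False) is None

    def test_homozygote_beats_compound(self):
        rows = q(
            [
                ("2:10:A:T", "het", "pathogenic", 0.0, True, True),
                ("2:20:G:C", "hom_alt", "likely_pathogenic", 0.0, True, True),
            ]
        )
        call = match_inheritance(MALE, AR_GENE, rows)
        assert call.configuration == "homozygous"
        assert call.variant_keys == ("2:20:G:C",)

    def test_dominant_single_het_calls(self):
        rows = q([("3:10:A:T", "het", "pathogenic", 0.0, True, True)])
        call = match_inheritance(MALE, AD_GENE, rows)
        assert call.configuration == "dominant_het"

    def test_dominant_hom_still_one_call_one_key(self):
        rows = q([("3:10:A:T", "hom_alt", "pathogenic", 0.0, True, True)])
        call = match_inheritance(MALE, AD_GENE, rows)
        assert call.configuration == "dominant_het" and len(call.variant_keys) == 1

    def test_xlr_male_hemi_female_het_asymmetry(self):
        rows_m = q([("X:10:A:T", "hemi", "pathogenic", 0.0, True, True)])
        assert match_inheritance(MALE, XLR_GENE, rows_m).configuration == "hemizygous"
        rows_f = q([("X:10:A:T", "het", "pathogenic", 0.0, True, True)])
        assert match_inheritance(FEMALE, XLR_GENE, rows_f) is None
        rows_fh = q([("X:10:A:T", "hom_alt", "pathogenic", 0.0, True, True)])
        assert match_inheritance(FEMALE, XLR_GENE, rows_fh).configuration == "homozygous"

    def test_dual_gene_dominant_context_first_then_recessive(self):
        dom = q([("5:10:A:T", "het", "pathogenic", 5e-5, True, True)])
        assert match_inheritance(MALE, DUAL_GENE, dom).configuration == "dominant_het"
        rec = q(
            [
                ("5:10:A:T", "het", "pathogenic", 5e-4, False, True),
                ("5:20:G:C", "het", "pathogenic", 5e-4, False, True),
            ]
        )
        call = match_inheritance(MALE, DUAL_GENE, rec)
        assert call.configuration == "compound_het"
        single = q([("5:10:A:T", "het", "pathogenic", 5e-4, False, True)])
        assert match_inheritance(MALE, DUAL_GENE, single) is None

    def test_tie_break_prefers_stronger_then_rarer_then_key(self):
        rows = q(
            [
                ("3:30:A:T", "het", "likely_pathogenic", 0.0, True, True),
                ("3:20:A:T", "het", "pathogenic", 1e-5, True, True),
                ("3:10:A:T", "het", "pathogenic", 0.0, True, True),
            ]
        )
        call = match_inheritance(MALE, AD_GENE, rows)
        assert call.variant_keys == ("3:10:A:T",)

    def test_mixed_genes_rejected(self):
        rows = q([("3:10:A:T", "het", "pathogenic", 0.0, True, True)])
        rows["gene"] = ["A"]
        rows2 = q([("3:20:A:T", "het", "pathogenic", 0.0, True, True)])
        rows2["gene"] = ["B"]
        with pytest.raises(ValueError, match="multiple genes"):
            match_inheritance(MALE, AD_GENE, pd.concat([rows, rows2]))


class TestDiagnosticCallInvariants:
    def test_compound_het_needs_two_distinct_keys(self):
        with pytest.raises(ValueError):
            DiagnosticCall("S", "G", ("k1",), "compound_het", "tier1", "pathogenic")
        with pytest.raises(ValueError):
            DiagnosticCall("S", "G", ("k1", "k1"), "compound_het", "tier1", "pathogenic")

    def test_only_plp_classifications_allowed(self):
        with pytest.raises(ValueError):
            DiagnosticCall("S", "G", ("k1",), "dominant_het", "tier1", "vus")


class TestTier2Rescue:
    def test_relaxed_stricter_than_strict_rejected(self, small_fixture):
        panel, data = small_fixture
        bad = STRICT_FILTERS.model_copy(update={"min_dp": 20})
        with pytest.raises(ConfigError):
            tier2_rescue(
                data.calls, data.sites, panel, STRICT_FILTERS, bad, {}, data.manifest
            )

    def test_relaxed_equal_strict_rescues_nothing(self, small_fixture):
        panel, data = small_fixture
        calls = tier2_rescue(
            data.calls, data.sites, panel, STRICT_FILTERS, STRICT_FILTERS,
            {k: "likely_pathogenic" for k in data.acmg_tags}, data.manifest,
        )
        assert calls == []

    def test_planted_rescues_recovered(self, small_fixture):
        panel, data = small_fixture
        from hepadx.diagnose import classify_variants

        classifications = classify_variants(data.acmg_tags)
        calls = tier2_rescue(
            data.calls, data.sites, panel, STRICT_FILTERS, RELAXED_FILTERS,
            classifications, data.manifest,
        )
        expected = truth_tuples([t for t in data.truth if t["tier"] == "tier2"])
        assert call_tuples(calls) == expected

    def test_variant_failing_both_configs_not_rescued(self, small_fixture):
        panel, data = small_fixture
        from hepadx.diagnose import classify_variants

        calls = data.calls.copy()
        rescued_keys = {k for t in data.truth if t["tier"] == "tier2" for k in t["variant_keys"]}
        calls.loc[calls["variant_key"].isin(rescued_keys), "dp"] = 1  # below relaxed too
        out = tier2_rescue(
            calls, data.sites, panel, STRICT_FILTERS, RELAXED_FILTERS,
            classify_variants(data.acmg_tags), data.manifest,
        )
        assert out == []


class TestAllowlist:
    def _calls(self, sample_genos):
        rows = []
        for sid, genos in sample_genos.items():
            for key, zyg in genos.items():
                rows.append(
                    {
                        "sample_id": sid, "variant_key": key, "zygosity": zyg,
                        "dp": 30, "gq": 90, "mq": 60.0, "qd": 10.0, "qual": 500.0,
                        "vqsr_pass": True, "alt_fraction": 1.0 if zyg == "hom_alt" else 0.5,
                    }
                )
        return pd.DataFrame(rows)

    def _manifest(self, ids):
        return pd.DataFrame(
            {"sample_id": list(ids), "cohort": "CLD", "sex": "female",
             "age_group": "0-21", "race_eth": "White", "primary_dx": "Other"}
        )

    def _sites(self):
        from hepadx.variants import AF_COLUMNS
        rows = []
        for key, gene, cons, loftee in [
            (DEFAULT_ALLOWLIST.key("HFE", "C282Y"), "HFE", "missense", "NA"),
            (DEFAULT_ALLOWLIST.key("HFE", "H63D"), "HFE", "missense", "NA"),
            (DEFAULT_ALLOWLIST.key("SERPINA1", "PiZ"), "SERPINA1", "missense", "NA"),
            (DEFAULT_ALLOWLIST.key("SERPINA1", "PiS"), "SERPINA1", "missense", "NA"),
            ("6:26091388:G:A", "HFE", "ptv", "HC"),
        ]:
            site = {c: 0.0 for c in AF_COLUMNS}
            site.update(variant_key=key, gene=gene, consequence=cons, global_af=0.02,
                        clinvar="P", hgmd="DM", loftee=loftee, cadd=25.0)
            rows.append(site)
        return pd.DataFrame(rows)

    def test_hom_c282y_is_diagnostic(self):
        c282y = DEFAULT_ALLOWLIST.key("HFE", "C282Y")
        tally, calls = allowlist_diagnose(
            self._calls({"S1": {c282y: "hom_alt"}}), self._sites(), self._manifest(["S1"])
        )
        assert tally.loc["Homozygous C282Y", "CLD"] == 1
        assert len(calls) == 1 and calls[0].tier == "allowlist"

    def test_pizz_diagnostic_but_pimz_carrier_only(self):
        piz = DEFAULT_ALLOWLIST.key("SERPINA1", "PiZ")
        tally, calls = allowlist_diagnose(
            self._calls({"S1": {piz: "hom_alt"}, "S2": {piz: "het"}}),
            self._sites(),
            self._manifest(["S1", "S2"]),
        )
        assert tally.loc["Pi ZZ", "CLD"] == 1
        assert tally.loc["Pi MZ", "CLD"] == 1
        assert {c.sample_id for c in calls} == {"S1"}

    def test_h63d_with_second_truncating_allele_is_diagnostic(self):
        h63d = DEFAULT_ALLOWLIST.key("HFE", "H63D")
        tally, calls = allowlist_diagnose(
            self._calls({"S1": {h63d: "het", "6:26091388:G:A": "het"}}),
            self._sites(),
            self._manifest(["S1"]),
        )
        assert tally.loc["C282Y or H63D/PTV", "CLD"] == 1
        assert len(calls) == 1 and set(calls[0].variant_keys) == {h63d, "6:26091388:G:A"}

    def test_compound_c282y_h63d_tallied_not_diagnostic(self):
        c282y = DEFAULT_ALLOWLIST.key("HFE", "C282Y")
        h63d = DEFAULT_ALLOWLIST.key("HFE", "H63D")
        tally, calls = allowlist_diagnose(
            self._calls({"S1": {c282y: "het", h63d: "het"}}), self._sites(), self._manifest(["S1"])
        )
        assert tally.loc["Compound C282Y/H63D", "CLD"] == 1
        assert calls == []


class TestPipeline:
    def test_recovers_planted_truth_exactly(self, small_fixture):
        panel, data = small_fixture
        result = run_pipeline(data.calls, data.sites, data.manifest, panel, data.acmg_tags)
        assert call_tuples(result.calls) == truth_tuples(data.truth)

    def test_tiers_disjoint_per_sample_gene(self, small_fixture):
        panel, data = small_fixture
        result = run_pipeline(data.calls, data.sites, data.manifest, panel, data.acmg_tags)
        seen = {}
        for c in result.calls:
            key = (c.sample_id, c.gene)
            assert key not in seen, f"{key} called at both {seen.get(key)} and {c.tier}"
            seen[key] = c.tier

    def test_recessive_calls_carry_two_pathogenic_alleles(self, small_fixture):
        panel, data = small_fixture
        result = run_pipeline(data.calls, data.sites, data.manifest, panel, data.acmg_tags)
        modes = {g.symbol: g.inheritance_mode for g in panel}
        for c in result.calls:
            if c.configuration == "compound_het":
                assert len(c.variant_keys) == 2
            if modes.get(c.gene) in ("AR", "XLR") and c.tier != "allowlist":
                assert c.configuration in ("homozygous", "compound_het", "hemizygous")

    def test_skip_tier2_equals_tier1_union_allowlist(self, small_fixture):
        panel, data = small_fixture
        full = run_pipeline(data.calls, data.sites, data.manifest, panel, data.acmg_tags)
        part = run_pipeline(
            data.calls, data.sites, data.manifest, panel, data.acmg_tags, skip_tier2=True
        )
        expected = {t for t in call_tuples(full.calls) if t[2] != "tier2"}
        assert call_tuples(part.calls) == expected

    def test_zero_planted_truth_zero_calls(self):
        from conftest import small_generator_config
        from hepadx import generate_cohort, generate_panel

        cfg = small_generator_config().model_copy(
            update={
                "tier1_carriers": {"HC": 0, "CKD": 0, "CLD": 0},
                "naive_carriers": {"HC": 0, "CKD": 0, "CLD": 0},
                "tier2_n_variants": 0,
                "tier2_n_samples": 0,
                "allowlist_planted": {"HC": {}, "CKD": {}, "CLD": {}},
            }
        )
        panel = generate_panel(cfg, seed=9)
        data = generate_cohort(cfg, panel, seed=9)
        result = run_pipeline(data.calls, data.sites, data.manifest, panel, data.acmg_tags)
        assert result.calls == []
        assert (result.stage_counts["diagnosed"] == 0).all()
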