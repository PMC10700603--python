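"""Quality gates, candidate categorisation, frequency gates, cohort screen."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hepadx.screen import (
    CATEGORIES,
    categorize_candidate,
    frequency_gates,
    pass_quality,
    pass_quality_frame,
    screen_cohort,
)
from hepadx.variants import AF_COLUMNS, FilterConfig, STRICT_FILTERS


def _call(**kw):
    base = dict(dp=30, gq=90, mq=60.0, qd=10.0, qual=500.0, vqsr_pass=True, alt_fraction=0.5)
    base.update(kw)
    return base


class TestPassQuality:
    def test_boundary_values_pass_strict_defaults(self):
        # DP>9, Qual>49 (strict on integers), QD/GQ/MQ inclusive, alt>0.25
        call = _call(dp=10, qual=50.0, qd=2.0, gq=20, mq=40.0, alt_fraction=0.26)
        assert pass_quality(call, STRICT_FILTERS)

    @pytest.mark.parametrize(
        "kw",
        [
            {"dp": 9},
            {"qual": 49.0},
            {"qd": 1.99},
            {"gq": 19},
            {"mq": 39.9},
            {"alt_fraction": 0.25},
            {"vqsr_pass": False},
        ],
    )
    def test_single_failing_metric_fails(self, kw):
        assert not pass_quality(_call(**kw), STRICT_FILTERS)

    def test_vqsr_not_required_when_configured(self):
        cfg = FilterConfig(require_vqsr_pass=False)
        assert pass_quality(_call(vqsr_pass=False), cfg)

    def test_frame_agrees_with_scalar(self):
        rng = np.random.default_rng(3)
        n = 500
        calls = pd.DataFrame(
            {
                "dp": rng.integers(0, 40, n),
                "gq": rng.integers(0, 100, n),
                "mq": rng.uniform(20, 70, n),
                "qd": rng.uniform(0, 20, n),
                "qual": rng.uniform(0, 600, n),
                "vqsr_pass": rng.random(n) < 0.8,
                "alt_fraction": rng.uniform(0, 1, n),
            }
        )
        vec = pass_quality_frame(calls, STRICT_FILTERS)
        scalar = calls.apply(lambda r: pass_quality(r, STRICT_FILTERS), axis=1)
        assert (vec == scalar).all()


def oracle_category(clinvar, hgmd, consequence, loftee):
    """Exhaustive enumeration oracle over the status grid."""
    if clinvar in ("P", "LP"):
        return "both" if hgmd == "DM" else "clinvar_only"
    if hgmd == "DM":
        return None if clinvar == "conflicting" else "hgmd_only"
    if clinvar == "absent" and hgmd == "absent" and consequence == "ptv" and loftee == "HC":
        return "novel_ptv"
    return None


class TestCategorize:
    def test_full_status_grid_matches_oracle(self):
        for clinvar, hgmd, cons, loftee in itertools.product(
            ("P", "LP", "conflicting", "other", "absent"),
            ("DM", "other", "absent"),
            ("ptv", "missense"),
            ("HC", "LC", "NA"),
        ):
            site = {"clinvar": clinvar, "hgmd": hgmd, "consequence": cons, "loftee": loftee}
            assert categorize_candidate(site) == oracle_category(clinvar, hgmd, cons, loftee), site

    def test_low_confidence_ptv_excluded(self):
        site = {"clinvar": "absent", "hgmd": "absent", "consequence": "ptv", "loftee": "LC"}
        assert categorize_candidate(site) is None

    def test_conflicting_clinvar_blocks_dm(self):
        site = {"clinvar": "conflicting", "hgmd": "DM", "consequence": "missense", "loftee": "NA"}
        assert categorize_candidate(site) is None


class TestFrequencyGates:
    def _site(self, global_af=0.0, subpop=0.0):
        site = {c: 0.0 for c in AF_COLUMNS}
        site["af_nfe_g"] = subpop
        site["global_af"] = global_af
        return site

    def test_all_zero_passes_everything(self):
        g, ctx = frequency_gates(self._site(), STRICT_FILTERS)
        assert g and ctx["dominant"] and ctx["recessive"]

    def test_dominant_bound_is_inclusive(self):
        _, ctx = frequency_gates(self._site(subpop=1e-4), STRICT_FILTERS)
        assert ctx["dominant"]

    def test_between_thresholds_splits_contexts(self):
        _, ctx = frequency_gates(self._site(subpop=5e-4), STRICT_FILTERS)
        assert not ctx["dominant"] and ctx["recessive"]

    def test_global_gate_strict_below_one_percent(self):
        g, _ = frequency_gates(self._site(global_af=0.01), STRICT_FILTERS)
        assert not g
        g, _ = frequency_gates(self._site(global_af=0.0099), STRICT_FILTERS)
        assert g


class TestScreenCohort:
    def test_empty_cohort(self, small_fixture):
        panel, data = small_fixture
        res = screen_cohort(data.calls.iloc[0:0], data.sites, panel)
        assert res.candidates.empty

    def test_tier1_subset_of_naive(self, small_fixture):
        panel, data = small_fixture
        res = screen_cohort(data.calls, data.sites, panel)
        assert res.candidates.loc[res.candidates["tier1"], "naive"].all()
        assert set(res.carriers("tier1")) <= set(res.carriers("naive"))

    def test_categories_partition_retained_set(self, small_fixture):
        panel, data = small_fixture
        res = screen_cohort(data.calls, data.sites, panel)
        naive = res.naive
        assert naive["category"].isin(CATEGORIES).all()
        assert sum(res.category_counts.values()) == len(naive)

    def test_decoy_in_naive_but_not_tier1(self, small_fixture):
        """Common misannotated 'pathogenic' sites survive the global AF gate
        but die at the subpopulation-MAF inheritance gate."""
        panel, data = small_fixture
        res = screen_cohort(data.calls, data.sites, panel)
        decoyish = res.candidates[res.candidates["max_subpop_maf"] > 1e-3]
        assert len(decoyish) and decoyish["naive"].any()
        assert not decoyish["tier1"].any()

    def test_matches_composed_predicate_oracle(self, small_fixture):
        panel, data = small_fixture
        from hepadx.screen import categorize_candidate, pass_quality
        from hepadx.variants import IMPACTFUL_CONSEQUENCES, max_subpop_maf

        res = screen_cohort(data.calls, data.sites, panel)
        modes = {g.symbol: g.inheritance_mode for g in panel}
        merged = data.calls.merge(data.sites, on="variant_key")
        merged = merged[merged["gene"].isin(modes)]
        sub = merged.sample(n=min(400, len(merged)), random_state=0)
        got = res.candidates.set_index(["sample_id", "variant_key"])
        for _, row in sub.iterrows():
            naive = (
                pass_quality(row, STRICT_FILTERS)
                and row["consequence"] in IMPACTFUL_CONSEQUENCES
                and row["global_af"] < STRICT_FILTERS.global_af_max
                and categorize_candidate(row) is not None
            )
            mx = max_subpop_maf(row)
            mode = modes[row["gene"]]
            gate = {
                "AD": mx <= 1e-4,
                "XLD": mx <= 1e-4,
                "AR": mx <= 1e-3,
                "XLR": mx <= 1e-3,
                "AD_AR": mx <= 1e-3,
            }[mode]
            rec = got.loc[(row["sample_id"], row["variant_key"])]
            assert bool(rec["naive"]) == naive
            assert bool(rec["tier1"]) == (naive and gate)

    def test_nonpanel_genes_counted_not_screened(self, small_fixture):
        panel, data = small_fixture
        sites = data.sites.copy()
        # rename one background gene out of the panel
        victim = sites["gene"].iloc[0]
        sites.loc[sites["gene"] == victim, "gene"] = "NOTPANEL1"
        res = screen_cohort(data.calls, sites, panel)
        assert res.n_nonpanel > 0
        assert not (res.candidates["gene"] == "NOTPANEL1").any()


_threshold_fields = ("min_dp", "min_qual", "min_qd", "min_gq", "min_mq", "min_alt_fraction")


@settings(max_examples=60, deadline=None, derandomize=True)
@given(
    field=st.sampled_from(_threshold_fields),
    delta=st.floats(0.1, 20),
    seed=st.integers(0, 1000),
)
def test_tightening_thresholds_never_enlarges_pass_set(field, delta, seed):
    rng = np.random.default_rng(seed)
    n = 200
    calls = pd.DataFrame(
        {
            "dp": rng.integers(0, 40, n),
            "gq": rng.integers(0, 100, n),
            "mq": rng.uniform(20, 70, n),
            "qd": rng.uniform(0, 20, n),
            "qual": rng.uniform(0, 600, n),
            "vqsr_pass": rng.random(n) < 0.8,
            "alt_fraction": rng.uniform(0, 1, n),
        }
    )
    base = FilterConfig()
    raised = getattr(base, field) + (int(np.ceil(delta)) if field in ("min_dp", "min_gq") else delta)
    tight = base.model_copy(update={field: raised})
    loose_set = set(np.flatnonzero(pass_quality_frame(calls, base)))
    tight_set = set(np.flatnonzero(pass_quality_frame(calls, tight)))
    assert tight_set <= loose_set
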