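"""Tier-1 candidate screening: quality gates, candidate categories, MAF gates.

The screen proceeds in stages that mirror a clinical filtering cascade:

1. genotype-quality gates (depth, genotype quality, mapping quality,
   site quality, quality-by-depth, VQSR status, alternate-read fraction);
2. restriction to consequence classes with at least moderate predicted
   effect, within panel genes;
3. candidate categorisation from ClinVar/HGMD status, plus novel
   high-confidence protein-truncating variants;
4. a global allele-frequency gate (AF < 1%);
5. an inheritance-mode-aware maximum-subpopulation MAF gate
   (≤ 1e−4 under a dominant context, ≤ 1e−3 under a recessive context).

"Naive" candidates are those surviving stages 1–4: on cohorts carrying
misannotated common "pathogenic" database entries this stage produces an
implausibly high carrier rate (~20%), which stage 5 collapses.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .panel import PanelGene
from .variants import (
    IMPACTFUL_CONSEQUENCES,
    FilterConfig,
    add_max_subpop_maf,
)

__all__ = [
    "CATEGORIES",
    "ScreenResult",
    "pass_quality",
    "pass_quality_frame",
    "categorize_candidate",
    "categorize_frame",
    "frequency_gates",
    "screen_cohort",
]

#: Mutually exclusive candidate categories over retained variants.
CATEGORIES = ("hgmd_only", "clinvar_only", "both", "novel_ptv")


def pass_quality(call, cfg: FilterConfig) -> bool:
    """Genotype-quality gate for a single call (Series/mapping/record).

    Integer thresholds are inclusive (``min_dp=10`` ≡ DP > 9 on integer
    depth); the alternate-read fraction bound is strict.
    """
    return bool(
        call["dp"] >= cfg.min_dp
        and call["qual"] >= cfg.min_qual
        and call["qd"] >= cfg.min_qd
        and call["gq"] >= cfg.min_gq
        and call["mq"] >= cfg.min_mq
        and call["alt_fraction"] > cfg.min_alt_fraction
        and (call["vqsr_pass"] or not cfg.require_vqsr_pass)
    )


def pass_quality_frame(calls: pd.DataFrame, cfg: FilterConfig) -> pd.Series:
    """Vectorised :func:`pass_quality` over a calls DataFrame."""
    ok = (
        (calls["dp"] >= cfg.min_dp)
        & (calls["qual"] >= cfg.min_qual)
        & (calls["qd"] >= cfg.min_qd)
        & (calls["gq"] >= cfg.min_gq)
        & (calls["mq"] >= cfg.min_mq)
        & (calls["alt_fraction"] > cfg.min_alt_fraction)
    )
    if cfg.require_vqsr_pass:
        ok &= calls["vqsr_pass"].astype(bool)
    return ok


def categorize_candidate(site) -> str | None:
    """Candidate category of one site, or None if not a candidate.

    ClinVar P/LP and HGMD DM → ``both``; ClinVar P/LP alone →
    ``clinvar_only``; HGMD DM with ClinVar neither P/LP nor conflicting →
    ``hgmd_only`` (a conflicting ClinVar record blocks candidacy); a
    variant absent from both databases qualifies only as ``novel_ptv``
    when it truncates protein with a high-confidence LOFTEE prediction.
    """
    clinvar, hgmd = site["clinvar"], site["hgmd"]
    clv_plp = clinvar in ("P", "LP")
    dm = hgmd == "DM"
    if clv_plp and dm:
        return "both"
    if clv_plp:
        return "clinvar_only"
    if dm:
        return None if clinvar == "conflicting" else "hgmd_only"
    if clinvar == "absent" and hgmd == "absent":
        if site["consequence"] == "ptv" and site["loftee"] == "HC":
            return "novel_ptv"
    return None


def categorize_frame(sites: pd.DataFrame) -> pd.Series:
    """Vectorised :func:`categorize_candidate`; None encoded as NaN."""
    clv_plp = sites["clinvar"].isin(("P", "LP")).to_numpy()
    dm = (sites["hgmd"] == "DM").to_numpy()
    conflicting = (sites["clinvar"] == "conflicting").to_numpy()
    novel = ((sites["clinvar"] == "absent") & (sites["hgmd"] == "absent")).to_numpy()
    hc_ptv = ((sites["consequence"] == "ptv") & (sites["loftee"] == "HC")).to_numpy()
    out = np.select(
        [
            clv_plp & dm,
            clv_plp,
            dm & ~conflicting,
            novel & hc_ptv,
        ],
        ["both", "clinvar_only", "hgmd_only", "novel_ptv"],
        default=None,
    )
    return pd.Series(out, index=sites.index, dtype=object)


def frequency_gates(site, cfg: FilterConfig) -> tuple[bool, dict[str, bool]]:
    """(global-AF gate, per-inheritance-context subpopulation-MAF gates)."""
    from .variants import max_subpop_maf

    passed_global = float(site["global_af"]) < cfg.global_af_max
    mx = max_subpop_maf(site)
    return passed_global, {
        "dominant": mx <= cfg.dominant_maf_max,
        "recessive": mx <= cfg.recessive_maf_max,
    }


@dataclass
class ScreenResult:
    """Screening output: per-call candidate rows with stage flags.

    ``candidates`` has one row per (sample, variant) in a panel gene with
    columns ``sample_id, variant_key, gene, zygosity, category,
    max_subpop_maf, naive, dominant_ok, recessive_ok, tier1`` —
    ``naive`` marks survival of quality + global AF + category gates;
    ``tier1`` additionally requires the mode-appropriate subpopulation
    gate (or a frequency exemption).
    """

    candidates: pd.DataFrame
    n_calls: int = 0
    n_nonpanel: int = 0
    category_counts: dict = field(default_factory=dict)

    @property
    def naive(self) -> pd.DataFrame:
        return self.candidates[self.candidates["naive"]]

    @property
    def tier1(self) -> pd.DataFrame:
        return self.candidates[self.candidates["tier1"]]

    def carriers(self, stage: str) -> pd.Series:
        """Unique sample ids with ≥1 candidate surviving ``stage``."""
        df = self.naive if stage == "naive" else self.tier1
        return df["sample_id"].drop_duplicates()


_EMPTY_COLS = [
    "sample_id",
    "variant_key",
    "gene",
    "zygosity",
    "category",
    "max_subpop_maf",
    "naive",
    "dominant_ok",
    "recessive_ok",
    "tier1",
]


def screen_cohort(
    calls: pd.DataFrame,
    sites: pd.DataFrame,
    panel: list[PanelGene],
    cfg: FilterConfig | None = None,
    maf_exempt_keys: frozenset[str] = frozenset(),
) -> ScreenResult:
    """Run the tier-1 screening cascade over a cohort.

    ``maf_exempt_keys`` are well-established pathogenic variants exempted
    from the subpopulation MAF gate (they still face quality, category
    and global-AF gates here; genotype-pattern allowlisting is separate).
    Calls in non-panel genes are ignored and counted.
    """
    cfg = cfg or FilterConfig()
    if calls.empty:
        return ScreenResult(pd.DataFrame(columns=_EMPTY_COLS))

    mode_by_gene = {g.symbol: g.inheritance_mode for g in panel}
    sites = add_max_subpop_maf(sites)
    df = calls.merge(sites, on="variant_key", how="left", validate="many_to_one")
    if df["gene"].isna().any():
        missing = df.loc[df["gene"].isna(), "variant_key"].iloc[0]
        raise ValueError(f"call references unannotated variant {missing}")

    in_panel = df["gene"].isin(mode_by_gene)
    n_nonpanel = int((~in_panel).sum())
    df = df[in_panel].copy()
    if df.empty:
        return ScreenResult(pd.DataFrame(columns=_EMPTY_COLS), n_calls=len(calls), n_nonpanel=n_nonpanel)

    quality_ok = pass_quality_frame(df, cfg)
    impactful = df["consequence"].isin(IMPACTFUL_CONSEQUENCES)
    df["category"] = categorize_frame(df)
    global_ok = df["global_af"] < cfg.global_af_max
    df["naive"] = quality_ok & impactful & global_ok & df["category"].notna()

    exempt = df["variant_key"].isin(maf_exempt_keys)
    df["dominant_ok"] = (df["max_subpop_maf"] <= cfg.dominant_maf_max) | exempt
    df["recessive_ok"] = (df["max_subpop_maf"] <= cfg.recessive_maf_max) | exempt

    mode = df["gene"].map(mode_by_gene)
    mode_gate = np.select(
        [
            mode.isin(("AD", "XLD")).to_numpy(),
            mode.isin(("AR", "XLR")).to_numpy(),
            (mode == "AD_AR").to_numpy(),
        ],
        [
            df["dominant_ok"].to_numpy(),
            df["recessive_ok"].to_numpy(),
            (df["dominant_ok"] | df["recessive_ok"]).to_numpy(),
        ],
        default=False,
    )
    df["tier1"] = df["naive"] & mode_gate

    out = df[_EMPTY_COLS].reset_index(drop=True)
    retained = out[out["naive"]]
    counts = retained["category"].value_counts().to_dict()
    return ScreenResult(
        candidates=out,
        n_calls=len(calls),
        n_nonpanel=n_nonpanel,
        category_counts={c: int(counts.get(c, 0)) for c in CATEGORIES},
    )
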