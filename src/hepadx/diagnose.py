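"""Sample-level diagnostic calling.

Turns screened candidates into monogenic diagnoses in three stages:

* **tier-1** — strict-quality candidates classified P/LP, matched against
  the gene's inheritance mode (dominant heterozygous; recessive
  homozygous or unphased compound heterozygous; X-linked hemizygous).
  A single heterozygous P/LP variant in a recessive gene is a carrier
  state, never a diagnosis.
* **tier-2** — a rescue pass re-screening under relaxed quality gates,
  restricted to variants that failed strict quality only; frequency and
  category gates are unchanged.
* **allowlist** — a handful of well-established pathogenic variants with
  population MAF above the gates (HFE C282Y/H63D, SERPINA1 Pi*Z/Pi*S)
  diagnosed by genotype pattern, plus frequency-exempt recessive alleles
  (ABCB4 Ala934Thr, CPT2 Lys414fs) fed back through ordinary matching.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .acmg import CLASSIFICATION_RANK, acmg_classify, is_diagnostic
from .panel import PanelGene
from .screen import ScreenResult, pass_quality_frame, screen_cohort
from .variants import FilterConfig, RELAXED_FILTERS, STRICT_FILTERS

__all__ = [
    "DiagnosticCall",
    "Allowlist",
    "AllowlistVariant",
    "DEFAULT_ALLOWLIST",
    "ConfigError",
    "classify_variants",
    "match_inheritance",
    "tier2_rescue",
    "allowlist_diagnose",
    "run_pipeline",
    "PipelineResult",
    "TALLY_CATEGORIES",
]


class ConfigError(ValueError):
    """Inconsistent pipeline configuration."""


@dataclass(frozen=True)
class DiagnosticCall:
    """One sample-level monogenic diagnosis."""

    sample_id: str
    gene: str
    variant_keys: tuple[str, ...]
    configuration: str  # dominant_het | homozygous | compound_het | hemizygous | allowlist_genotype
    tier: str  # tier1 | tier2 | allowlist
    classification: str  # pathogenic | likely_pathogenic
    phase_known: bool = True

    def __post_init__(self) -> None:
        if self.configuration == "compound_het":
            if len(self.variant_keys) != 2 or len(set(self.variant_keys)) != 2:
                raise ValueError("compound_het requires exactly 2 distinct variant keys")
        elif self.configuration in ("dominant_het", "homozygous", "hemizygous"):
            if len(self.variant_keys) != 1:
                raise ValueError(f"{self.configuration} requires exactly 1 variant key")
        if not is_diagnostic(self.classification):
            raise ValueError("diagnostic calls must be pathogenic or likely_pathogenic")


def classify_variants(tags_by_key: dict[str, frozenset[str]]) -> dict[str, str]:
    """Apply the ACMG-AMP combining engine to per-variant evidence tags."""
    return {k: acmg_classify(v) for k, v in tags_by_key.items()}


# ---------------------------------------------------------------------------
# inheritance matching


def _ordered(qualifying: pd.DataFrame) -> pd.DataFrame:
    """Deterministic tie-break: classification rank desc, subpop MAF asc, key."""
    q = qualifying.copy()
    q["_rank"] = q["classification"].map(CLASSIFICATION_RANK)
    return q.sort_values(
        ["_rank", "max_subpop_maf", "variant_key"], ascending=[False, True, True]
    )


def match_inheritance(
    sample,
    gene: PanelGene,
    qualifying: pd.DataFrame,
    tier: str = "tier1",
    include_unphased: bool = True,
) -> DiagnosticCall | None:
    """Match P/LP variants in one gene against its inheritance mode.

    ``qualifying`` rows carry ``variant_key, zygosity, classification,
    max_subpop_maf, dominant_ok, recessive_ok`` and must all be P/LP in
    ``gene``.  Dual-mode (AD_AR) genes are evaluated dominant-context
    first, then recessive.  Returns None when the genotype configuration
    is insufficient (e.g. a single recessive-gene heterozygote).
    """
    if qualifying.empty:
        return None
    if "gene" in qualifying.columns and qualifying["gene"].nunique() > 1:
        raise ValueError("qualifying variants span multiple genes")
    mode = gene.inheritance_mode
    sample_id = sample["sample_id"]
    sex = sample.get("sex", "unknown") if hasattr(sample, "get") else sample["sex"]

    def _call(cfgn, keys, classification, phase_known=True):
        return DiagnosticCall(
            sample_id=sample_id,
            gene=gene.symbol,
            variant_keys=tuple(keys),
            configuration=cfgn,
            tier=tier,
            classification=classification,
            phase_known=phase_known,
        )

    if mode in ("AD", "XLD", "AD_AR"):
        dom = _ordered(qualifying[qualifying["dominant_ok"]])
        if len(dom):
            best = dom.iloc[0]
            return _call("dominant_het", [best["variant_key"]], best["classification"])
        if mode in ("AD", "XLD"):
            return None

    rec = _ordered(qualifying[qualifying["recessive_ok"]])
    if rec.empty:
        return None

    if mode == "XLR":
        if sex == "male":
            hemi = rec[rec["zygosity"].isin(("hemi", "hom_alt"))]
            if len(hemi):
                best = hemi.iloc[0]
                return _call("hemizygous", [best["variant_key"]], best["classification"])
            return None
        hom = rec[rec["zygosity"] == "hom_alt"]
        if len(hom):
            best = hom.iloc[0]
            return _call("homozygous", [best["variant_key"]], best["classification"])
        return None

    # AR, or AD_AR falling through to the recessive context
    hom = rec[rec["zygosity"] == "hom_alt"]
    if len(hom):
        best = hom.iloc[0]
        return _call("homozygous", [best["variant_key"]], best["classification"])
    hets = rec[rec["zygosity"] == "het"].drop_duplicates(subset="variant_key")
    if len(hets) >= 2 and include_unphased:
        pair = hets.iloc[:2]
        # the pair's class is the weaker of the two alleles' classes
        classification = min(pair["classification"], key=lambda c: CLASSIFICATION_RANK[c])
        return _call(
            "compound_het", sorted(pair["variant_key"]), classification, phase_known=False
        )
    return None


def _calls_from_screen(
    screened: ScreenResult,
    classifications: dict[str, str],
    panel_by_symbol: dict[str, PanelGene],
    sex_by_sample: dict[str, str],
    tier: str,
    candidate_mask_col: str = "tier1",
    include_unphased: bool = True,
    require_rescued: frozenset[str] | None = None,
    exclude_sample_genes: set[tuple[str, str]] | None = None,
) -> list[DiagnosticCall]:
    cand = screened.candidates
    cand = cand[cand[candidate_mask_col]].copy()
    if cand.empty:
        return []
    cand["classification"] = cand["variant_key"].map(classifications)
    cand = cand[cand["classification"].isin(("pathogenic", "likely_pathogenic"))]
    calls: list[DiagnosticCall] = []
    for (sample_id, gene_sym), group in cand.groupby(["sample_id", "gene"], sort=True):
        if exclude_sample_genes and (sample_id, gene_sym) in exclude_sample_genes:
            continue
        sample = {"sample_id": sample_id, "sex": sex_by_sample.get(sample_id, "unknown")}
        call = match_inheritance(
            sample, panel_by_symbol[gene_sym], group, tier=tier, include_unphased=include_unphased
        )
        if call is None:
            continue
        if require_rescued is not None and not set(call.variant_keys) & require_rescued:
            continue
        calls.append(call)
    return calls


# ---------------------------------------------------------------------------
# tier-2 rescue


def tier2_rescue(
    calls: pd.DataFrame,
    sites: pd.DataFrame,
    panel: list[PanelGene],
    strict_cfg: FilterConfig,
    relaxed_cfg: FilterConfig,
    classifications: dict[str, str],
    manifest: pd.DataFrame,
    maf_exempt_keys: frozenset[str] = frozenset(),
    tier1_calls: list[DiagnosticCall] = (),
    include_unphased: bool = True,
) -> list[DiagnosticCall]:
    """Rescue P/LP diagnoses lost to strict quality gates.

    Re-screens under ``relaxed_cfg``; only genotype configurations that
    include at least one variant failing strict quality (while passing
    relaxed) yield new calls, and sample×gene pairs already diagnosed at
    tier-1 are skipped.  Frequency and category gates are those of the
    strict pass — only quality is relaxed.
    """
    if not relaxed_cfg.no_stricter_than(strict_cfg):
        raise ConfigError("relaxed config is stricter than the strict config in some field")
    # quality relaxes; frequency gates must be identical between regimes
    for f in ("global_af_max", "dominant_maf_max", "recessive_maf_max"):
        if getattr(relaxed_cfg, f) != getattr(strict_cfg, f):
            raise ConfigError(f"tier-2 rescue must not alter frequency gate {f}")

    strict_q = pass_quality_frame(calls, strict_cfg)
    relaxed_q = pass_quality_frame(calls, relaxed_cfg)
    rescued_keys = frozenset(calls.loc[~strict_q & relaxed_q, "variant_key"])
    if not rescued_keys:
        return []

    screened = screen_cohort(calls, sites, panel, relaxed_cfg, maf_exempt_keys)
    panel_by_symbol = {g.symbol: g for g in panel}
    sex_by_sample = dict(zip(manifest["sample_id"], manifest["sex"]))
    done = {(c.sample_id, c.gene) for c in tier1_calls}
    return _calls_from_screen(
        screened,
        classifications,
        panel_by_symbol,
        sex_by_sample,
        tier="tier2",
        require_rescued=rescued_keys,
        exclude_sample_genes=done,
        include_unphased=include_unphased,
    )


# ---------------------------------------------------------------------------
# allowlist


@dataclass(frozen=True)
class AllowlistVariant:
    gene: str
    name: str
    variant_key: str


#: Table-style tally rows for the high-MAF allowlist genotypes.
TALLY_CATEGORIES = (
    "Homozygous C282Y",
    "Homozygous H63D",
    "Compound C282Y/H63D",
    "C282Y or H63D/PTV",
    "Pi ZZ",
    "Pi MZ",
    "Pi SS",
    "Pi MS",
    "Pi Z/Pi S",
)

#: Genotype categories that constitute a diagnosis by themselves.
DIAGNOSTIC_CATEGORIES = frozenset(
    {"Homozygous C282Y", "C282Y or H63D/PTV", "Pi ZZ"}
)


@dataclass(frozen=True)
class Allowlist:
    """Known-pathogenic common variants and their genotype rules."""

    variants: tuple[AllowlistVariant, ...]
    #: variants exempt from the subpopulation MAF gate but diagnosed
    #: through ordinary inheritance matching (not genotype patterns)
    maf_exempt: tuple[AllowlistVariant, ...] = ()

    def key(self, gene: str, name: str) -> str:
        for v in self.variants + self.maf_exempt:
            if v.gene == gene and v.name == name:
                return v.variant_key
        raise KeyError(f"allowlist variant {gene} {name} not declared")

    @property
    def pattern_keys(self) -> frozenset[str]:
        return frozenset(v.variant_key for v in self.variants)

    @property
    def maf_exempt_keys(self) -> frozenset[str]:
        return frozenset(v.variant_key for v in self.maf_exempt)


#: GRCh37-style keys for the canonical high-MAF liver alleles.
DEFAULT_ALLOWLIST = Allowlist(
    variants=(
        AllowlistVariant("HFE", "C282Y", "6:26093141:G:A"),
        AllowlistVariant("HFE", "H63D", "6:26091179:C:G"),
        AllowlistVariant("SERPINA1", "PiZ", "14:94844947:C:T"),
        AllowlistVariant("SERPINA1", "PiS", "14:94847262:A:T"),
    ),
    maf_exempt=(
        AllowlistVariant("ABCB4", "Ala934Thr", "7:87031395:C:T"),
        AllowlistVariant("CPT2", "Lys414fs", "1:53676638:CAA:C"),
    ),
)


def _zyg(genos: dict[str, str], key: str) -> str | None:
    return genos.get(key)


def allowlist_diagnose(
    calls: pd.DataFrame,
    sites: pd.DataFrame,
    manifest: pd.DataFrame,
    allowlist: Allowlist = DEFAULT_ALLOWLIST,
    cfg: FilterConfig | None = None,
    classifications: dict[str, str] | None = None,
) -> tuple[pd.DataFrame, list[DiagnosticCall]]:
    """Match per-sample genotype patterns at the allowlisted loci.

    Returns a per-cohort tally table over the named genotype categories
    and the diagnostic calls for the categories that establish a
    diagnosis on genotype alone (homozygous C282Y, C282Y-or-H63D with a
    second HFE P/LP or truncating allele, Pi ZZ).  Compound C282Y/H63D,
    Pi MZ/MS/SS/ZS and homozygous H63D are tallied as carrier states.
    Only genotype calls passing the quality gates are considered.
    """
    cfg = cfg or STRICT_FILTERS
    classifications = classifications or {}
    c282y = allowlist.key("HFE", "C282Y")
    h63d = allowlist.key("HFE", "H63D")
    piz = allowlist.key("SERPINA1", "PiZ")
    pis = allowlist.key("SERPINA1", "PiS")

    if calls.empty:
        good = calls
    else:
        good = calls[pass_quality_frame(calls, cfg)]
    site_gene = dict(zip(sites["variant_key"], sites["gene"])) if len(sites) else {}
    site_cons = dict(zip(sites["variant_key"], sites["consequence"])) if len(sites) else {}
    site_loftee = dict(zip(sites["variant_key"], sites["loftee"])) if len(sites) else {}

    hfe_genes = {"HFE"}
    relevant = good[
        good["variant_key"].isin(allowlist.pattern_keys)
        | good["variant_key"].map(site_gene).isin(hfe_genes)
    ]

    records: list[dict] = []
    diag_calls: list[DiagnosticCall] = []
    for sample_id, group in relevant.groupby("sample_id", sort=True):
        genos = dict(zip(group["variant_key"], group["zygosity"]))
        cats: list[tuple[str, tuple[str, ...]]] = []

        # --- HFE hemochromatosis patterns
        zc, zh = _zyg(genos, c282y), _zyg(genos, h63d)
        second = [
            k
            for k in genos
            if k not in (c282y, h63d)
            and site_gene.get(k) == "HFE"
            and (
                (site_cons.get(k) == "ptv" and site_loftee.get(k) == "HC")
                or classifications.get(k) in ("pathogenic", "likely_pathogenic")
            )
        ]
        if zc == "hom_alt":
            cats.append(("Homozygous C282Y", (c282y,)))
        elif (zc or zh) and second:
            primary = c282y if zc else h63d
            cats.append(("C282Y or H63D/PTV", (primary, sorted(second)[0])))
        elif zh == "hom_alt":
            cats.append(("Homozygous H63D", (h63d,)))
        elif zc == "het" and zh == "het":
            cats.append(("Compound C282Y/H63D", (c282y, h63d)))

        # --- SERPINA1 alpha-1 antitrypsin patterns
        zz, zs = _zyg(genos, piz), _zyg(genos, pis)
        if zz == "hom_alt":
            cats.append(("Pi ZZ", (piz,)))
        elif zs == "hom_alt":
            cats.append(("Pi SS", (pis,)))
        elif zz == "het" and zs == "het":
            cats.append(("Pi Z/Pi S", (piz, pis)))
        elif zz == "het":
            cats.append(("Pi MZ", (piz,)))
        elif zs == "het":
            cats.append(("Pi MS", (pis,)))

        for cat, keys in cats:
            records.append({"sample_id": sample_id, "category": cat})
            if cat in DIAGNOSTIC_CATEGORIES:
                gene = "HFE" if "C282Y" in cat or "H63D" in cat else "SERPINA1"
                diag_calls.append(
                    DiagnosticCall(
                        sample_id=sample_id,
                        gene=gene,
                        variant_keys=tuple(keys),
                        configuration="allowlist_genotype",
                        tier="allowlist",
                        classification="pathogenic",
                        phase_known=len(keys) == 1,
                    )
                )

    per_sample = pd.DataFrame(records, columns=["sample_id", "category"])
    cohort = dict(zip(manifest["sample_id"], manifest["cohort"]))
    per_sample["cohort"] = per_sample["sample_id"].map(cohort)
    tally = (
        per_sample.groupby(["category", "cohort"]).size().unstack(fill_value=0)
        if len(per_sample)
        else pd.DataFrame()
    )
    tally = tally.reindex(index=list(TALLY_CATEGORIES), fill_value=0)
    for c in ("HC", "CKD", "CLD"):
        if c not in tally.columns:
            tally[c] = 0
    tally = tally[["HC", "CKD", "CLD"]].fillna(0).astype(int)
    return tally, diag_calls


# ---------------------------------------------------------------------------
# pipeline


@dataclass
class PipelineResult:
    """End-to-end pipeline output."""

    calls: list[DiagnosticCall]
    stage_counts: pd.DataFrame  # cohort × {n, naive, tier1, tier2, allowlist, diagnosed}
    tally: pd.DataFrame  # allowlist genotype tallies (category × cohort)
    gene_counts: pd.DataFrame  # gene × cohort diagnosis counts
    category_counts: dict

    def calls_frame(self) -> pd.DataFrame:
        rows = [
            {
                "sample_id": c.sample_id,
                "gene": c.gene,
                "variant_keys": ",".join(c.variant_keys),
                "configuration": c.configuration,
                "tier": c.tier,
                "classification": c.classification,
                "phase_known": c.phase_known,
            }
            for c in self.calls
        ]
        return pd.DataFrame(
            rows,
            columns=[
                "sample_id",
                "gene",
                "variant_keys",
                "configuration",
                "tier",
                "classification",
                "phase_known",
            ],
        )

    def diagnosed_samples(self, tiers: tuple[str, ...] = ("tier1", "tier2", "allowlist")) -> set[str]:
        return {c.sample_id for c in self.calls if c.tier in tiers}

    def diagnostic_rates(self) -> pd.DataFrame:
        out = self.stage_counts.copy()
        out["rate_percent"] = 100.0 * out["diagnosed"] / out["n"]
        return out


def run_pipeline(
    calls: pd.DataFrame,
    sites: pd.DataFrame,
    manifest: pd.DataFrame,
    panel: list[PanelGene],
    acmg_tags: dict[str, frozenset[str]],
    strict_cfg: FilterConfig | None = None,
    relaxed_cfg: FilterConfig | None = None,
    allowlist: Allowlist | None = DEFAULT_ALLOWLIST,
    skip_tier2: bool = False,
    include_unphased: bool = True,
) -> PipelineResult:
    """Run the full diagnostic cascade: tier-1 → tier-2 rescue → allowlist.

    A sample's diagnostic status is the union over stages; stage
    provenance is retained per call.  Allowlisted pattern loci (the
    high-MAF HFE/SERPINA1 alleles) never enter tier-1/2 matching, and
    MAF-exempt allowlist alleles bypass the subpopulation gate there.
    """
    strict_cfg = strict_cfg or STRICT_FILTERS
    relaxed_cfg = relaxed_cfg or RELAXED_FILTERS
    panel_by_symbol = {g.symbol: g for g in panel}
    sex_by_sample = dict(zip(manifest["sample_id"], manifest["sex"]))
    classifications = classify_variants(acmg_tags)

    pattern_keys = allowlist.pattern_keys if allowlist else frozenset()
    exempt_keys = allowlist.maf_exempt_keys if allowlist else frozenset()
    core_calls = calls[~calls["variant_key"].isin(pattern_keys)] if len(calls) else calls

    screened = screen_cohort(core_calls, sites, panel, strict_cfg, exempt_keys)
    tier1_calls = _calls_from_screen(
        screened,
        classifications,
        panel_by_symbol,
        sex_by_sample,
        tier="tier1",
        include_unphased=include_unphased,
    )

    tier2_calls: list[DiagnosticCall] = []
    if not skip_tier2:
        tier2_calls = tier2_rescue(
            core_calls,
            sites,
            panel,
            strict_cfg,
            relaxed_cfg,
            classifications,
            manifest,
            exempt_keys,
            tier1_calls,
            include_unphased=include_unphased,
        )

    if allowlist is not None:
        tally, allow_calls = allowlist_diagnose(
            calls, sites, manifest, allowlist, strict_cfg, classifications
        )
    else:
        tally = pd.DataFrame(
            0, index=list(TALLY_CATEGORIES), columns=["HC", "CKD", "CLD"], dtype=int
        )
        allow_calls = []

    all_calls = tier1_calls + tier2_calls + allow_calls

    cohort_of = dict(zip(manifest["sample_id"], manifest["cohort"]))
    cohorts = ["HC", "CKD", "CLD"]
    counts = pd.DataFrame(index=cohorts, dtype=float)
    counts["n"] = [int((manifest["cohort"] == c).sum()) for c in cohorts]

    def _carrier_count(samples: set[str] | pd.Series) -> list[int]:
        by = pd.Series([cohort_of.get(s) for s in samples])
        return [int((by == c).sum()) for c in cohorts]

    counts["naive"] = _carrier_count(set(screened.carriers("naive")))
    counts["tier1"] = _carrier_count({c.sample_id for c in tier1_calls})
    counts["tier2"] = _carrier_count({c.sample_id for c in tier2_calls})
    counts["allowlist"] = _carrier_count({c.sample_id for c in allow_calls})
    counts["diagnosed"] = _carrier_count({c.sample_id for c in all_calls})
    counts = counts.astype(int)
    counts.index.name = "cohort"

    gene_rows = [
        {"gene": c.gene, "cohort": cohort_of.get(c.sample_id, "?")} for c in all_calls
    ]
    gene_counts = (
        pd.DataFrame(gene_rows).groupby(["gene", "cohort"]).size().unstack(fill_value=0)
        if gene_rows
        else pd.DataFrame()
    )

    return PipelineResult(
        calls=all_calls,
        stage_counts=counts,
        tally=tally,
        gene_counts=gene_counts,
        category_counts=screened.category_counts,
    )
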