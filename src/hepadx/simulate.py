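"""Synthetic three-cohort fixture generator with planted truth.

Emulates the study conditions of a gene-panel exome diagnostic screen:
a healthy-control cohort (n=7856), a chronic-kidney-disease cohort
(n=2187) and a chronic-liver-disease cohort (n=758), each carrying

* benign background variation in panel genes (passes quality, fails the
  candidate-category gate);
* misannotated common "pathogenic" decoys — database P/DM entries with
  global AF below 1% but subpopulation MAF far above the inheritance
  gates — planted until the naive candidate carrier rate reaches the
  ~20% level the strict subpopulation-MAF filter then collapses;
* tier-1 truth: P/LP carriers (51 HC / 25 CKD / 24 CLD) whose genotype
  configuration matches their gene's inheritance mode and passes every
  strict gate;
* tier-2 truth (CLD only): 16 diagnostic variants in 14 patients, each
  degraded in exactly one quality metric to fall between the relaxed and
  strict thresholds;
* allowlist genotypes: high-MAF HFE/SERPINA1 patterns per the configured
  per-cohort category counts (diagnostic genotypes in CLD by default,
  carrier genotypes in all cohorts).

Every planted diagnostic is recorded in a truth set that the pipeline
must recover exactly.  Generation is a pure function of (config, seed).
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, model_validator

from .acmg import acmg_classify
from .diagnose import DEFAULT_ALLOWLIST, Allowlist
from .panel import PanelGene
from .screen import pass_quality_frame
from .variants import (
    AF_COLUMNS,
    CALL_COLUMNS,
    RELAXED_FILTERS,
    SITE_COLUMNS,
    STRICT_FILTERS,
    write_acmg_tags,
    write_manifest,
    write_variant_table,
)
from .panel import write_panel

__all__ = ["GeneratorConfig", "CohortData", "generate_panel", "generate_cohort", "write_fixture"]

_BASES = ("A", "C", "G", "T")

#: Printed Table-1-style allowlist genotype counts, diagnostic rows in CLD only.
_DEFAULT_ALLOWLIST_PLANTED = {
    "HC": {
        "Homozygous H63D": 9,
        "Compound C282Y/H63D": 60,
        "Pi MZ": 138,
        "Pi MS": 482,
        "Pi SS": 1,
        "Pi Z/Pi S": 7,
    },
    "CKD": {
        "Homozygous H63D": 3,
        "Compound C282Y/H63D": 11,
        "Pi MZ": 49,
        "Pi MS": 92,
        "Pi Z/Pi S": 5,
    },
    "CLD": {
        "Homozygous C282Y": 1,
        "C282Y or H63D/PTV": 1,
        "Pi ZZ": 3,
        "Compound C282Y/H63D": 2,
        "Pi MZ": 15,
        "Pi MS": 32,
    },
}

#: Diagnosed / undiagnosed CLD metadata marginals (clinical subgroup table).
_DEFAULT_TABLE2 = {
    "sex": {"no_dx": {"male": 328, "female": 387}, "dx": {"male": 23, "female": 20}},
    "age_group": {
        "no_dx": {"0-21": 232, "22-44": 141, "45-64": 218, "65plus": 124},
        "dx": {"0-21": 23, "22-44": 9, "45-64": 8, "65plus": 3},
    },
    "race_eth": {
        "no_dx": {"White": 349, "Hispanic": 128, "Black": 88, "Asian": 57, "Other": 93},
        "dx": {"White": 18, "Hispanic": 8, "Black": 7, "Asian": 4, "Other": 6},
    },
    "primary_dx": {
        "no_dx": {
            "Metabolic_Congenital": 7,
            "NAFLD_NASH": 174,
            "AIH_PBC_PSC": 122,
            "Abnormal_LFT": 47,
            "Biliary_Atresia": 73,
            "Other": 292,
        },
        "dx": {
            "Metabolic_Congenital": 10,
            "NAFLD_NASH": 8,
            "AIH_PBC_PSC": 6,
            "Abnormal_LFT": 5,
            "Biliary_Atresia": 3,
            "Other": 11,
        },
    },
}


class GeneratorConfig(BaseModel):
    """Planted-truth and decoy parameters for the synthetic cohorts."""

    cohort_sizes: dict[str, int] = Field(
        default_factory=lambda: {"HC": 7856, "CKD": 2187, "CLD": 758}
    )
    tier1_carriers: dict[str, int] = Field(
        default_factory=lambda: {"HC": 51, "CKD": 25, "CLD": 24}
    )
    #: naive-stage candidate carriers per cohort (planted decoys top up to these)
    naive_carriers: dict[str, int] = Field(
        default_factory=lambda: {"HC": 1567, "CKD": 416, "CLD": 159}
    )
    tier2_n_variants: int = 16
    tier2_n_samples: int = 14
    allowlist_planted: dict[str, dict[str, int]] = Field(
        default_factory=lambda: {c: dict(v) for c, v in _DEFAULT_ALLOWLIST_PLANTED.items()}
    )
    #: fraction of planted P/LP variants that are protein-truncating (78/112)
    ptv_fraction: float = 78 / 112
    n_decoy_sites: int = 30
    decoy_subpop_af_range: tuple[float, float] = (0.005, 0.05)
    decoy_global_af_range: tuple[float, float] = (0.002, 0.0095)
    background_per_sample: int = 50
    n_background_sites: int = 4000
    panel_composition: dict[str, int] = Field(
        default_factory=lambda: {"AR": 363, "XLR": 15, "AD": 61, "XLD": 1, "AD_AR": 62}
    )
    tag_frequencies: dict[str, float] = Field(
        default_factory=lambda: {
            "hepatomegaly": 0.47,
            "metabolic": 0.25,
            "fibrosis_cirrhosis": 0.25,
            "elevated_transaminase": 0.20,
            "cholestasis": 0.19,
        }
    )
    primary_liver_fraction: float = 193 / 502
    table2_marginals: dict = Field(default_factory=lambda: json.loads(json.dumps(_DEFAULT_TABLE2)))

    @model_validator(mode="after")
    def _check(self) -> "GeneratorConfig":
        for cohort, n in self.cohort_sizes.items():
            k1 = self.tier1_carriers.get(cohort, 0)
            naive = self.naive_carriers.get(cohort, 0)
            planted_allow = sum(self.allowlist_planted.get(cohort, {}).values())
            extra = self.tier2_n_samples if cohort == "CLD" else 0
            if k1 > n:
                raise ValueError(f"{cohort}: tier-1 carriers {k1} exceed cohort size {n}")
            if naive < k1:
                raise ValueError(f"{cohort}: naive carriers {naive} below tier-1 carriers {k1}")
            if naive + extra + planted_allow > n:
                raise ValueError(f"{cohort}: planted samples exceed cohort size {n}")
        if not self.tier2_n_samples <= self.tier2_n_variants <= 2 * self.tier2_n_samples:
            raise ValueError("tier2_n_variants must lie in [n_samples, 2*n_samples]")
        if not 0.0 <= self.ptv_fraction <= 1.0:
            raise ValueError("ptv_fraction must be in [0, 1]")
        for tag, f in self.tag_frequencies.items():
            if not 0.0 <= f <= 1.0:
                raise ValueError(f"tag frequency {tag}={f} outside [0, 1]")
        return self

    @property
    def panel_size(self) -> int:
        return sum(self.panel_composition.values())


@dataclass
class CohortData:
    """Generated fixture: manifest, calls, site annotations, evidence, truth."""

    manifest: pd.DataFrame
    calls: pd.DataFrame
    sites: pd.DataFrame
    acmg_tags: dict[str, frozenset[str]]
    truth: list[dict]


# ---------------------------------------------------------------------------
# panel

_RESERVED = {
    "HFE": ("6", "AR"),
    "SERPINA1": ("14", "AR"),
    "ABCB4": ("7", "AR"),
    "CPT2": ("1", "AR"),
}


def generate_panel(cfg: GeneratorConfig, seed: int = 0) -> list[PanelGene]:
    """Generate a synthetic liver panel matching the configured composition.

    Gene symbols are synthetic (LIVG0001…) except the four allowlist
    genes (HFE, SERPINA1, ABCB4, CPT2), seated as AR genes when the AR
    count allows.  Phenotype tags hit the configured frequencies exactly
    (round(f·N) genes per tag); pLI is drawn Beta(5,1) for dominant-only,
    Beta(1,5) for recessive-only and Beta(2,2) for dual-mode genes, and
    missense Z analogously shifted, so the dominant/recessive constraint
    contrast points the expected way.
    """
    rng = np.random.default_rng(seed)
    modes: list[str] = []
    for mode in ("AR", "XLR", "AD", "XLD", "AD_AR"):
        modes.extend([mode] * cfg.panel_composition.get(mode, 0))
    n = len(modes)
    if n != cfg.panel_size:
        raise ValueError("panel composition does not sum to panel size")

    reserve = dict(_RESERVED) if cfg.panel_composition.get("AR", 0) >= len(_RESERVED) else {}
    symbols: list[str] = []
    chroms: list[str] = []
    reserved_iter = iter(reserve.items())
    synth = itertools.count(1)
    for mode in modes:
        if mode == "AR":
            item = next(reserved_iter, None)
            if item is not None:
                sym, (chrom, _) = item
                symbols.append(sym)
                chroms.append(chrom)
                continue
        symbols.append(f"LIVG{next(synth):04d}")
        chroms.append("X" if mode in ("XLD", "XLR") else str(rng.integers(1, 23)))

    tag_members: dict[int, set[str]] = {i: set() for i in range(n)}
    for tag in sorted(cfg.tag_frequencies):
        k = int(round(cfg.tag_frequencies[tag] * n))
        for i in rng.choice(n, size=k, replace=False):
            tag_members[int(i)].add(tag)
    n_primary = int(round(cfg.primary_liver_fraction * n))
    primary = set(int(i) for i in rng.choice(n, size=n_primary, replace=False))

    genes: list[PanelGene] = []
    for i, mode in enumerate(modes):
        if mode in ("AD", "XLD"):
            pli, mz = rng.beta(5, 1), rng.normal(2.5, 1.0)
        elif mode in ("AR", "XLR"):
            pli, mz = rng.beta(1, 5), rng.normal(0.0, 1.0)
        else:
            pli, mz = rng.beta(2, 2), rng.normal(1.0, 1.0)
        genes.append(
            PanelGene(
                symbol=symbols[i],
                chrom=chroms[i],
                inheritance_mode=mode,
                phenotype_tags=frozenset(tag_members[i]),
                primary_liver=i in primary,
                pli=float(pli),
                mis_z=float(mz),
            )
        )
    return genes


# ---------------------------------------------------------------------------
# helpers


class _KeyFactory:
    """Unique, pre-normalised SNV/indel keys laid out per gene."""

    def __init__(self, panel: list[PanelGene], rng: np.random.Generator):
        self.base = {g.symbol: (g.chrom, 100_000 + 50_000 * i) for i, g in enumerate(panel)}
        self.offset: dict[str, int] = {}
        self.rng = rng

    def snv(self, gene: str) -> str:
        chrom, base = self.base[gene]
        off = self.offset.get(gene, 0) + self.rng.integers(1, 10)
        self.offset[gene] = int(off)
        ref, alt = self.rng.choice(4, size=2, replace=False)
        return f"{chrom}:{base + off}:{_BASES[ref]}:{_BASES[alt]}"


def _proportional_counts(weights: dict[str, int | float], n: int) -> dict[str, int]:
    """Integer apportionment of n among levels by largest remainder."""
    total = float(sum(weights.values()))
    raw = {k: n * v / total for k, v in weights.items()}
    out = {k: int(np.floor(v)) for k, v in raw.items()}
    rem = n - sum(out.values())
    for k in sorted(raw, key=lambda k: raw[k] - np.floor(raw[k]), reverse=True)[:rem]:
        out[k] += 1
    return out


def _assign_levels(n: int, counts: dict[str, int], rng: np.random.Generator) -> np.ndarray:
    """Random permutation of levels repeated per exact (or apportioned) counts."""
    if sum(counts.values()) != n:
        counts = _proportional_counts(counts, n)
    levels = np.concatenate([np.repeat(k, v) for k, v in sorted(counts.items())])
    return rng.permutation(levels)


def _good_quality(rng: np.random.Generator, zygosity: str) -> dict:
    alt = rng.uniform(0.9, 1.0) if zygosity == "hom_alt" else rng.uniform(0.35, 0.6)
    return {
        "dp": int(rng.integers(20, 80)),
        "gq": int(rng.integers(60, 100)),
        "mq": float(np.round(rng.uniform(55, 70), 2)),
        "qd": float(np.round(rng.uniform(5, 20), 2)),
        "qual": float(np.round(rng.uniform(200, 900), 1)),
        "vqsr_pass": True,
        "alt_fraction": float(np.round(alt, 3)),
    }


_DEGRADABLE = ("dp", "gq", "qual", "qd", "alt_fraction", "vqsr_pass")


def _degrade(metrics: dict, metric: str) -> dict:
    """Push one quality metric between the relaxed and strict thresholds."""
    out = dict(metrics)
    if metric == "dp":
        out["dp"] = 6  # relaxed >=4, strict >=10
    elif metric == "gq":
        out["gq"] = 15  # relaxed >=10, strict >=20
    elif metric == "qual":
        out["qual"] = 40.0  # relaxed >=30, strict >=50
    elif metric == "qd":
        out["qd"] = 1.5  # relaxed >=1, strict >=2
    elif metric == "alt_fraction":
        out["alt_fraction"] = 0.22  # relaxed >0.20, strict >0.25
    elif metric == "vqsr_pass":
        out["vqsr_pass"] = False  # relaxed does not require PASS
    return out


def _blank_site(key: str, gene: str, consequence: str) -> dict:
    site = {c: 0.0 for c in AF_COLUMNS}
    site.update(
        variant_key=key,
        gene=gene,
        consequence=consequence,
        global_af=0.0,
        clinvar="absent",
        hgmd="absent",
        loftee="NA",
        cadd=np.nan,
    )
    return site


# ---------------------------------------------------------------------------
# cohort generation


def generate_cohort(
    cfg: GeneratorConfig,
    panel: list[PanelGene],
    seed: int = 0,
    allowlist: Allowlist = DEFAULT_ALLOWLIST,
    validate: bool = True,
) -> CohortData:
    """Generate manifest, calls, sites, evidence tags and the truth set."""
    rng = np.random.default_rng(np.random.SeedSequence([seed, 7]))
    keys = _KeyFactory(panel, rng)
    by_symbol = {g.symbol: g for g in panel}
    # HFE/SERPINA1 diagnoses go through the allowlist stage, never tier-1/2
    truth_pool = [g for g in panel if g.symbol not in ("HFE", "SERPINA1")]

    site_rows: list[dict] = []
    call_rows: list[dict] = []
    acmg_tags: dict[str, frozenset[str]] = {}
    truth: list[dict] = []

    # ---- sample ids and per-cohort special-role slices
    sample_ids = {
        c: [f"{c}{i:06d}" for i in range(1, n + 1)] for c, n in cfg.cohort_sizes.items()
    }
    roles: dict[str, dict[str, list[str]]] = {}
    for cohort, ids in sample_ids.items():
        perm = rng.permutation(len(ids))
        k1 = cfg.tier1_carriers.get(cohort, 0)
        k2 = cfg.tier2_n_samples if cohort == "CLD" else 0
        planted = cfg.allowlist_planted.get(cohort, {})
        diag_cats = ("Homozygous C282Y", "C282Y or H63D/PTV", "Pi ZZ")
        k_allow_diag = sum(planted.get(c, 0) for c in diag_cats)
        # C282Y-or-H63D/PTV samples carry a rare naive-stage candidate too
        extra_naive = planted.get("C282Y or H63D/PTV", 0)
        k_decoy = max(cfg.naive_carriers.get(cohort, 0) - k1 - extra_naive, 0)
        k_carrier = sum(v for c, v in planted.items() if c not in diag_cats)
        cuts = np.cumsum([k1, k2, k_allow_diag, k_decoy, k_carrier])
        idx = [perm[a:b] for a, b in zip([0, *cuts[:-1]], cuts)]
        roles[cohort] = {
            "tier1": [ids[i] for i in idx[0]],
            "tier2": [ids[i] for i in idx[1]],
            "allow_diag": [ids[i] for i in idx[2]],
            "decoy": [ids[i] for i in idx[3]],
            "allow_carrier": [ids[i] for i in idx[4]],
        }

    # ---- manifest (CLD metadata correlated with diagnosis status)
    manifest_frames = []
    for cohort, ids in sample_ids.items():
        n = len(ids)
        df = pd.DataFrame({"sample_id": ids, "cohort": cohort})
        if cohort == "CLD":
            diagnosed = set(
                roles[cohort]["tier1"] + roles[cohort]["tier2"] + roles[cohort]["allow_diag"]
            )
            is_dx = df["sample_id"].isin(diagnosed).to_numpy()
            for field_name in ("sex", "age_group", "race_eth", "primary_dx"):
                marg = cfg.table2_marginals[field_name]
                col = np.empty(n, dtype=object)
                col[is_dx] = _assign_levels(int(is_dx.sum()), marg["dx"], rng)
                col[~is_dx] = _assign_levels(int((~is_dx).sum()), marg["no_dx"], rng)
                df[field_name] = col
        else:
            df["sex"] = _assign_levels(n, {"male": 1, "female": 1}, rng)
            df["age_group"] = _assign_levels(n, {"0-21": 1, "22-44": 2, "45-64": 2, "65plus": 1}, rng)
            df["race_eth"] = _assign_levels(
                n, {"White": 5, "Hispanic": 2, "Black": 1, "Asian": 1, "Other": 1}, rng
            )
            df["primary_dx"] = "NA"
        manifest_frames.append(df)
    manifest = pd.concat(manifest_frames, ignore_index=True)
    sex_of = dict(zip(manifest["sample_id"], manifest["sex"]))

    # ---- background sites (benign: never a candidate category)
    bg_keys: list[str] = []
    bg_gene_pool = [g.symbol for g in panel]
    for _ in range(cfg.n_background_sites):
        gene = bg_gene_pool[int(rng.integers(len(bg_gene_pool)))]
        cons = ("missense", "synonymous", "other", "ptv")[
            int(rng.choice(4, p=[0.5, 0.3, 0.15, 0.05]))
        ]
        site = _blank_site(keys.snv(gene), gene, cons)
        if cons == "ptv":
            site["loftee"] = "LC"  # low-confidence truncations are screened out
        if rng.random() < 0.3:
            site["clinvar"] = "other"
        site["global_af"] = float(np.round(rng.uniform(0, 0.3), 6))
        pop = AF_COLUMNS[int(rng.integers(len(AF_COLUMNS)))]
        site[pop] = float(np.round(site["global_af"] * rng.uniform(0.5, 2.0), 6))
        site["cadd"] = float(np.round(rng.uniform(0, 25), 2))
        bg_keys.append(site["variant_key"])
        site_rows.append(site)

    # ---- tier-1 truth
    def plant_variant(
        sample_id: str,
        gene: PanelGene,
        zygosity: str,
        subpop_maf: float,
        degrade_metric: str | None = None,
    ) -> str:
        key = keys.snv(gene.symbol)
        is_ptv = rng.random() < cfg.ptv_fraction
        if is_ptv:
            site = _blank_site(key, gene.symbol, "ptv")
            site["loftee"] = "HC"
            tags = ("PVS1", "PM2") if rng.random() < 0.5 else ("PVS1", "PM2", "PP5")
        else:
            site = _blank_site(key, gene.symbol, "missense")
            site["clinvar"], site["hgmd"] = (
                ("P", "DM"),
                ("LP", "absent"),
                ("absent", "DM"),
            )[int(rng.integers(3))]
            tags = ("PS1", "PM2") if rng.random() < 0.7 else ("PS1", "PS3", "PM2")
        if subpop_maf > 0:
            pop = AF_COLUMNS[int(rng.integers(len(AF_COLUMNS)))]
            site[pop] = subpop_maf
            site["global_af"] = float(np.round(subpop_maf / 2, 8))
        site["cadd"] = float(np.round(rng.uniform(20, 45), 2))
        site_rows.append(site)
        acmg_tags[key] = frozenset(tags)
        metrics = _good_quality(rng, zygosity)
        if degrade_metric:
            metrics = _degrade(metrics, degrade_metric)
        call_rows.append({"sample_id": sample_id, "variant_key": key, "zygosity": zygosity, **metrics})
        return key

    def plant_config(sample_id: str, gene: PanelGene, tier: str, degrade: bool = False, force_pair: bool = False):
        mode = gene.inheritance_mode
        male = sex_of[sample_id] == "male"
        deg = (lambda: _DEGRADABLE[int(rng.integers(len(_DEGRADABLE)))]) if degrade else (lambda: None)
        if mode in ("AD", "XLD"):
            maf = float(rng.choice([0.0, 5e-5]))
            k = plant_variant(sample_id, gene, "het", maf, deg())
            config, ks = "dominant_het", [k]
        elif mode == "XLR":
            zyg = "hemi" if male else "hom_alt"
            k = plant_variant(sample_id, gene, zyg, float(rng.choice([0.0, 5e-4])), deg())
            config, ks = ("hemizygous" if male else "homozygous"), [k]
        else:  # AR or AD_AR
            recessive_maf = 5e-4 if mode == "AD_AR" else float(rng.choice([0.0, 5e-4]))
            if mode == "AD_AR" and not force_pair and rng.random() < 0.5:
                k = plant_variant(sample_id, gene, "het", 5e-5, deg())
                config, ks = "dominant_het", [k]
            elif not force_pair and rng.random() < 0.5:
                k = plant_variant(sample_id, gene, "hom_alt", recessive_maf, deg())
                config, ks = "homozygous", [k]
            else:
                k1 = plant_variant(sample_id, gene, "het", recessive_maf, deg())
                k2 = plant_variant(sample_id, gene, "het", recessive_maf, deg())
                config, ks = "compound_het", sorted([k1, k2])
        classification = min(
            (acmg_classify(acmg_tags[k]) for k in ks),
            key=lambda c: {"pathogenic": 1, "likely_pathogenic": 0}.get(c, -1),
        )
        truth.append(
            {
                "sample_id": sample_id,
                "gene": gene.symbol,
                "variant_keys": ks,
                "configuration": config,
                "tier": tier,
                "classification": classification,
            }
        )

    for cohort in cfg.cohort_sizes:
        for sid in roles[cohort]["tier1"]:
            gene = truth_pool[int(rng.integers(len(truth_pool)))]
            plant_config(sid, gene, "tier1")

    # ---- tier-2 rescue truth (CLD): pairs use two degraded variants
    tier2_samples = roles.get("CLD", {"tier2": []})["tier2"]
    n_pairs = cfg.tier2_n_variants - cfg.tier2_n_samples
    ar_pool = [g for g in truth_pool if g.inheritance_mode == "AR"]
    single_pool = [g for g in truth_pool if g.inheritance_mode in ("AD", "AR")]
    for j, sid in enumerate(tier2_samples):
        if j < n_pairs:
            gene = ar_pool[int(rng.integers(len(ar_pool)))]
            plant_config(sid, gene, "tier2", degrade=True, force_pair=True)
        else:
            gene = single_pool[int(rng.integers(len(single_pool)))]
            # singles: dominant het or recessive hom, one degraded variant
            if gene.inheritance_mode == "AD":
                plant_config(sid, gene, "tier2", degrade=True)
            else:
                k = plant_variant(sid, gene, "hom_alt", 0.0, _DEGRADABLE[int(rng.integers(len(_DEGRADABLE)))])
                truth.append(
                    {
                        "sample_id": sid,
                        "gene": gene.symbol,
                        "variant_keys": [k],
                        "configuration": "homozygous",
                        "tier": "tier2",
                        "classification": acmg_classify(acmg_tags[k]),
                    }
                )

    # ---- decoys: misannotated common "pathogenic" database entries
    decoy_keys: list[str] = []
    lo, hi = cfg.decoy_subpop_af_range
    glo, ghi = cfg.decoy_global_af_range
    decoy_genes = [g.symbol for g in truth_pool]
    for _ in range(cfg.n_decoy_sites):
        gene = decoy_genes[int(rng.integers(len(decoy_genes)))]
        site = _blank_site(keys.snv(gene), gene, "missense")
        site["clinvar"], site["hgmd"] = (("P", "DM"), ("P", "absent"), ("absent", "DM"))[
            int(rng.integers(3))
        ]
        site["global_af"] = float(np.round(rng.uniform(glo, ghi), 6))
        pop = AF_COLUMNS[int(rng.integers(len(AF_COLUMNS)))]
        site[pop] = float(np.round(rng.uniform(lo, hi), 6))
        site["cadd"] = float(np.round(rng.uniform(0, 20), 2))
        decoy_keys.append(site["variant_key"])
        site_rows.append(site)
    for cohort in cfg.cohort_sizes:
        for sid in roles[cohort]["decoy"]:
            key = decoy_keys[int(rng.integers(len(decoy_keys)))]
            call_rows.append(
                {"sample_id": sid, "variant_key": key, "zygosity": "het", **_good_quality(rng, "het")}
            )

    # ---- allowlist sites and genotypes
    c282y, h63d = allowlist.key("HFE", "C282Y"), allowlist.key("HFE", "H63D")
    piz, pis = allowlist.key("SERPINA1", "PiZ"), allowlist.key("SERPINA1", "PiS")
    hfe_splice = "6:26091388:G:A"  # rare truncating second HFE allele
    allow_sites = {
        c282y: ("HFE", "missense", 0.04, 0.07),
        h63d: ("HFE", "missense", 0.11, 0.15),
        piz: ("SERPINA1", "missense", 0.012, 0.022),
        pis: ("SERPINA1", "missense", 0.018, 0.03),
    }
    for key, (gene, cons, g_af, nfe_af) in allow_sites.items():
        site = _blank_site(key, gene, cons)
        site["clinvar"], site["hgmd"] = "P", "DM"
        site["global_af"], site["af_nfe_g"], site["af_nfe_e"] = g_af, nfe_af, nfe_af
        site["cadd"] = 25.0
        site_rows.append(site)
    splice_site = _blank_site(hfe_splice, "HFE", "ptv")
    splice_site["loftee"] = "HC"
    splice_site["cadd"] = 33.0
    site_rows.append(splice_site)

    _PATTERNS = {
        "Homozygous C282Y": ((c282y, "hom_alt"),),
        "Homozygous H63D": ((h63d, "hom_alt"),),
        "Compound C282Y/H63D": ((c282y, "het"), (h63d, "het")),
        "C282Y or H63D/PTV": ((h63d, "het"), (hfe_splice, "het")),
        "Pi ZZ": ((piz, "hom_alt"),),
        "Pi MZ": ((piz, "het"),),
        "Pi SS": ((pis, "hom_alt"),),
        "Pi MS": ((pis, "het"),),
        "Pi Z/Pi S": ((piz, "het"), (pis, "het")),
    }
    _DIAG_TRUTH_KEYS = {
        "Homozygous C282Y": ("HFE", [c282y]),
        "C282Y or H63D/PTV": ("HFE", sorted([h63d, hfe_splice])),
        "Pi ZZ": ("SERPINA1", [piz]),
    }
    for cohort in cfg.cohort_sizes:
        planted = cfg.allowlist_planted.get(cohort, {})
        diag_iter = iter(roles[cohort]["allow_diag"])
        carrier_iter = iter(roles[cohort]["allow_carrier"])
        for category in sorted(planted):
            for _ in range(planted[category]):
                sid = next(diag_iter) if category in _DIAG_TRUTH_KEYS else next(carrier_iter)
                for key, zyg in _PATTERNS[category]:
                    call_rows.append(
                        {
                            "sample_id": sid,
                            "variant_key": key,
                            "zygosity": zyg,
                            **_good_quality(rng, zyg),
                        }
                    )
                if category in _DIAG_TRUTH_KEYS:
                    gene, ks = _DIAG_TRUTH_KEYS[category]
                    truth.append(
                        {
                            "sample_id": sid,
                            "gene": gene,
                            "variant_keys": list(ks),
                            "configuration": "allowlist_genotype",
                            "tier": "allowlist",
                            "classification": "pathogenic",
                        }
                    )

    planted_calls = pd.DataFrame(call_rows, columns=list(CALL_COLUMNS))

    # ---- vectorised background calls
    all_ids = np.concatenate([np.asarray(v, dtype=object) for v in sample_ids.values()])
    per = cfg.background_per_sample
    n_total = len(all_ids)
    samp_idx = np.repeat(np.arange(n_total), per)
    site_idx = rng.integers(0, len(bg_keys), size=n_total * per)
    zyg = np.where(rng.random(n_total * per) < 0.1, "hom_alt", "het")
    bg = pd.DataFrame(
        {
            "sample_id": all_ids[samp_idx],
            "variant_key": np.asarray(bg_keys, dtype=object)[site_idx],
            "zygosity": zyg,
            "dp": rng.integers(20, 80, size=n_total * per),
            "gq": rng.integers(60, 100, size=n_total * per),
            "mq": np.round(rng.uniform(55, 70, size=n_total * per), 2),
            "qd": np.round(rng.uniform(5, 20, size=n_total * per), 2),
            "qual": np.round(rng.uniform(200, 900, size=n_total * per), 1),
            "vqsr_pass": True,
            "alt_fraction": np.round(
                np.where(zyg == "hom_alt", rng.uniform(0.9, 1.0, n_total * per), rng.uniform(0.35, 0.6, n_total * per)),
                3,
            ),
        }
    )
    bg = bg.drop_duplicates(subset=["sample_id", "variant_key"], keep="first")

    frames = [f for f in (planted_calls, bg) if len(f)]
    calls = pd.concat(frames, ignore_index=True)[list(CALL_COLUMNS)] if frames else planted_calls
    sites = pd.DataFrame(site_rows, columns=list(SITE_COLUMNS))
    if sites["variant_key"].duplicated().any():
        raise RuntimeError("generator produced duplicate variant keys")

    data = CohortData(manifest=manifest, calls=calls, sites=sites, acmg_tags=acmg_tags, truth=truth)
    if validate:
        _validate_planting(data, decoy_keys)
    return data


def _validate_planting(data: CohortData, decoy_keys: list[str]) -> None:
    """Generation-time invariants on planted truth, rescue and decoy variants."""
    from .variants import add_max_subpop_maf

    truth_keys = {
        k for t in data.truth if t["tier"] == "tier1" for k in t["variant_keys"]
    }
    rescue_keys = {
        k for t in data.truth if t["tier"] == "tier2" for k in t["variant_keys"]
    }
    calls = data.calls
    t1 = calls[calls["variant_key"].isin(truth_keys)]
    if not pass_quality_frame(t1, STRICT_FILTERS).all():
        raise RuntimeError("planted tier-1 variant fails strict quality gates")
    t2 = calls[calls["variant_key"].isin(rescue_keys)]
    strict_q = pass_quality_frame(t2, STRICT_FILTERS)
    relaxed_q = pass_quality_frame(t2, RELAXED_FILTERS)
    if strict_q.any() or not relaxed_q.all():
        raise RuntimeError("planted tier-2 variant not in the strict-fail/relaxed-pass band")
    sites = add_max_subpop_maf(data.sites)
    decoys = sites[sites["variant_key"].isin(decoy_keys)]
    if not (decoys["max_subpop_maf"] > RELAXED_FILTERS.recessive_maf_max).all():
        raise RuntimeError("planted decoy passes the recessive subpopulation MAF gate")
    if not (decoys["global_af"] < STRICT_FILTERS.global_af_max).all():
        raise RuntimeError("planted decoy fails the global AF gate")


# ---------------------------------------------------------------------------
# fixture output


def write_fixture(outdir, data: CohortData, panel: list[PanelGene]) -> dict[str, Path]:
    """Write panel/manifest/variant/evidence/truth files (deterministic bytes)."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "panel": out / "panel.tsv",
        "manifest": out / "manifest.tsv",
        "variants": out / "variants.tsv",
        "acmg": out / "acmg_tags.tsv",
        "truth": out / "truth.json",
    }
    write_panel(paths["panel"], panel)
    write_manifest(paths["manifest"], data.manifest)
    write_variant_table(paths["variants"], data.calls, data.sites)
    write_acmg_tags(paths["acmg"], data.acmg_tags)
    with open(paths["truth"], "w", encoding="utf-8") as fh:
        json.dump(sorted(data.truth, key=lambda t: (t["sample_id"], t["gene"])), fh, indent=1)
        fh.write("\n")
    return paths
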