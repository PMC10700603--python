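"""Cohort variant data model: sample manifest, genotype calls, site annotations.

Cohort-scale collections are pandas DataFrames with fixed, validated
schemas (one row per sample for the manifest; one row per sample×variant
observation for calls; one row per unique variant for site annotations).
Variant keys follow the 1-based VCF convention ``chrom:pos:ref:alt`` and
are normalised to their minimal representation so that keys written by
different tools compare equal.

Allele frequencies are carried for the gnomAD overall population and for
eight ancestry subpopulations (AFR, AMR, ASJ, FIN, NFE, EAS, SAS, OTH) in
each of two databases (gnomAD ``_g`` and ExAC ``_e``); a variant absent
from a database has frequency 0 ("novel").
"""

from __future__ import annotations

from typing import Iterable

import numpy as np
import pandas as pd
from pydantic import BaseModel, model_validator

__all__ = [
    "COHORTS",
    "SUBPOPULATIONS",
    "AF_COLUMNS",
    "CALL_COLUMNS",
    "SITE_COLUMNS",
    "MANIFEST_COLUMNS",
    "VARIANT_TSV_COLUMNS",
    "CONSEQUENCES",
    "IMPACTFUL_CONSEQUENCES",
    "FilterConfig",
    "STRICT_FILTERS",
    "RELAXED_FILTERS",
    "VariantDataError",
    "normalize_variant_key",
    "variant_key_chrom",
    "read_manifest",
    "write_manifest",
    "read_variant_table",
    "write_variant_table",
    "read_acmg_tags",
    "write_acmg_tags",
    "max_subpop_maf",
    "add_max_subpop_maf",
]

COHORTS = ("HC", "CKD", "CLD")
SEXES = ("male", "female", "unknown")
AGE_GROUPS = ("0-21", "22-44", "45-64", "65plus", "unknown")
RACE_ETH = ("White", "Hispanic", "Black", "Asian", "Other")
PRIMARY_DX = (
    "Metabolic_Congenital",
    "NAFLD_NASH",
    "AIH_PBC_PSC",
    "Abnormal_LFT",
    "Biliary_Atresia",
    "Other",
    "NA",
)

SUBPOPULATIONS = ("afr", "amr", "asj", "fin", "nfe", "eas", "sas", "oth")
#: 16 subpopulation AF columns: 8 ancestries × {gnomAD (_g), ExAC (_e)}.
AF_COLUMNS = tuple(f"af_{p}_{db}" for db in ("g", "e") for p in SUBPOPULATIONS)

CONSEQUENCES = ("ptv", "missense", "splice_region", "inframe", "synonymous", "other")
#: Consequence classes with at least moderate predicted biological effect.
IMPACTFUL_CONSEQUENCES = frozenset({"ptv", "missense", "splice_region", "inframe"})

CLINVAR_STATES = ("P", "LP", "conflicting", "other", "absent")
HGMD_STATES = ("DM", "other", "absent")
LOFTEE_STATES = ("HC", "LC", "NA")
ZYGOSITIES = ("het", "hom_alt", "hemi")

MANIFEST_COLUMNS = ("sample_id", "cohort", "sex", "age_group", "race_eth", "primary_dx")
CALL_COLUMNS = (
    "sample_id",
    "variant_key",
    "zygosity",
    "dp",
    "gq",
    "mq",
    "qd",
    "qual",
    "vqsr_pass",
    "alt_fraction",
)
SITE_COLUMNS = (
    ("variant_key", "gene", "consequence")
    + ("global_af",)
    + AF_COLUMNS
    + ("clinvar", "hgmd", "loftee", "cadd")
)
#: Flat per-call TSV dialect: call fields followed by the site annotation.
VARIANT_TSV_COLUMNS = (
    "sample_id",
    "variant_key",
    "gene",
    "consequence",
    "zygosity",
    "dp",
    "gq",
    "mq",
    "qd",
    "qual",
    "vqsr_pass",
    "alt_fraction",
    "global_af",
) + AF_COLUMNS + ("clinvar", "hgmd", "loftee", "cadd")


class VariantDataError(ValueError):
    """Malformed or inconsistent cohort variant data."""


class FilterConfig(BaseModel):
    """Genotype-quality and allele-frequency gates.

    Integer thresholds are inclusive lower bounds (``min_dp=10`` admits
    DP ≥ 10, i.e. the conventional "DP > 9"); ``min_alt_fraction`` is a
    strict lower bound, matching the convention that the alternate-read
    fraction must *exceed* the cutoff.  ``global_af_max`` is a strict
    upper bound (AF < 1%); the per-inheritance-context subpopulation MAF
    bounds are inclusive (MAF ≤ 1e−4 dominant, ≤ 1e−3 recessive).
    """

    min_dp: int = 10
    min_qual: float = 50.0
    min_qd: float = 2.0
    min_gq: int = 20
    min_mq: float = 40.0
    require_vqsr_pass: bool = True
    min_alt_fraction: float = 0.25
    global_af_max: float = 0.01
    dominant_maf_max: float = 1e-4
    recessive_maf_max: float = 1e-3

    @model_validator(mode="after")
    def _check(self) -> "FilterConfig":
        if not self.dominant_maf_max <= self.recessive_maf_max:
            raise ValueError("dominant_maf_max must be <= recessive_maf_max")
        for name in ("min_dp", "min_qual", "min_qd", "min_gq", "min_mq", "min_alt_fraction"):
            if not np.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite")
        return self

    def no_stricter_than(self, other: "FilterConfig") -> bool:
        """True iff every gate of ``self`` admits at least what ``other`` admits."""
        return (
            self.min_dp <= other.min_dp
            and self.min_qual <= other.min_qual
            and self.min_qd <= other.min_qd
            and self.min_gq <= other.min_gq
            and self.min_mq <= other.min_mq
            and self.min_alt_fraction <= other.min_alt_fraction
            and (not self.require_vqsr_pass or other.require_vqsr_pass)
        )


#: Strict (tier-1) defaults: DP > 9, VQSR PASS, Qual > 49, QD ≥ 2, GQ ≥ 20,
#: MQ ≥ 40, alt fraction > 0.25.
STRICT_FILTERS = FilterConfig()

#: Relaxed (tier-2 rescue) defaults: DP ≥ 4, GQ ≥ 10, Qual ≥ 30, QD ≥ 1,
#: MQ ≥ 40, alt fraction > 0.20, VQSR not required.
RELAXED_FILTERS = FilterConfig(
    min_dp=4,
    min_qual=30.0,
    min_qd=1.0,
    min_gq=10,
    min_mq=40.0,
    require_vqsr_pass=False,
    min_alt_fraction=0.20,
)


# ---------------------------------------------------------------------------
# variant keys


def normalize_variant_key(key: str) -> str:
    """Normalise ``chrom:pos:ref:alt`` to its minimal 1-based representation.

    Shared ref/alt suffixes are trimmed first, then shared prefixes (the
    position advancing accordingly), keeping at least one base of each
    allele — the usual parsimonious representation of indels.
    """
    parts = str(key).split(":")
    if len(parts) != 4:
        raise VariantDataError(f"malformed variant key {key!r} (want chrom:pos:ref:alt)")
    chrom, pos_s, ref, alt = parts
    chrom = chrom[3:] if chrom.lower().startswith("chr") else chrom
    chrom = chrom.upper() if chrom.upper() in ("X", "Y") else chrom
    try:
        pos = int(pos_s)
    except ValueError as exc:
        raise VariantDataError(f"malformed variant key {key!r}: non-integer position") from exc
    ref, alt = ref.upper(), alt.upper()
    if not ref or not alt or set(ref + alt) - set("ACGTN"):
        raise VariantDataError(f"malformed variant key {key!r}: bad alleles")
    if "," in alt:
        raise VariantDataError(f"multi-allelic key {key!r}: decompose before ingestion")
    while len(ref) > 1 and len(alt) > 1 and ref[-1] == alt[-1]:
        ref, alt = ref[:-1], alt[:-1]
    while len(ref) > 1 and len(alt) > 1 and ref[0] == alt[0]:
        ref, alt = ref[1:], alt[1:]
        pos += 1
    return f"{chrom}:{pos}:{ref}:{alt}"


def variant_key_chrom(key: str) -> str:
    return str(key).split(":", 1)[0]


# ---------------------------------------------------------------------------
# manifest


def read_manifest(path) -> pd.DataFrame:
    """Read and validate a sample manifest TSV.

    Header: ``sample_id  cohort  sex  age_group  race_eth  primary_dx``.
    Enum fields are normalised case-insensitively against the documented
    vocabularies; duplicate sample ids and unknown cohorts are errors.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if tuple(df.columns) != MANIFEST_COLUMNS:
        raise VariantDataError(f"manifest header {list(df.columns)} != {list(MANIFEST_COLUMNS)}")
    return validate_manifest(df)


def _norm_enum(series: pd.Series, allowed: tuple[str, ...], field: str) -> pd.Series:
    lut = {a.lower(): a for a in allowed}
    out = series.str.strip().str.lower().map(lut)
    if out.isna().any():
        bad = series[out.isna()].iloc[0]
        raise VariantDataError(f"unknown {field} label {bad!r} (allowed: {', '.join(allowed)})")
    return out


def validate_manifest(df: pd.DataFrame) -> pd.DataFrame:
    df = df.copy()
    if df.empty:
        return df
    dup = df["sample_id"][df["sample_id"].duplicated()]
    if len(dup):
        raise VariantDataError(f"duplicate sample_id in manifest: {dup.iloc[0]}")
    df["cohort"] = _norm_enum(df["cohort"], COHORTS, "cohort")
    df["sex"] = _norm_enum(df["sex"], SEXES, "sex")
    df["age_group"] = _norm_enum(df["age_group"], AGE_GROUPS, "age_group")
    df["race_eth"] = _norm_enum(df["race_eth"], RACE_ETH, "race_eth")
    df["primary_dx"] = _norm_enum(df["primary_dx"], PRIMARY_DX, "primary_dx")
    bad_dx = (df["cohort"] == "CLD") & (df["primary_dx"] == "NA")
    if bad_dx.any():
        raise VariantDataError(
            f"CLD sample {df.loc[bad_dx, 'sample_id'].iloc[0]} has primary_dx NA"
        )
    return df


def write_manifest(path, manifest: pd.DataFrame) -> None:
    manifest.to_csv(path, sep="\t", index=False, columns=list(MANIFEST_COLUMNS))


# ---------------------------------------------------------------------------
# variant tables


def read_variant_table(path, manifest: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Read the flat per-call variant TSV into (calls, sites) DataFrames.

    Every call must reference a manifest sample.  Missing AF fields become
    0 (novel); missing CADD becomes NaN.  Site annotations are de-duplicated
    by variant key; conflicting duplicate annotations are an error.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if tuple(df.columns) != VARIANT_TSV_COLUMNS:
        raise VariantDataError(
            f"variant table header {list(df.columns)} != {list(VARIANT_TSV_COLUMNS)}"
        )
    if df.empty:
        calls = pd.DataFrame(columns=list(CALL_COLUMNS))
        sites = pd.DataFrame(columns=list(SITE_COLUMNS))
        return calls, sites

    df["variant_key"] = df["variant_key"].map(normalize_variant_key)
    known = set(manifest["sample_id"]) if len(manifest) else set()
    unknown = ~df["sample_id"].isin(known)
    if unknown.any():
        raise VariantDataError(
            f"call references sample {df.loc[unknown, 'sample_id'].iloc[0]!r} not in manifest"
        )

    for col in ("dp", "gq"):
        df[col] = pd.to_numeric(df[col]).astype(int)
    for col in ("mq", "qd", "qual", "alt_fraction", "cadd"):
        df[col] = pd.to_numeric(df[col].replace("", np.nan))
    for col in ("global_af",) + AF_COLUMNS:
        df[col] = pd.to_numeric(df[col].replace("", "0")).fillna(0.0)
        if ((df[col] < 0) | (df[col] > 1)).any():
            raise VariantDataError(f"allele frequency outside [0,1] in column {col}")
    df["vqsr_pass"] = df["vqsr_pass"].str.strip().str.lower().isin(("1", "true", "pass", "yes"))

    for col, allowed in (
        ("zygosity", ZYGOSITIES),
        ("consequence", CONSEQUENCES),
        ("clinvar", CLINVAR_STATES),
        ("hgmd", HGMD_STATES),
        ("loftee", LOFTEE_STATES),
    ):
        bad = ~df[col].isin(allowed)
        if bad.any():
            raise VariantDataError(f"unknown {col} value {df.loc[bad, col].iloc[0]!r}")
    if ((df["alt_fraction"] < 0) | (df["alt_fraction"] > 1)).any():
        raise VariantDataError("alt_fraction outside [0,1]")
    # LOFTEE annotation only applies to protein-truncating consequences
    bad_loftee = (df["loftee"] != "NA") & (df["consequence"] != "ptv")
    if bad_loftee.any():
        raise VariantDataError("LOFTEE flag present on non-PTV consequence")
    # hemizygous calls only make sense on the sex chromosomes
    hemi = df["zygosity"] == "hemi"
    if hemi.any():
        chroms = df.loc[hemi, "variant_key"].map(variant_key_chrom)
        if (~chroms.isin(("X", "Y"))).any():
            raise VariantDataError("hemizygous call on an autosome")

    calls = df[list(CALL_COLUMNS)].copy()
    sites = df[list(SITE_COLUMNS)].drop_duplicates()
    if sites["variant_key"].duplicated().any():
        key = sites.loc[sites["variant_key"].duplicated(), "variant_key"].iloc[0]
        raise VariantDataError(f"conflicting site annotations for {key}")
    return calls.reset_index(drop=True), sites.reset_index(drop=True)


def write_variant_table(path, calls: pd.DataFrame, sites: pd.DataFrame) -> None:
    """Write (calls, sites) back to the flat TSV dialect (lossless round trip)."""
    flat = calls.merge(sites, on="variant_key", how="left", validate="many_to_one")
    flat = flat[list(VARIANT_TSV_COLUMNS)].copy()
    flat["vqsr_pass"] = flat["vqsr_pass"].map({True: "1", False: "0"})
    flat.to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_acmg_tags(path) -> dict[str, frozenset[str]]:
    """Read a two-column TSV ``variant_key  tags`` (tags semicolon-delimited)."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if tuple(df.columns) != ("variant_key", "tags"):
        raise VariantDataError("ACMG tag table must have columns variant_key, tags")
    return {
        normalize_variant_key(k): frozenset(t for t in tags.split(";") if t)
        for k, tags in zip(df["variant_key"], df["tags"])
    }


def write_acmg_tags(path, tags: dict[str, Iterable[str]]) -> None:
    with open(path, "w", encoding="utf-8", newline="") as fh:
        fh.write("variant_key\ttags\n")
        for key in sorted(tags):
            fh.write(f"{key}\t{';'.join(sorted(tags[key]))}\n")


# ---------------------------------------------------------------------------
# subpopulation MAF


def max_subpop_maf(site) -> float:
    """Maximum allele frequency over 8 subpopulations × 2 databases.

    Accepts a site row (Series/mapping with the ``af_*`` columns); missing
    entries count as 0.
    """
    return float(max(float(site[c]) for c in AF_COLUMNS))


def add_max_subpop_maf(sites: pd.DataFrame) -> pd.DataFrame:
    """Return ``sites`` with a ``max_subpop_maf`` column appended."""
    out = sites.copy()
    if len(out):
        out["max_subpop_maf"] = out[list(AF_COLUMNS)].to_numpy(dtype=float).max(axis=1)
    else:
        out["max_subpop_maf"] = pd.Series(dtype=float)
    return out
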