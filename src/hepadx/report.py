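"""Human-readable reporting and run provenance.

Renders a pipeline + statistics run as four TSV tables (stage counts,
per-gene diagnoses, allowlist genotype tallies, clinical subgroup
contrasts) and one JSON summary validated by a shipped pydantic schema.
Rates print with one decimal; panel-style percents print as integers.
"""

from __future__ import annotations

import hashlib
import json
import platform
from datetime import datetime, timezone
from pathlib import Path

import pandas as pd
from pydantic import BaseModel

from .diagnose import PipelineResult
from .stats import chi_square, odds_ratio_wald, subgroup_association

__all__ = ["ReportSummary", "RunManifest", "render_report", "write_run_manifest", "summary_schema"]


class CohortStage(BaseModel):
    n: int
    naive: int
    tier1: int
    tier2: int
    allowlist: int
    diagnosed: int
    diagnostic_rate_percent: float


class EnrichmentBlock(BaseModel):
    table: list[list[int]]
    odds_ratio: float
    ci_low: float
    ci_high: float
    chi2: float
    df: int
    p: float
    yates: bool


class SubgroupBlock(BaseModel):
    field: str
    chi2: float
    df: int
    p: float
    yates: bool


class ReportSummary(BaseModel):
    """JSON summary schema for a full pipeline + statistics run."""

    cohorts: dict[str, CohortStage]
    enrichment_cld_vs_hc: EnrichmentBlock | None = None
    overall_3x2: EnrichmentBlock | None = None
    subgroups: list[SubgroupBlock] = []
    n_calls: int = 0


def summary_schema() -> dict:
    """The shipped JSON schema for :class:`ReportSummary`."""
    return ReportSummary.model_json_schema()


def render_report(
    result: PipelineResult,
    manifest: pd.DataFrame,
    outdir,
    enrichment_tiers: tuple[str, ...] = ("tier1",),
    subgroup_fields: tuple[str, ...] = ("sex", "age_group", "race_eth", "primary_dx"),
) -> ReportSummary:
    """Write the report tables and JSON summary; returns the summary model.

    Enrichment (odds ratio + chi-square) contrasts CLD vs HC carriers at
    ``enrichment_tiers``; a 3×2 overall test across all cohorts is also
    emitted.  Subgroup contrasts run on the CLD cohort for each field
    with ≥2 populated levels.  Rendering is a pure function of its
    inputs and is idempotent.
    """
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    counts = result.stage_counts
    rates = result.diagnostic_rates()

    stage_tsv = rates.copy()
    stage_tsv["rate_percent"] = stage_tsv["rate_percent"].map(lambda r: f"{r:.1f}")
    stage_tsv.to_csv(out / "stage_counts.tsv", sep="\t")
    result.gene_counts.to_csv(out / "gene_counts.tsv", sep="\t")
    result.tally.to_csv(out / "allowlist_tally.tsv", sep="\t")
    result.calls_frame().sort_values(["sample_id", "gene"]).to_csv(
        out / "diagnostic_calls.tsv", sep="\t", index=False
    )

    cohort_of = dict(zip(manifest["sample_id"], manifest["cohort"]))
    diagnosed = {c.sample_id for c in result.calls if c.tier in enrichment_tiers}

    def _cells(cohort: str) -> tuple[int, int]:
        n = int(counts.loc[cohort, "n"])
        k = sum(1 for s in diagnosed if cohort_of.get(s) == cohort)
        return k, n

    enrichment = overall = None
    k_cld, n_cld = _cells("CLD")
    k_hc, n_hc = _cells("HC")
    if min(k_cld, n_cld - k_cld, k_hc, n_hc - k_hc) > 0:
        orr = odds_ratio_wald(k_cld, n_cld - k_cld, k_hc, n_hc - k_hc)
        chi = chi_square([[k_cld, n_cld - k_cld], [k_hc, n_hc - k_hc]])
        enrichment = EnrichmentBlock(
            table=[[k_cld, n_cld - k_cld], [k_hc, n_hc - k_hc]],
            odds_ratio=orr.odds_ratio,
            ci_low=orr.ci_low,
            ci_high=orr.ci_high,
            chi2=chi.chi2,
            df=chi.df,
            p=chi.p,
            yates=chi.yates,
        )
        k_ckd, n_ckd = _cells("CKD")
        if 0 < k_ckd < n_ckd:
            t3 = [
                [k_hc, n_hc - k_hc],
                [k_ckd, n_ckd - k_ckd],
                [k_cld, n_cld - k_cld],
            ]
            chi3 = chi_square(t3)
            overall = EnrichmentBlock(
                table=t3,
                odds_ratio=orr.odds_ratio,
                ci_low=orr.ci_low,
                ci_high=orr.ci_high,
                chi2=chi3.chi2,
                df=chi3.df,
                p=chi3.p,
                yates=chi3.yates,
            )

    subgroups = []
    sub_frames = []
    all_diagnosed = result.diagnosed_samples()
    for field in subgroup_fields:
        try:
            table_df, res = subgroup_association(manifest, all_diagnosed, field)
        except ValueError:
            continue
        table_df = table_df.copy()
        table_df.insert(0, "field", field)
        sub_frames.append(table_df)
        subgroups.append(
            SubgroupBlock(field=field, chi2=res.chi2, df=res.df, p=res.p, yates=res.yates)
        )
    if sub_frames:
        pd.concat(sub_frames).to_csv(out / "subgroup_table.tsv", sep="\t")

    summary = ReportSummary(
        cohorts={
            cohort: CohortStage(
                **{k: int(counts.loc[cohort, k]) for k in ("n", "naive", "tier1", "tier2", "allowlist", "diagnosed")},
                diagnostic_rate_percent=round(float(rates.loc[cohort, "rate_percent"]), 1),
            )
            for cohort in counts.index
        },
        enrichment_cld_vs_hc=enrichment,
        overall_3x2=overall,
        subgroups=subgroups,
        n_calls=len(result.calls),
    )
    (out / "summary.json").write_text(summary.model_dump_json(indent=1) + "\n", encoding="utf-8")
    return summary


class RunManifest(BaseModel):
    """Provenance record written once per output directory."""

    command: str
    seed: int | None = None
    config: dict = {}
    input_checksums: dict[str, str] = {}
    tool_version: str = "0.1.0"
    python: str = platform.python_version()
    timestamp: str = ""


def write_run_manifest(outdir, command: str, seed: int | None, config: dict, inputs: dict) -> Path:
    checksums = {}
    for name, path in inputs.items():
        p = Path(path)
        if p.exists():
            checksums[name] = hashlib.sha256(p.read_bytes()).hexdigest()
    manifest = RunManifest(
        command=command,
        seed=seed,
        config=config,
        input_checksums=checksums,
        timestamp=datetime.now(timezone.utc).isoformat(timespec="seconds"),
    )
    path = Path(outdir) / "run_manifest.json"
    path.write_text(manifest.model_dump_json(indent=1) + "\n", encoding="utf-8")
    return path
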