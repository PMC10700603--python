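"""Case-control enrichment and subgroup statistics.

Carrier prevalences per cohort, Wald odds ratios with log-scale
confidence intervals, and Pearson chi-square tests of r×c contingency
tables (Yates continuity correction automatically for 2×2).  The
headline comparison is the CLD-vs-HC 2×2 carrier table; subgroup tables
contrast diagnosed vs undiagnosed patients over a clinical covariate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as _sps

__all__ = [
    "OrResult",
    "ContingencyResult",
    "carrier_prevalence",
    "odds_ratio_wald",
    "chi_square",
    "subgroup_association",
]


@dataclass(frozen=True)
class OrResult:
    """Odds ratio with a Wald (log-scale normal) confidence interval."""

    odds_ratio: float
    ci_low: float
    ci_high: float
    alpha: float = 0.05

    def __post_init__(self) -> None:
        if not (self.ci_low <= self.odds_ratio <= self.ci_high):
            raise ValueError("confidence interval must bracket the odds ratio")


@dataclass(frozen=True)
class ContingencyResult:
    table: np.ndarray
    chi2: float
    df: int
    p: float
    yates: bool


def carrier_prevalence(
    calls: pd.DataFrame | list,
    manifest: pd.DataFrame,
    tiers: tuple[str, ...] = ("tier1",),
) -> pd.DataFrame:
    """Per-cohort carrier counts and fractions.

    A carrier is a sample with ≥1 diagnostic call in the requested tier
    set.  ``calls`` is a calls frame (columns sample_id, tier) or a list
    of :class:`~hepadx.diagnose.DiagnosticCall`.  Empty cohorts report a
    missing (NaN) fraction.
    """
    if not isinstance(calls, pd.DataFrame):
        calls = pd.DataFrame(
            [{"sample_id": c.sample_id, "tier": c.tier} for c in calls],
            columns=["sample_id", "tier"],
        )
    if len(calls):
        unknown = ~calls["sample_id"].isin(set(manifest["sample_id"]))
        if unknown.any():
            raise ValueError(
                f"call sample {calls.loc[unknown, 'sample_id'].iloc[0]!r} not in manifest"
            )
    carriers = set(calls.loc[calls["tier"].isin(tiers), "sample_id"]) if len(calls) else set()
    rows = []
    for cohort, group in manifest.groupby("cohort", sort=True):
        n = len(group)
        k = int(group["sample_id"].isin(carriers).sum())
        rows.append(
            {
                "cohort": cohort,
                "carriers": k,
                "total": n,
                "fraction": (k / n) if n else np.nan,
            }
        )
    return pd.DataFrame(rows).set_index("cohort")


def odds_ratio_wald(
    a: int, b: int, c: int, d: int, alpha: float = 0.05, haldane: bool = False
) -> OrResult:
    """Wald odds ratio for the 2×2 table [[a, b], [c, d]].

    Rows are (exposed: a affected, b unaffected) vs (reference: c
    affected, d unaffected): OR = ad/(bc), with the (1−alpha) CI
    exp(ln OR ± z·√(1/a+1/b+1/c+1/d)).  Zero cells are an error unless
    ``haldane`` adds the +0.5 Haldane–Anscombe correction to every cell.
    """
    cells = [a, b, c, d]
    if any(x < 0 for x in cells):
        raise ValueError("contingency cells must be non-negative")
    if haldane:
        a, b, c, d = (x + 0.5 for x in cells)
    elif 0 in cells:
        raise ValueError("zero cell in 2x2 table; use haldane=True for the +0.5 correction")
    orr = (a * d) / (b * c)
    z = float(_sps.norm.ppf(1 - alpha / 2))
    se = np.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    return OrResult(
        odds_ratio=float(orr),
        ci_low=float(np.exp(np.log(orr) - z * se)),
        ci_high=float(np.exp(np.log(orr) + z * se)),
        alpha=alpha,
    )


def chi_square(table, yates: bool | str = "auto") -> ContingencyResult:
    """Pearson chi-square test of independence for an r×c count table.

    ``yates="auto"`` applies the continuity correction exactly for 2×2
    tables (the R ``chisq.test`` default) and plain Pearson otherwise.
    Zero row/column margins are an error.
    """
    t = np.asarray(table, dtype=float)
    if t.ndim != 2 or t.shape[0] < 2 or t.shape[1] < 2:
        raise ValueError("contingency table must be at least 2x2")
    if (t < 0).any():
        raise ValueError("contingency cells must be non-negative")
    if (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
        raise ValueError("zero margin in contingency table")
    if yates == "auto":
        use_yates = t.shape == (2, 2)
    else:
        use_yates = bool(yates) and t.shape == (2, 2)
    chi2, p, df, _ = _sps.chi2_contingency(t, correction=use_yates)
    return ContingencyResult(table=t.astype(int), chi2=float(chi2), df=int(df), p=float(p), yates=use_yates)


SUBGROUP_LEVELS = {
    "sex": ("male", "female"),
    "age_group": ("0-21", "22-44", "45-64", "65plus"),
    "race_eth": ("White", "Hispanic", "Black", "Asian", "Other"),
    "primary_dx": (
        "Metabolic_Congenital",
        "NAFLD_NASH",
        "AIH_PBC_PSC",
        "Abnormal_LFT",
        "Biliary_Atresia",
        "Other",
    ),
}


def subgroup_association(
    manifest: pd.DataFrame,
    diagnosed: set[str],
    field: str,
    cohort: str = "CLD",
) -> tuple[pd.DataFrame, ContingencyResult]:
    """Diagnosed-vs-undiagnosed contrast over one clinical covariate.

    Builds the r×2 table of (no diagnosis, diagnosis) counts per level of
    ``field`` among ``cohort`` samples (levels with the 'unknown'/'NA'
    sentinel are dropped), with row percents, and tests it with
    :func:`chi_square` (Yates only when the field is binary).
    """
    if field not in SUBGROUP_LEVELS:
        raise ValueError(f"field must be one of {sorted(SUBGROUP_LEVELS)}")
    sub = manifest[manifest["cohort"] == cohort]
    levels = [lv for lv in SUBGROUP_LEVELS[field] if (sub[field] == lv).any()]
    if len(levels) < 2:
        raise ValueError(f"subgroup field {field!r} has fewer than 2 populated levels")
    rows = []
    for lv in levels:
        grp = sub[sub[field] == lv]
        dx = int(grp["sample_id"].isin(diagnosed).sum())
        no_dx = len(grp) - dx
        rows.append({"level": lv, "total": len(grp), "no_dx": no_dx, "dx": dx})
    table_df = pd.DataFrame(rows).set_index("level")
    table_df["no_dx_percent"] = 100.0 * table_df["no_dx"] / table_df["total"]
    table_df["dx_percent"] = 100.0 * table_df["dx"] / table_df["total"]
    result = chi_square(table_df[["no_dx", "dx"]].to_numpy(), yates="auto")
    return table_df, result
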