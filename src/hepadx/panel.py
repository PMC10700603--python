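"""Curated liver gene panel: loading, validation, and summaries.

A panel row describes one gene implicated in a Mendelian disorder with
hepatic manifestations: its inheritance mode (AD, AR, XLD, XLR, or dual
AD_AR), a set of clinical phenotype tags drawn from a controlled
vocabulary, whether the disorder is primarily hepatic, and two gene-level
constraint scores (pLI and missense Z).  Dominant-disease genes are
expected to be more constrained than recessive-disease genes; the
one-way ANOVA here quantifies that contrast across inheritance groups.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy import stats as _sps

__all__ = [
    "INHERITANCE_MODES",
    "PHENOTYPE_VOCABULARY",
    "PanelGene",
    "PanelSummary",
    "PanelValidationError",
    "InsufficientDataError",
    "load_panel",
    "write_panel",
    "summarize_panel",
    "constraint_anova",
    "inheritance_group",
]

INHERITANCE_MODES = ("AD", "AR", "XLD", "XLR", "AD_AR")

AUTOSOMES = tuple(str(i) for i in range(1, 23))

#: Controlled vocabulary of clinical liver phenotype tags.
PHENOTYPE_VOCABULARY = frozenset(
    {
        "hepatomegaly",
        "metabolic",
        "fibrosis_cirrhosis",
        "elevated_transaminase",
        "cholestasis",
        "steatosis",
        "cystic_liver",
        "liver_failure",
        "hepatocellular_carcinoma",
        "jaundice",
        "portal_hypertension",
        "splenomegaly",
    }
)

PANEL_COLUMNS = ("symbol", "chrom", "inheritance", "phenotype_tags", "pli", "mis_z", "primary_liver")


class PanelValidationError(ValueError):
    """A panel row violates the panel invariants."""


class InsufficientDataError(ValueError):
    """Too few usable groups/observations for the requested statistic."""


def _norm_chrom(chrom: str) -> str:
    c = chrom.strip()
    if c.lower().startswith("chr"):
        c = c[3:]
    return c.upper() if c.upper() in ("X", "Y") else c


@dataclass(frozen=True)
class PanelGene:
    """One curated gene with inheritance mode, phenotypes and constraint."""

    symbol: str
    chrom: str
    inheritance_mode: str
    phenotype_tags: frozenset[str] = field(default_factory=frozenset)
    primary_liver: bool = False
    pli: float | None = None
    mis_z: float | None = None

    def __post_init__(self) -> None:
        if not self.symbol or self.symbol != self.symbol.upper():
            raise PanelValidationError(f"gene symbol must be non-empty uppercase: {self.symbol!r}")
        chrom = _norm_chrom(self.chrom)
        object.__setattr__(self, "chrom", chrom)
        if chrom not in AUTOSOMES + ("X", "Y"):
            raise PanelValidationError(f"{self.symbol}: unknown chromosome {self.chrom!r}")
        if self.inheritance_mode not in INHERITANCE_MODES:
            raise PanelValidationError(
                f"{self.symbol}: unknown inheritance code {self.inheritance_mode!r} "
                f"(expected one of {', '.join(INHERITANCE_MODES)})"
            )
        if self.inheritance_mode in ("XLD", "XLR") and chrom != "X":
            raise PanelValidationError(
                f"{self.symbol}: X-linked mode {self.inheritance_mode} on chromosome {chrom}"
            )
        bad = set(self.phenotype_tags) - PHENOTYPE_VOCABULARY
        if bad:
            raise PanelValidationError(f"{self.symbol}: unknown phenotype tags {sorted(bad)}")
        if self.pli is not None and not (0.0 <= self.pli <= 1.0):
            raise PanelValidationError(f"{self.symbol}: pLI {self.pli} outside [0, 1]")


@dataclass(frozen=True)
class PanelSummary:
    """Composition of a panel: mode counts, tag frequencies, recessive share."""

    total: int
    mode_counts: dict[str, int]
    tag_frequencies: dict[str, tuple[int, float | None]]  # tag -> (count, percent)
    recessive_only_percent: float | None  # percent of genes with mode in {AR, XLR}
    primary_liver_count: int = 0


def load_panel(path) -> list[PanelGene]:
    """Read a panel TSV and return validated :class:`PanelGene` records.

    The dialect is UTF-8 TSV with header
    ``symbol  chrom  inheritance  phenotype_tags  pli  mis_z  primary_liver``;
    phenotype tags are semicolon-delimited; empty pli/mis_z mean missing.
    """
    genes: list[PanelGene] = []
    seen: set[str] = set()
    with open(path, encoding="utf-8", newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        if reader.fieldnames is None or tuple(reader.fieldnames) != PANEL_COLUMNS:
            raise PanelValidationError(
                f"panel header {reader.fieldnames} does not match {list(PANEL_COLUMNS)}"
            )
        for row in reader:
            symbol = row["symbol"].strip().upper()
            if symbol in seen:
                raise PanelValidationError(f"duplicate gene symbol in panel: {symbol}")
            seen.add(symbol)
            tags = frozenset(t.strip() for t in row["phenotype_tags"].split(";") if t.strip())
            genes.append(
                PanelGene(
                    symbol=symbol,
                    chrom=row["chrom"],
                    inheritance_mode=row["inheritance"].strip(),
                    phenotype_tags=tags,
                    primary_liver=row["primary_liver"].strip().lower() in ("1", "true", "yes", "primary"),
                    pli=float(row["pli"]) if row["pli"].strip() else None,
                    mis_z=float(row["mis_z"]) if row["mis_z"].strip() else None,
                )
            )
    return genes


def write_panel(path, panel: Iterable[PanelGene]) -> None:
    """Write genes in the panel TSV dialect (inverse of :func:`load_panel`)."""
    with open(path, "w", encoding="utf-8", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(PANEL_COLUMNS)
        for g in panel:
            w.writerow(
                [
                    g.symbol,
                    g.chrom,
                    g.inheritance_mode,
                    ";".join(sorted(g.phenotype_tags)),
                    "" if g.pli is None else f"{g.pli:.6g}",
                    "" if g.mis_z is None else f"{g.mis_z:.6g}",
                    "1" if g.primary_liver else "0",
                ]
            )


def summarize_panel(panel: Sequence[PanelGene], percent_decimals: int = 0) -> PanelSummary:
    """Tabulate inheritance-mode counts, tag frequencies and the recessive share.

    ``recessive_only_percent`` is 100 × (|AR| + |XLR|) / total, rounded to
    ``percent_decimals`` (panel reports conventionally print whole percents).
    Empty panels yield zero counts with percents flagged missing (None).
    """
    total = len(panel)
    mode_counts = {m: 0 for m in INHERITANCE_MODES}
    tag_counts: dict[str, int] = {}
    primary = 0
    for g in panel:
        mode_counts[g.inheritance_mode] += 1
        primary += g.primary_liver
        for t in g.phenotype_tags:
            tag_counts[t] = tag_counts.get(t, 0) + 1
    if total == 0:
        return PanelSummary(0, mode_counts, {}, None, 0)
    tag_freq = {
        t: (c, round(100.0 * c / total, percent_decimals)) for t, c in sorted(tag_counts.items())
    }
    rec = mode_counts["AR"] + mode_counts["XLR"]
    return PanelSummary(
        total=total,
        mode_counts=mode_counts,
        tag_frequencies=tag_freq,
        recessive_only_percent=round(100.0 * rec / total, percent_decimals),
        primary_liver_count=primary,
    )


def inheritance_group(mode: str) -> str:
    """Collapse the five modes into the three constraint-analysis groups."""
    if mode in ("AD", "XLD"):
        return "dominant"
    if mode in ("AR", "XLR"):
        return "recessive"
    return "dual"


def constraint_anova(
    panel: Sequence[PanelGene],
    score: str = "pli",
    two_group: bool = False,
) -> tuple[float, float, dict[str, float]]:
    """One-way ANOVA of a constraint score across inheritance groups.

    Groups are dominant-only (AD ∪ XLD), recessive-only (AR ∪ XLR) and
    dual-mode (AD_AR); missing scores are excluded listwise.  With
    ``two_group=True`` only the dominant/recessive contrast is tested.
    Returns ``(F, p, group_means)``.
    """
    if score not in ("pli", "mis_z"):
        raise ValueError(f"score must be 'pli' or 'mis_z', got {score!r}")
    groups: dict[str, list[float]] = {"dominant": [], "recessive": [], "dual": []}
    for g in panel:
        val = g.pli if score == "pli" else g.mis_z
        if val is not None:
            groups[inheritance_group(g.inheritance_mode)].append(float(val))
    if two_group:
        groups.pop("dual")
    usable = {k: np.asarray(v) for k, v in groups.items() if len(v) >= 2}
    if len(usable) < 2:
        raise InsufficientDataError(
            f"constraint ANOVA needs >=2 groups with >=2 scores; got {len(usable)}"
        )
    f_stat, p = _sps.f_oneway(*usable.values())
    # all observations identical -> zero variance everywhere; report F=0, p=1
    if np.isnan(f_stat):
        f_stat, p = 0.0, 1.0
    means = {k: float(v.mean()) for k, v in usable.items()}
    return float(f_stat), float(p), means
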