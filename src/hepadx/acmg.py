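"""ACMG-AMP evidence combination.

Evidence criteria are tags with a strength prefix: PVS (very strong
pathogenic), PS (strong), PM (moderate), PP (supporting), and on the
benign side BA (stand-alone), BS (strong), BP (supporting).  The engine
implements only the combination algebra — which class a given tag set
yields — not the assignment of tags to variants, which in clinical
practice is analyst consensus and here arrives as input annotation.

Contradictory evidence (a pathogenic-side rule and a benign-side rule
both firing) yields VUS, as does insufficient evidence.
"""

from __future__ import annotations

from typing import Collection

__all__ = [
    "VALID_TAGS",
    "PATHOGENIC",
    "LIKELY_PATHOGENIC",
    "VUS",
    "LIKELY_BENIGN",
    "BENIGN",
    "CLASSIFICATION_RANK",
    "acmg_classify",
    "is_diagnostic",
]

PATHOGENIC = "pathogenic"
LIKELY_PATHOGENIC = "likely_pathogenic"
VUS = "vus"
LIKELY_BENIGN = "likely_benign"
BENIGN = "benign"

#: Higher rank = stronger pathogenicity assertion (used for tie-breaking).
CLASSIFICATION_RANK = {
    PATHOGENIC: 4,
    LIKELY_PATHOGENIC: 3,
    VUS: 2,
    LIKELY_BENIGN: 1,
    BENIGN: 0,
}

VALID_TAGS = frozenset(
    {"PVS1"}
    | {f"PS{i}" for i in range(1, 5)}
    | {f"PM{i}" for i in range(1, 7)}
    | {f"PP{i}" for i in range(1, 6)}
    | {"BA1"}
    | {f"BS{i}" for i in range(1, 5)}
    | {f"BP{i}" for i in range(1, 8)}
)


def _counts(tags: frozenset[str]) -> tuple[int, int, int, int, bool, int, int]:
    pvs = "PVS1" in tags
    ps = sum(1 for t in tags if t.startswith("PS"))
    pm = sum(1 for t in tags if t.startswith("PM"))
    pp = sum(1 for t in tags if t.startswith("PP"))
    ba = "BA1" in tags
    bs = sum(1 for t in tags if t.startswith("BS"))
    bp = sum(1 for t in tags if t.startswith("BP"))
    return int(pvs), ps, pm, pp, ba, bs, bp


def acmg_classify(tags: Collection[str]) -> str:
    """Combine ACMG-AMP evidence tags into one of the five classes.

    Raises ``ValueError`` for tags outside the criteria vocabulary.
    """
    tagset = frozenset(tags)
    unknown = tagset - VALID_TAGS
    if unknown:
        raise ValueError(f"unknown ACMG-AMP tags: {sorted(unknown)}")
    pvs, ps, pm, pp, ba, bs, bp = _counts(tagset)

    pathogenic = (
        (pvs and (ps >= 1 or pm >= 2 or (pm == 1 and pp == 1) or pp >= 2))
        or ps >= 2
        or (ps == 1 and (pm >= 3 or (pm == 2 and pp >= 2) or (pm == 1 and pp >= 4)))
    )
    likely_pathogenic = not pathogenic and (
        (pvs and pm == 1)
        or (ps == 1 and 1 <= pm <= 2)
        or (ps == 1 and pp >= 2)
        or pm >= 3
        or (pm == 2 and pp >= 2)
        or (pm == 1 and pp >= 4)
    )
    benign = ba or bs >= 2
    likely_benign = not benign and ((bs == 1 and bp == 1) or bp >= 2)

    path_side = pathogenic or likely_pathogenic
    benign_side = benign or likely_benign
    if path_side and benign_side:
        return VUS
    if pathogenic:
        return PATHOGENIC
    if likely_pathogenic:
        return LIKELY_PATHOGENIC
    if benign:
        return BENIGN
    if likely_benign:
        return LIKELY_BENIGN
    return VUS


def is_diagnostic(classification: str) -> bool:
    """Pathogenic and likely-pathogenic calls count toward a diagnosis."""
    return classification in (PATHOGENIC, LIKELY_PATHOGENIC)
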