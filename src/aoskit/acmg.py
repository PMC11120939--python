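"""Point-based ACMG/ACGS variant classification.

Evidence codes carry a strength (very_strong/strong/moderate/supporting)
weighted 8/4/2/1; benign codes (BA/BS/BP prefixes) contribute negative
points.  The point total maps to a five-tier classification, and variants
of uncertain significance (VUS) are sub-tiered "hot" (4-5 points),
"warm" (2-3) or "cold" (0-1) following the ACGS convention.  Example:
PM2_Moderate + PM4_Moderate + PP3_Supporting = 2 + 2 + 1 = 5 points,
a hot VUS.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

from .errors import ValidationError

__all__ = ["AcmgAssessment", "acmg_classify", "STRENGTH_POINTS"]

STRENGTH_POINTS = {
    "very_strong": 8,
    "strong": 4,
    "moderate": 2,
    "supporting": 1,
}

_PATHOGENIC_PREFIXES = ("PVS", "PS", "PM", "PP")
_BENIGN_PREFIXES = ("BA", "BS", "BP")

# Point thresholds (Tavtigian-style Bayesian point system):
#   >= 10 pathogenic, 6..9 likely pathogenic, 0..5 VUS,
#   -6..-1 likely benign, <= -7 benign.
PATHOGENIC_MIN = 10
LIKELY_PATHOGENIC_MIN = 6
LIKELY_BENIGN_MAX = -1
BENIGN_MAX = -7


@dataclass(frozen=True)
class AcmgAssessment:
    criteria: tuple[tuple[str, str], ...]
    points: int
    classification: str
    vus_tier: str  # hot | warm | cold | none


def _criterion_points(code: str, strength: str) -> int:
    if strength not in STRENGTH_POINTS:
        raise ValidationError(
            f"unknown strength {strength!r} for {code}; expected one of "
            f"{sorted(STRENGTH_POINTS)}"
        )
    upper = code.upper()
    if upper.startswith(_BENIGN_PREFIXES):
        sign = -1
    elif upper.startswith(_PATHOGENIC_PREFIXES):
        sign = 1
    else:
        raise ValidationError(f"unrecognized ACMG code {code!r}")
    return sign * STRENGTH_POINTS[strength]


def acmg_classify(
    criteria: Iterable[Sequence[str]],
) -> AcmgAssessment:
    """Sum weighted evidence points and classify.

    ``criteria`` is a list of ``(code, strength)`` pairs, e.g.
    ``[("PM2", "moderate"), ("PM4", "moderate"), ("PP3", "supporting")]``.
    The sum is order-invariant and additive by construction.
    """
    crits = tuple((str(c), str(s)) for c, s in criteria)
    points = sum(_criterion_points(c, s) for c, s in crits)

    if points >= PATHOGENIC_MIN:
        classification = "pathogenic"
    elif points >= LIKELY_PATHOGENIC_MIN:
        classification = "likely_pathogenic"
    elif points >= 0:
        classification = "VUS"
    elif points > BENIGN_MAX:
        classification = "likely_benign"
    else:
        classification = "benign"

    if classification == "VUS":
        vus_tier = "hot" if points >= 4 else "warm" if points >= 2 else "cold"
    else:
        vus_tier = "none"

    return AcmgAssessment(crits, points, classification, vus_tier)
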