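"""Verbal numerical pain score (VNPS) vocabulary.

The VNPS is a self-reported, severity-increasing integer scale from 0 (no
pain) to 10 (worst imaginable pain) used routinely by UK ambulance services.
Scores are grouped into four clinical categories: severe (7-10), moderate
(4-6), mild (1-3) and none (0).
"""

from __future__ import annotations

from enum import IntEnum

VNPS_MIN = 0
VNPS_MAX = 10

#: Lowest score counted as "moderate" pain; eligibility for strong analgesia
#: requires moderate-to-severe pain, i.e. a score of at least this value.
MODERATE_THRESHOLD = 4
#: Lowest score counted as "severe" pain.
SEVERE_THRESHOLD = 7


class PainCategory(IntEnum):
    """Four-level clinical pain classification, ordered by severity."""

    NONE = 0
    MILD = 1
    MODERATE = 2
    SEVERE = 3

    @property
    def label(self) -> str:
        return self.name.lower()


class VnpsError(ValueError):
    """Raised for scores outside the 0-10 integer scale."""


def validate_vnps(score: object) -> int:
    """Validate ``score`` as an integer VNPS and return it as ``int``.

    Half-point or VAS-style fractional inputs are rejected, not rounded:
    the scale is integer-only. Booleans are rejected as well.
    """
    if isinstance(score, bool):
        raise VnpsError(f"VNPS must be an integer 0-10, got {score!r}")
    if isinstance(score, float):
        if not score.is_integer():
            raise VnpsError(f"VNPS must be a whole number, got {score!r}")
        score = int(score)
    if not isinstance(score, int):
        try:
            as_int = int(score)  # numpy integer scalars
        except (TypeError, ValueError):
            raise VnpsError(f"VNPS must be an integer 0-10, got {score!r}") from None
        if as_int != score:
            raise VnpsError(f"VNPS must be a whole number, got {score!r}")
        score = as_int
    if not VNPS_MIN <= score <= VNPS_MAX:
        raise VnpsError(f"VNPS out of range 0-10: {score}")
    return score


def categorize_vnps(score: object) -> PainCategory:
    """Map a VNPS to its clinical category.

    severe = 7-10, moderate = 4-6, mild = 1-3, none = 0. The category
    boundaries partition the scale, so every valid score maps to exactly
    one category.
    """
    value = validate_vnps(score)
    if value >= SEVERE_THRESHOLD:
        return PainCategory.SEVERE
    if value >= MODERATE_THRESHOLD:
        return PainCategory.MODERATE
    if value >= 1:
        return PainCategory.MILD
    return PainCategory.NONE


def is_moderate_to_severe(score: object) -> bool:
    """True iff the score is at least 4 (moderate or severe pain)."""
    return validate_vnps(score) >= MODERATE_THRESHOLD
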