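"""Shared vocabulary: functional domains, severity codes, cost categories.

The six functional domains and the four ordered severity levels follow the
Washington Group Short Set (WG-SS) disability identification questions used
in Indonesian national surveys. Two severity thresholds are in use
throughout: the *lower* threshold counts any reported difficulty
("some difficulty" or worse), the *higher* threshold counts only
moderate/severe difficulty ("a lot of difficulty" or "cannot do at all").
"""

from __future__ import annotations

#: WG-SS functional domains, in canonical order.
DOMAINS: tuple[str, ...] = (
    "seeing",
    "hearing",
    "walking",
    "remembering",
    "communicating",
    "selfcare",
)

#: Member-file column per domain (integer codes 0-3).
WG_COLUMNS: tuple[str, ...] = tuple(f"wg_{d}" for d in DOMAINS)

#: Ordered WG-SS response codes.
NO_DIFFICULTY, SOME_DIFFICULTY, A_LOT_DIFFICULTY, CANNOT_DO = 0, 1, 2, 3
RESPONSE_LABELS = {
    NO_DIFFICULTY: "none",
    SOME_DIFFICULTY: "some",
    A_LOT_DIFFICULTY: "a_lot",
    CANNOT_DO: "cannot",
}

#: Severity thresholds: minimum response code that flags a domain.
THRESHOLDS: dict[str, int] = {"lower": SOME_DIFFICULTY, "higher": A_LOT_DIFFICULTY}

#: The six goods-and-services cost categories.
GS_CATEGORIES: tuple[str, ...] = (
    "assistive_devices",
    "special_accommodation",
    "human_assistance",
    "commute_travel",
    "interstate_travel",
    "essential_needs",
)

#: Quintile labels, Q1 = poorest.
QUINTILES: tuple[int, ...] = (1, 2, 3, 4, 5)

#: Age bands used in GS summaries.
AGE_BANDS: tuple[str, ...] = ("young", "productive", "elderly")


def age_band(age: float) -> str:
    """Map an age in years to the young (<25) / productive (25-59) / elderly (60+) band."""
    if age < 25:
        return "young"
    if age < 60:
        return "productive"
    return "elderly"


def check_threshold(threshold: str) -> int:
    """Return the minimum flagging code for a named threshold, or raise ValueError."""
    try:
        return THRESHOLDS[threshold]
    except KeyError:
        raise ValueError(
            f"unknown threshold {threshold!r}; expected one of {sorted(THRESHOLDS)}"
        ) from None
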