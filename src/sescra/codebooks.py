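"""Category codebooks and unit constants shared across the package.

Survey alcohol use is recorded as a usual-frequency category (never up to
daily) and a usual-quantity category (standard drinks per occasion, 1-2 up
to 13+).  The quantity-frequency midpoints below convert those categories
to grams of pure alcohol per day.  Open-ended categories carry assigned
values rather than midpoints; all of these are configuration, not physics,
and may be overridden.
"""

from __future__ import annotations

# grams of pure alcohol in one standard drink (South African convention)
GRAMS_PER_STANDARD_DRINK: float = 12.0

# density of ethanol, grams per litre, for litres <-> grams conversion
ETHANOL_GRAMS_PER_LITRE: float = 789.24

# usual drinking frequency -> occasions per week
FREQ_OCCASIONS_PER_WEEK: dict[str, float] = {
    "never": 0.0,
    "<weekly": 0.5,
    "1-2/wk": 1.5,
    "3-4/wk": 3.5,
    "5-6/wk": 5.5,
    "daily": 7.0,
}

# usual quantity per occasion -> standard drinks ("13+" assigned 14)
QTY_DRINKS_PER_OCCASION: dict[str, float] = {
    "1-2": 1.5,
    "3-4": 3.5,
    "5-6": 5.5,
    "7-9": 8.0,
    "10-12": 11.0,
    "13+": 14.0,
}

# quantity categories that meet the binge definition (5+ drinks per occasion)
BINGE_QTY_CATEGORIES: frozenset[str] = frozenset({"5-6", "7-9", "10-12", "13+"})

SES_LEVELS: tuple[str, ...] = ("low", "middle", "high")
SEXES: tuple[str, ...] = ("male", "female")

# 20-year exposure age bands
EXPOSURE_AGE_BANDS: tuple[str, ...] = ("15-34", "35-54", "55+")

# 5-year mortality age groups, ages 15-19 through 85+
AGE_GROUPS_5Y: tuple[str, ...] = tuple(
    f"{lo}-{lo + 4}" for lo in range(15, 85, 5)
) + ("85+",)

BROADER_CATEGORIES: tuple[str, ...] = ("infectious", "chronic", "injuries")


def age_group_of(age: float) -> str:
    """5-year mortality age group for a completed age (15+)."""
    if age < 15:
        raise ValueError(f"age {age} below the adult (15+) population")
    if age >= 85:
        return "85+"
    lo = int(age) - (int(age) - 15) % 5
    return f"{lo}-{lo + 4}"


def band_of_age(age: float) -> str:
    """Exposure age band for a completed age (15+)."""
    if age < 15:
        raise ValueError(f"age {age} below the adult (15+) population")
    if age < 35:
        return "15-34"
    if age < 55:
        return "35-54"
    return "55+"


def band_of_age_group(age_group: str) -> str:
    """Exposure band a 5-year mortality age group maps onto.

    Membership is decided by the group's lower bound; 85+ maps to 55+.
    """
    lo = 85 if age_group == "85+" else int(age_group.split("-")[0])
    return band_of_age(lo)
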