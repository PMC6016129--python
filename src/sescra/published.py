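"""Published South Africa 2015 population statistics used as model inputs.

These are the printed national estimates the analysis is calibrated to:
adult (15+) population counts, drinking prevalences, mean consumption
among current drinkers, per-capita consumption, and the SES mortality
hazard ratios estimated from the Africa Centre demographic surveillance
cohort.  They are inputs in the same sense a life table is an input —
aggregate, public numbers — and are kept in one place so calibration is
auditable.

Keys are (ses, sex) with ses in {low, middle, high} and sex in
{male, female}.
"""

from __future__ import annotations

# adult (15+ years) population counts, South Africa 2015
POPULATION_15PLUS: dict[tuple[str, str], int] = {
    ("high", "male"): 5_838_935,
    ("middle", "male"): 6_030_496,
    ("low", "male"): 6_305_738,
    ("high", "female"): 7_081_701,
    ("middle", "female"): 6_828_503,
    ("low", "female"): 6_782_163,
}

# prevalence of lifetime abstention (proportion)
P_LIFETIME_ABSTAINER: dict[tuple[str, str], float] = {
    ("high", "male"): 0.354,
    ("middle", "male"): 0.367,
    ("low", "male"): 0.408,
    ("high", "female"): 0.586,
    ("middle", "female"): 0.708,
    ("low", "female"): 0.766,
}

# prevalence of current drinking (proportion), with 95% CI
P_CURRENT_DRINKER: dict[tuple[str, str], float] = {
    ("high", "male"): 0.505,
    ("middle", "male"): 0.478,
    ("low", "male"): 0.450,
    ("high", "female"): 0.285,
    ("middle", "female"): 0.178,
    ("low", "female"): 0.139,
}

CI_CURRENT_DRINKER: dict[tuple[str, str], tuple[float, float]] = {
    ("high", "male"): (0.460, 0.550),
    ("middle", "male"): (0.445, 0.512),
    ("low", "male"): (0.419, 0.481),
    ("high", "female"): (0.244, 0.327),
    ("middle", "female"): (0.154, 0.201),
    ("low", "female"): (0.120, 0.158),
}

# prevalence of binge drinking (5+ drinks per usual occasion; proportion)
P_BINGE_DRINKER: dict[tuple[str, str], float] = {
    ("high", "male"): 0.119,
    ("middle", "male"): 0.147,
    ("low", "male"): 0.135,
    ("high", "female"): 0.026,
    ("middle", "female"): 0.029,
    ("low", "female"): 0.027,
}

# mean grams of pure alcohol per day among current drinkers (SD in parens
# of the source table; SD is reproduced by the sex-specific SD/mean ratio)
MEAN_GPD_DRINKERS: dict[tuple[str, str], float] = {
    ("high", "male"): 47.7,
    ("middle", "male"): 65.6,
    ("low", "male"): 67.4,
    ("high", "female"): 20.3,
    ("middle", "female"): 29.4,
    ("low", "female"): 41.6,
}

SD_GPD_DRINKERS: dict[tuple[str, str], float] = {
    ("high", "male"): 55.9,
    ("middle", "male"): 76.8,
    ("low", "male"): 78.9,
    ("high", "female"): 25.6,
    ("middle", "female"): 36.9,
    ("low", "female"): 52.3,
}

# sex-specific SD/mean ratio of the gamma consumption model
GAMMA_SD_MEAN_RATIO: dict[str, float] = {"male": 1.171, "female": 1.258}

# adult per-capita consumption, litres of pure alcohol per year (WHO, 2015)
APC_LITRES: float = 9.5
# fraction of per-capita consumption assumed actually consumed
COVERAGE: float = 0.8

# all-cause deaths among adults (15+), South Africa 2015
TOTAL_DEATHS_ALL_CAUSE: int = 529_400

# total deaths by SES and sex (15+), with 95% UI dropped
TOTAL_DEATHS: dict[tuple[str, str], int] = {
    ("high", "male"): 48_469,
    ("middle", "male"): 95_873,
    ("low", "male"): 122_436,
    ("high", "female"): 44_289,
    ("middle", "female"): 92_189,
    ("low", "female"): 126_146,
}

# alcohol-attributable deaths by broader cause category, point estimates
ATTRIBUTABLE_DEATHS: dict[tuple[str, str], dict[str, int]] = {
    ("high", "male"): {"injuries": 1850, "infectious": 2051, "chronic": 2985},
    ("middle", "male"): {"injuries": 4334, "infectious": 4768, "chronic": 4205},
    ("low", "male"): {"injuries": 4600, "infectious": 18_311, "chronic": 5981},
    ("high", "female"): {"injuries": 320, "infectious": 601, "chronic": 1181},
    ("middle", "female"): {"injuries": 604, "infectious": 1171, "chronic": 1946},
    ("low", "female"): {"injuries": 627, "infectious": 6520, "chronic": 3240},
}

# printed per-column totals of the attributable-deaths table
ATTRIBUTABLE_TOTALS: dict[tuple[str, str], int] = {
    ("high", "male"): 6886,
    ("middle", "male"): 13_307,
    ("low", "male"): 28_892,
    ("high", "female"): 2102,
    ("middle", "female"): 3721,
    ("low", "female"): 10_387,
}

# national total attributable deaths and age-standardised rates per 100,000
TOTAL_ATTRIBUTABLE_DEATHS: int = 62_300
AGE_STD_RATE_PER_100K: dict[str, float] = {"low": 727.0, "middle": 377.0, "high": 163.0}

# all-cause mortality hazard ratios vs high SES (cohort, 95% CI)
HR_ALL_CAUSE: dict[str, tuple[float, float, float]] = {
    "low": (2.73, 2.30, 3.24),
    "middle": (2.07, 1.74, 2.46),
    "high": (1.0, 1.0, 1.0),
}

# sensitivity analysis (unprojected asset score): attributable deaths by SES
SENSITIVITY_ATTRIBUTABLE: dict[str, int] = {
    "high": 12_500,
    "middle": 17_200,
    "low": 32_600,
}
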