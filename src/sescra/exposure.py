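"""Survey-based alcohol exposure estimation.

Estimates, for every (SES, sex, age-band) subgroup: the prevalence of
lifetime abstention, former drinking, current drinking and binge
drinking; and the mean grams of pure alcohol per day among current
drinkers by the standard quantity-frequency approach.  Survey means are
then triangulated — rescaled by a single global factor so that the
population-weighted total matches a coverage-adjusted per-capita
consumption envelope, preserving relative differences between subgroups —
and the continuous consumption distribution among drinkers is
parameterised as a gamma with a sex-specific SD/mean ratio.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .codebooks import (
    BINGE_QTY_CATEGORIES,
    ETHANOL_GRAMS_PER_LITRE,
    EXPOSURE_AGE_BANDS,
    FREQ_OCCASIONS_PER_WEEK,
    GRAMS_PER_STANDARD_DRINK,
    QTY_DRINKS_PER_OCCASION,
    SES_LEVELS,
    SEXES,
    band_of_age,
)
from .published import GAMMA_SD_MEAN_RATIO


@dataclass(frozen=True)
class ConsumptionEnvelope:
    """Coverage-adjusted adult per-capita consumption target."""

    apc_litres: float = 9.5
    coverage: float = 0.8
    density_g_per_litre: float = ETHANOL_GRAMS_PER_LITRE

    def __post_init__(self) -> None:
        if self.apc_litres <= 0:
            raise ValueError("apc_litres must be positive")
        if not 0 < self.coverage <= 1:
            raise ValueError("coverage must be in (0, 1]")

    @property
    def target_gpd_per_capita(self) -> float:
        """Grams of pure alcohol per adult per day implied by the envelope."""
        return self.coverage * self.apc_litres * self.density_g_per_litre / 365.0


@dataclass
class ExposureProfile:
    """Drinking exposure for one (SES, sex, age-band) subgroup.

    ``age_band`` may be None for analyses at (SES, sex) resolution.
    """

    ses: str
    sex: str
    age_band: str | None
    p_abstainer: float
    p_former: float
    p_current: float
    p_binge: float
    mean_gpd: float
    sd_gpd: float = float("nan")
    gamma_shape: float = float("nan")
    gamma_scale: float = float("nan")
    se_p_abstainer: float = 0.0
    se_p_current: float = 0.0
    se_p_binge: float = 0.0
    se_mean_gpd: float = 0.0
    n_effective: float = float("nan")
    missing: bool = False

    def key(self) -> tuple:
        if self.age_band is None:
            return (self.ses, self.sex)
        return (self.ses, self.sex, self.age_band)

    def validate(self) -> None:
        if abs(self.p_abstainer + self.p_former + self.p_current - 1.0) > 1e-9:
            raise ValueError(f"{self.key()}: drinking-status proportions do not sum to 1")
        if self.p_binge > self.p_current + 1e-12:
            raise ValueError(f"{self.key()}: p_binge exceeds p_current")
        if self.p_current > 0 and not self.mean_gpd > 0:
            raise ValueError(f"{self.key()}: positive drinking prevalence needs mean_gpd > 0")


def grams_per_day(
    freq_cat: str,
    qty_cat: str,
    grams_per_drink: float = GRAMS_PER_STANDARD_DRINK,
) -> float:
    """Quantity-frequency grams of pure alcohol per day.

    occasions/week midpoint x drinks/occasion midpoint x grams per drink / 7.
    """
    try:
        occ = FREQ_OCCASIONS_PER_WEEK[freq_cat]
    except KeyError:
        raise KeyError(f"unknown frequency category {freq_cat!r}") from None
    try:
        drinks = QTY_DRINKS_PER_OCCASION[qty_cat]
    except KeyError:
        raise KeyError(f"unknown quantity category {qty_cat!r}") from None
    return occ * drinks * grams_per_drink / 7.0


def _weighted_mean_se(values: np.ndarray, weights: np.ndarray) -> tuple[float, float, float]:
    """Weighted mean, its SE (effective-n), and the effective sample size."""
    wsum = weights.sum()
    mean = float((weights * values).sum() / wsum)
    n_eff = float(wsum**2 / (weights**2).sum())
    var = float((weights * (values - mean) ** 2).sum() / wsum)
    se = np.sqrt(var / n_eff) if n_eff > 1 else float("nan")
    return mean, se, n_eff


def _prevalence(indicator: np.ndarray, weights: np.ndarray) -> tuple[float, float]:
    wsum = weights.sum()
    p = float((weights * indicator).sum() / wsum)
    n_eff = wsum**2 / (weights**2).sum()
    se = float(np.sqrt(max(p * (1 - p), 0.0) / n_eff))
    return p, se


def subgroup_profiles(
    survey: pd.DataFrame,
    ses_labels: Sequence[str] | None = None,
    grams_per_drink: float = GRAMS_PER_STANDARD_DRINK,
    by_age_band: bool = True,
) -> list[ExposureProfile]:
    """Weighted exposure profiles per (SES, sex[, age band]) subgroup.

    ``survey`` needs columns age, sex, weight, drink_status
    (abstainer|former|current), freq_cat, qty_cat, and an ``ses`` column
    unless labels are passed separately.  Binge status is derived from the
    quantity category (5+ drinks per usual occasion).  Empty subgroups are
    returned flagged as missing.
    """
    df = survey.copy()
    if ses_labels is not None:
        df["ses"] = np.asarray(ses_labels)
    if (df["weight"] <= 0).any():
        raise ValueError("survey weights must be positive")
    df["gpd"] = [
        grams_per_day(f, q, grams_per_drink)
        for f, q in zip(df["freq_cat"], df["qty_cat"])
    ]
    df["_band"] = [band_of_age(a) for a in df["age"]] if by_age_band else None

    bands: tuple = EXPOSURE_AGE_BANDS if by_age_band else (None,)
    out: list[ExposureProfile] = []
    for ses in SES_LEVELS:
        for sex in SEXES:
            for band in bands:
                mask = (df["ses"] == ses) & (df["sex"] == sex)
                if band is not None:
                    mask &= df["_band"] == band
                sub = df.loc[mask]
                if len(sub) == 0:
                    out.append(
                        ExposureProfile(
                            ses, sex, band, 1.0, 0.0, 0.0, 0.0, float("nan"),
                            missing=True,
                        )
                    )
                    continue
                w = sub["weight"].to_numpy(float)
                status = sub["drink_status"].to_numpy()
                p_abst, se_abst = _prevalence(status == "abstainer", w)
                p_cur, se_cur = _prevalence(status == "current", w)
                p_former = max(1.0 - p_abst - p_cur, 0.0)
                is_binge = (
                    (status == "current")
                    & sub["qty_cat"].isin(BINGE_QTY_CATEGORIES).to_numpy()
                )
                p_binge, se_binge = _prevalence(is_binge, w)
                drinkers = sub.loc[status == "current"]
                if len(drinkers):
                    mean_gpd, se_mean, n_eff = _weighted_mean_se(
                        drinkers["gpd"].to_numpy(float),
                        drinkers["weight"].to_numpy(float),
                    )
                else:
                    mean_gpd, se_mean, n_eff = float("nan"), 0.0, 0.0
                prof = ExposureProfile(
                    ses, sex, band,
                    p_abstainer=p_abst, p_former=p_former, p_current=p_cur,
                    p_binge=min(p_binge, p_cur),
                    mean_gpd=mean_gpd,
                    se_p_abstainer=se_abst, se_p_current=se_cur,
                    se_p_binge=se_binge, se_mean_gpd=se_mean,
                    n_effective=n_eff,
                )
                out.append(prof)
    return out


def triangulate(
    profiles: Iterable[ExposureProfile],
    population_counts: Mapping[tuple, float],
    envelope: ConsumptionEnvelope,
) -> tuple[list[ExposureProfile], float]:
    """Rescale subgroup means so total consumption matches the envelope.

    A single scale factor c is applied to every subgroup's mean so that
    sum_g N_g p_current,g (c mean_g) equals the coverage-adjusted
    per-capita target times the total population; relative quantities
    between subgroups are unchanged.  Returns the rescaled profiles
    (with gamma parameters refreshed) and c.
    """
    profiles = list(profiles)
    n_total = 0.0
    implied = 0.0
    for p in profiles:
        n_g = float(population_counts[p.key()])
        n_total += n_g
        if p.p_current > 0 and not p.missing:
            implied += n_g * p.p_current * p.mean_gpd
    if implied <= 0:
        raise ValueError("zero survey-implied consumption; cannot triangulate")
    target_total = envelope.target_gpd_per_capita * n_total
    c = target_total / implied
    out = []
    for p in profiles:
        if p.missing or not p.p_current > 0:
            out.append(replace(p))
            continue
        new = replace(p, mean_gpd=c * p.mean_gpd, se_mean_gpd=c * p.se_mean_gpd)
        out.append(with_gamma(new))
    return out, c


def implied_per_capita_litres(
    profiles: Iterable[ExposureProfile],
    population_counts: Mapping[tuple, float],
    density_g_per_litre: float = ETHANOL_GRAMS_PER_LITRE,
) -> float:
    """Population-weighted litres of pure alcohol per adult per year."""
    n_total = 0.0
    grams_per_day_total = 0.0
    for p in profiles:
        n_g = float(population_counts[p.key()])
        n_total += n_g
        if p.p_current > 0 and not p.missing:
            grams_per_day_total += n_g * p.p_current * p.mean_gpd
    return grams_per_day_total / n_total * 365.0 / density_g_per_litre


def gamma_params(mean_gpd: float, sex: str) -> tuple[float, float]:
    """Gamma (shape, scale) for drinker consumption by moment matching.

    SD is the sex-specific ratio times the mean, so the shape depends on
    sex only: shape = (mean/sd)^2, scale = sd^2/mean.
    """
    if not mean_gpd > 0:
        raise ValueError("mean_gpd must be positive")
    ratio = GAMMA_SD_MEAN_RATIO[sex]
    sd = ratio * mean_gpd
    shape = (mean_gpd / sd) ** 2
    scale = sd**2 / mean_gpd
    return shape, scale


def with_gamma(profile: ExposureProfile) -> ExposureProfile:
    """Profile with sd/gamma fields filled from its mean and sex."""
    if profile.missing or not profile.p_current > 0:
        return replace(profile)
    shape, scale = gamma_params(profile.mean_gpd, profile.sex)
    return replace(
        profile,
        sd_gpd=GAMMA_SD_MEAN_RATIO[profile.sex] * profile.mean_gpd,
        gamma_shape=shape,
        gamma_scale=scale,
    )


def profiles_to_frame(profiles: Iterable[ExposureProfile]) -> pd.DataFrame:
    rows = []
    for p in profiles:
        rows.append(
            dict(
                ses=p.ses, sex=p.sex, age_band=p.age_band or "",
                p_abst=p.p_abstainer, p_former=p.p_former,
                p_current=p.p_current, p_binge=p.p_binge,
                mean_gpd=p.mean_gpd, sd_gpd=p.sd_gpd,
                gamma_shape=p.gamma_shape, gamma_scale=p.gamma_scale,
                se_p_abst=p.se_p_abstainer, se_p_current=p.se_p_current,
                se_p_binge=p.se_p_binge, se_mean_gpd=p.se_mean_gpd,
                n_effective=p.n_effective, missing=p.missing,
            )
        )
    return pd.DataFrame(rows)
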