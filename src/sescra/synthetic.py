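"""Synthetic survey, cohort, and national death-count generators.

The study's microdata (a national income-dynamics household survey and a
demographic-surveillance open cohort) are restricted; this module
generates stand-ins with the statistical structure the analysis assumes,
calibrated by default to the published South Africa 2015 population
statistics.  Everything downstream — asset scoring, exposure estimation,
hazard-ratio estimation, death splitting — is therefore testable end to
end, including parameter recovery against the generating truth.

What is emulated: SES-graded asset ownership (10 binary items with a
logistic ownership gradient in the latent SES tertile); drinking status
and quantity-frequency reporting whose implied grams/day match the
subgroup mean in expectation; a rural/urban divide with the cohort drawn
from the (poorer) rural stratum, so that projecting the national tertile
cutoffs onto the cohort matters, as it does in the real data; exponential
cause-specific mortality with SES hazard ratios; and a deterministic
expected national death table.  Ground-truth columns are prefixed with an
underscore and never written to CSV.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .codebooks import (
    AGE_GROUPS_5Y,
    BINGE_QTY_CATEGORIES,
    FREQ_OCCASIONS_PER_WEEK,
    GRAMS_PER_STANDARD_DRINK,
    QTY_DRINKS_PER_OCCASION,
    SES_LEVELS,
    SEXES,
    age_group_of,
)
from . import published
from .published import GAMMA_SD_MEAN_RATIO
from .risk import CauseRegistry, load_default_risk_config

N_ASSETS = 10

# per-item logistic intercepts (spread so items range from common to rare)
# and slope per latent-SES step (low=-1, middle=0, high=+1); the gradient
# is strong enough that the MCA score recovers the generating tertile for
# the large majority of records (>90% agreement at survey scale)
_ASSET_INTERCEPTS = np.linspace(-2.0, 2.0, N_ASSETS)
_ASSET_SLOPE = 3.0

# probability a record is rural given its latent SES (poorer => more rural)
_P_RURAL = {"low": 0.6, "middle": 0.4, "high": 0.2}

# default 5-year age-group population shares (young-skewed pyramid)
_DEFAULT_AGE_SHAPE = np.exp(-0.25 * np.arange(len(AGE_GROUPS_5Y)))
DEFAULT_AGE_GROUP_WEIGHTS = dict(
    zip(AGE_GROUPS_5Y, _DEFAULT_AGE_SHAPE / _DEFAULT_AGE_SHAPE.sum())
)

# relative age pattern of mortality (Gompertz-like increase, normalised
# against the age distribution so cause hazards are population averages)
_MORTALITY_AGE_SLOPE = 0.055

# default cause shares of total mortality (sums to 1); HIV-dominant
# pattern with a large chronic block and a visible injury share
DEFAULT_CAUSE_SHARES: dict[str, float] = {
    "hiv_aids": 0.28,
    "tuberculosis": 0.07,
    "lower_respiratory_infections": 0.05,
    "oral_cavity_pharynx_cancer": 0.01,
    "oesophagus_cancer": 0.02,
    "liver_cancer": 0.01,
    "larynx_cancer": 0.005,
    "breast_cancer": 0.02,
    "diabetes_mellitus": 0.06,
    "epilepsy": 0.01,
    "hypertensive_heart_disease": 0.04,
    "ischemic_heart_disease": 0.07,
    "ischemic_stroke": 0.05,
    "hemorrhagic_stroke": 0.04,
    "liver_cirrhosis": 0.02,
    "pancreatitis": 0.005,
    "road_injuries": 0.06,
    "intentional_injuries": 0.05,
    "other_unintentional_injuries": 0.02,
}
_OTHER = sum(DEFAULT_CAUSE_SHARES.values())  # remainder is non-alcohol-related
assert _OTHER <= 1.0


@dataclass
class SyntheticScenario:
    """Generating truth for the synthetic world.

    Defaults reproduce the published 2015 adult population counts,
    drinking prevalences and drinker means per (SES, sex), the all-cause
    SES mortality gradient (hazard ratios 2.73 low and 2.07 middle vs
    high), and a national all-cause death envelope of ~529,400.
    """

    population_counts: dict[tuple[str, str], int] = field(
        default_factory=lambda: dict(published.POPULATION_15PLUS)
    )
    p_abstainer: dict[tuple[str, str], float] = field(
        default_factory=lambda: dict(published.P_LIFETIME_ABSTAINER)
    )
    p_current: dict[tuple[str, str], float] = field(
        default_factory=lambda: dict(published.P_CURRENT_DRINKER)
    )
    p_binge: dict[tuple[str, str], float] = field(
        default_factory=lambda: dict(published.P_BINGE_DRINKER)
    )
    mean_gpd: dict[tuple[str, str], float] = field(
        default_factory=lambda: dict(published.MEAN_GPD_DRINKERS)
    )
    hr_by_cause_category: dict[str, dict[str, float]] = field(
        default_factory=lambda: {
            cat: {"low": 2.73, "middle": 2.07, "high": 1.0}
            for cat in ("infectious", "chronic", "injuries", "all")
        }
    )
    baseline_hazards: dict[str, float] = field(default_factory=dict)
    age_group_weights: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_AGE_GROUP_WEIGHTS)
    )
    underreporting_factor: float = 0.4
    total_death_envelope: float = float(published.TOTAL_DEATHS_ALL_CAUSE)
    seed: int = 0
    registry: CauseRegistry = field(
        default_factory=lambda: load_default_risk_config()[0]
    )

    def __post_init__(self) -> None:
        if not self.baseline_hazards:
            self.baseline_hazards = self._calibrated_hazards()
        self.validate()

    # -- validation ---------------------------------------------------
    def p_former(self, key: tuple[str, str]) -> float:
        return 1.0 - self.p_abstainer[key] - self.p_current[key]

    def validate(self) -> None:
        for key in self.population_counts:
            if self.population_counts[key] <= 0:
                raise ValueError(f"population count for {key} must be positive")
            probs = (
                self.p_abstainer[key],
                self.p_current[key],
                self.p_binge[key],
                self.p_former(key),
            )
            if any(p < -1e-12 or p > 1 for p in probs):
                raise ValueError(f"probability outside [0,1] for {key}")
            if abs(self.p_abstainer[key] + self.p_former(key) + self.p_current[key] - 1) > 1e-9:
                raise ValueError(f"drinking statuses for {key} do not sum to 1")
            if self.p_current[key] > 0 and not self.mean_gpd[key] > 0:
                raise ValueError(f"mean_gpd must be positive where drinking occurs ({key})")
            if self.p_binge[key] > self.p_current[key] + 1e-12:
                raise ValueError(f"p_binge exceeds p_current for {key}")
        if not 0 <= self.underreporting_factor <= 1:
            raise ValueError("underreporting_factor must lie in [0, 1]")
        if any(h < 0 for h in self.baseline_hazards.values()):
            raise ValueError("negative baseline hazard")

    # -- calibration --------------------------------------------------
    def _calibrated_hazards(self) -> dict[str, float]:
        """Cause hazards (per person-year, high-SES reference) scaled so
        the expected national death total equals the envelope."""
        shares = {
            c: DEFAULT_CAUSE_SHARES.get(c, 0.0) for c in self.registry.causes
        }
        # expected deaths with unit hazards, accounting for SES HRs
        total_pop_hr = {
            ses: sum(
                n for (s, _sex), n in self.population_counts.items() if s == ses
            )
            for ses in SES_LEVELS
        }
        denom = 0.0
        for cause, share in shares.items():
            cat = self.registry.category_of(cause)
            hrs = self.hr_by_cause_category.get(cat, {"low": 1, "middle": 1, "high": 1})
            denom += share * sum(total_pop_hr[s] * hrs[s] for s in SES_LEVELS)
        if denom <= 0:
            return {c: 0.0 for c in self.registry.causes}
        scale = self.total_death_envelope / denom
        return {c: shares[c] * scale for c in self.registry.causes}

    # -- helpers ------------------------------------------------------
    def cell_probs(self) -> tuple[list[tuple[str, str]], np.ndarray]:
        keys = [(ses, sex) for ses in SES_LEVELS for sex in SEXES]
        n = np.array([self.population_counts[k] for k in keys], float)
        return keys, n / n.sum()

    def rng(self, stream: int) -> np.random.Generator:
        return np.random.default_rng([int(self.seed) % 2**31, stream])


# ---------------------------------------------------------------------
# asset indicators


def _draw_assets(rng: np.random.Generator, ses_idx: np.ndarray) -> np.ndarray:
    """10 binary items; ownership probability logistic in latent SES.

    ses_idx: 0=low, 1=middle, 2=high.
    """
    s = ses_idx.astype(float) - 1.0  # -1, 0, +1
    logits = _ASSET_INTERCEPTS[None, :] + _ASSET_SLOPE * s[:, None]
    p = 1.0 / (1.0 + np.exp(-logits))
    return (rng.random(p.shape) < p).astype(int)


ASSET_COLUMNS = [f"asset_{i}" for i in range(1, N_ASSETS + 1)]


# ---------------------------------------------------------------------
# quantity-frequency assignment

_NONZERO_FREQS = [f for f, occ in FREQ_OCCASIONS_PER_WEEK.items() if occ > 0]
_FREQ_OCC = np.array([FREQ_OCCASIONS_PER_WEEK[f] for f in _NONZERO_FREQS])
_BINGE_QTYS = [q for q in QTY_DRINKS_PER_OCCASION if q in BINGE_QTY_CATEGORIES]
_NONBINGE_QTYS = [q for q in QTY_DRINKS_PER_OCCASION if q not in BINGE_QTY_CATEGORIES]


def _assign_qf(
    rng: np.random.Generator, reported_gpd: float, binge: bool
) -> tuple[str, str]:
    """Frequency/quantity categories for a reported grams/day value.

    The quantity category is constrained by binge status (5+ vs <5 drinks
    per occasion); the frequency category is then chosen by randomising
    between the two categories bracketing the required occasions/week, so
    the implied grams/day is unbiased for the reported value wherever the
    codebook range permits.
    """
    qtys = _BINGE_QTYS if binge else _NONBINGE_QTYS
    best = None
    for q in qtys:
        drinks = QTY_DRINKS_PER_OCCASION[q]
        occ_needed = reported_gpd * 7.0 / (GRAMS_PER_STANDARD_DRINK * drinks)
        # prefer a quantity whose needed frequency is representable
        if _FREQ_OCC[0] <= occ_needed <= _FREQ_OCC[-1]:
            best = (q, occ_needed)
            break
        best = best or (q, occ_needed)
    if best is None or best[1] > _FREQ_OCC[-1]:
        # even daily at the largest quantity under-represents: take the max
        q = qtys[-1]
        drinks = QTY_DRINKS_PER_OCCASION[q]
        occ_needed = reported_gpd * 7.0 / (GRAMS_PER_STANDARD_DRINK * drinks)
        if occ_needed >= _FREQ_OCC[-1]:
            return "daily", q
        best = (q, occ_needed)
    q, occ_needed = best
    if occ_needed <= _FREQ_OCC[0]:
        return _NONZERO_FREQS[0], q
    j = int(np.searchsorted(_FREQ_OCC, occ_needed, side="right"))
    lo, hi = _FREQ_OCC[j - 1], _FREQ_OCC[j]
    p_hi = (occ_needed - lo) / (hi - lo)
    pick = j if rng.random() < p_hi else j - 1
    return _NONZERO_FREQS[pick], q


# ---------------------------------------------------------------------
# generators


def generate_survey(
    scenario: SyntheticScenario, n_respondents: int
) -> pd.DataFrame:
    """Synthetic national survey of drinking and household assets.

    Columns: age, sex, weight, region, asset_1..asset_10, drink_status,
    freq_cat, qty_cat; plus ground-truth audit columns _latent_ses and
    _latent_gpd (grams/day before underreporting) that CSV writers drop.
    Weighted subgroup prevalences and reported means converge to the
    scenario values as n grows.
    """
    if n_respondents < 1:
        raise ValueError("n_respondents must be >= 1")
    rng = scenario.rng(1)
    keys, probs = scenario.cell_probs()
    cell = rng.choice(len(keys), size=n_respondents, p=probs)
    ses = np.array([keys[i][0] for i in cell])
    sex = np.array([keys[i][1] for i in cell])
    ses_idx = np.array([SES_LEVELS.index(s) for s in ses])

    groups = list(scenario.age_group_weights)
    gw = np.array([scenario.age_group_weights[g] for g in groups], float)
    gi = rng.choice(len(groups), size=n_respondents, p=gw / gw.sum())
    lo = np.array([85 if g == "85+" else int(g.split("-")[0]) for g in groups])
    age = lo[gi] + rng.random(n_respondents) * 5.0

    weight = rng.lognormal(mean=0.0, sigma=0.3, size=n_respondents)
    region = np.where(
        rng.random(n_respondents) < np.array([_P_RURAL[s] for s in ses]),
        "rural",
        "urban",
    )
    assets = _draw_assets(rng, ses_idx)

    status = np.empty(n_respondents, dtype=object)
    freq = np.full(n_respondents, "never", dtype=object)
    qty = np.full(n_respondents, "1-2", dtype=object)
    latent = np.zeros(n_respondents)
    for key in scenario.population_counts:
        mask = (ses == key[0]) & (sex == key[1])
        m = int(mask.sum())
        if m == 0:
            continue
        p = (scenario.p_abstainer[key], scenario.p_former(key), scenario.p_current[key])
        draw = rng.choice(3, size=m, p=np.clip(p, 0, 1) / np.sum(np.clip(p, 0, 1)))
        status[mask] = np.array(["abstainer", "former", "current"], dtype=object)[draw]
        cur_idx = np.flatnonzero(mask)[draw == 2]
        if cur_idx.size and scenario.p_current[key] > 0:
            ratio = GAMMA_SD_MEAN_RATIO[key[1]]
            shape = 1.0 / ratio**2
            scale = scenario.mean_gpd[key] * ratio**2
            x = rng.gamma(shape, scale, size=cur_idx.size)
            latent[cur_idx] = x
            # binge drinkers (5+ drinks per usual occasion) are the upper
            # tail of the consumption distribution: the threshold is the
            # (1 - binge share) quantile, so the binge prevalence and the
            # reported mean are both matched in expectation
            b_share = scenario.p_binge[key] / scenario.p_current[key]
            if b_share > 0:
                x_thresh = stats.gamma.ppf(1.0 - b_share, shape, scale=scale)
            else:
                x_thresh = np.inf
            binge = x > x_thresh
            y = scenario.underreporting_factor * x
            for i, idx in enumerate(cur_idx):
                f, q = _assign_qf(rng, y[i], bool(binge[i]))
                freq[idx], qty[idx] = f, q

    df = pd.DataFrame(
        dict(age=age, sex=sex, weight=weight, region=region)
        | {c: assets[:, i] for i, c in enumerate(ASSET_COLUMNS)}
        | dict(
            drink_status=status,
            freq_cat=freq,
            qty_cat=qty,
            _latent_ses=ses,
            _latent_gpd=latent,
        )
    )
    return df


def generate_cohort(
    scenario: SyntheticScenario,
    n_subjects: int,
    followup_years: float,
) -> pd.DataFrame:
    """Synthetic open-cohort records with SES-graded mortality.

    Subjects are drawn from the rural stratum of the national population
    (richer tertiles under-represented), carry asset indicators on the
    same items as the survey, and die from cause categories with
    exponential event times at hazard baseline x HR(SES); deaths are
    administratively censored at ``followup_years``.
    """
    if n_subjects < 1 or followup_years <= 0:
        raise ValueError("need positive cohort size and follow-up")
    if not scenario.baseline_hazards:
        raise ValueError("empty cause set")
    rng = scenario.rng(2)
    keys, probs = scenario.cell_probs()
    # rural sampling: reweight national cells by P(rural | ses)
    rural_p = probs * np.array([_P_RURAL[k[0]] for k in keys])
    rural_p /= rural_p.sum()
    cell = rng.choice(len(keys), size=n_subjects, p=rural_p)
    ses = np.array([keys[i][0] for i in cell])
    sex = np.array([keys[i][1] for i in cell])
    ses_idx = np.array([SES_LEVELS.index(s) for s in ses])
    assets = _draw_assets(rng, ses_idx)

    groups = list(scenario.age_group_weights)
    gw = np.array([scenario.age_group_weights[g] for g in groups], float)
    gi = rng.choice(len(groups), size=n_subjects, p=gw / gw.sum())
    lo = np.array([85 if g == "85+" else int(g.split("-")[0]) for g in groups])
    age0 = lo[gi] + rng.random(n_subjects) * 5.0

    causes = list(scenario.baseline_hazards)
    base = np.array([scenario.baseline_hazards[c] for c in causes])
    cats = [scenario.registry.category_of(c) if c in scenario.registry.broader
            else "all" for c in causes]
    hr_mat = np.array(
        [
            [
                scenario.hr_by_cause_category.get(cat, {}).get(s, 1.0)
                for s in SES_LEVELS
            ]
            for cat in cats
        ]
    )  # (n_causes, 3)
    subj_haz = base[None, :] * hr_mat[:, ses_idx].T  # (n, n_causes)
    total = subj_haz.sum(axis=1)
    with np.errstate(divide="ignore"):
        t_event = np.where(
            total > 0, rng.exponential(1.0, n_subjects) / np.where(total > 0, total, 1.0),
            np.inf,
        )
    event = t_event < followup_years
    exit_t = np.minimum(t_event, followup_years)
    cause_cat = np.full(n_subjects, "", dtype=object)
    if event.any():
        p_cause = subj_haz[event] / total[event, None]
        u = rng.random(event.sum())
        idx = (p_cause.cumsum(axis=1) < u[:, None]).sum(axis=1)
        cause_cat[event] = np.array(causes, dtype=object)[idx]

    return pd.DataFrame(
        dict(
            id=np.arange(n_subjects),
            entry=0.0,
            exit=exit_t,
            event=event.astype(int),
            cause_cat=cause_cat,
            age0=age0,
            sex=sex,
        )
        | {c: assets[:, i] for i, c in enumerate(ASSET_COLUMNS)}
        | {"_latent_ses": ses}
    )


def generate_death_table(scenario: SyntheticScenario) -> pd.DataFrame:
    """Deterministic expected national death counts, cause x sex x age.

    Counts are the scenario's implied expectations: population in each
    (sex, age) cell times the population-average cause hazard times a
    normalised Gompertz-like age multiplier, summed over SES with the
    scenario hazard ratios.  Marginal totals therefore equal the implied
    expected deaths exactly (the calibrated default hits the national
    all-cause envelope).
    """
    groups = list(AGE_GROUPS_5Y)
    age_w = np.array([scenario.age_group_weights[g] for g in groups], float)
    age_w = age_w / age_w.sum()
    mid = np.array([87.5 if g == "85+" else int(g.split("-")[0]) + 2.5 for g in groups])
    mult = np.exp(_MORTALITY_AGE_SLOPE * (mid - 50.0))
    mult = mult / (age_w * mult).sum()  # population-average multiplier = 1

    rows = []
    for cause, h in scenario.baseline_hazards.items():
        cat = (
            scenario.registry.category_of(cause)
            if cause in scenario.registry.broader
            else "all"
        )
        hrs = scenario.hr_by_cause_category.get(cat, {s: 1.0 for s in SES_LEVELS})
        for sex in SEXES:
            pop_ses = {
                s: scenario.population_counts[(s, sex)] for s in SES_LEVELS
            }
            for g, w, m in zip(groups, age_w, mult):
                count = sum(
                    pop_ses[s] * w * h * m * hrs[s] for s in SES_LEVELS
                )
                rows.append(dict(cause=cause, sex=sex, age_group=g, count=count))
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------
# CSV writers (ground-truth audit columns dropped)


def write_survey_csv(survey: pd.DataFrame, path: str | Path) -> None:
    cols = ["age", "sex", "weight", "region", *ASSET_COLUMNS,
            "drink_status", "freq_cat", "qty_cat"]
    survey[cols].to_csv(path, index=False)


def write_cohort_csv(cohort: pd.DataFrame, path: str | Path) -> None:
    cols = ["id", "entry", "exit", "event", "cause_cat", "age0", "sex",
            *ASSET_COLUMNS]
    cohort[cols].to_csv(path, index=False)


def write_deaths_csv(deaths: pd.DataFrame, path: str | Path) -> None:
    deaths[["cause", "sex", "age_group", "count"]].to_csv(path, index=False)
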