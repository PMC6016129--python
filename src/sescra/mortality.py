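"""SES hazard ratios, death-count splitting, and mortality rates.

Step 2 of the assessment: national death counts are only available by
cause, sex and 5-year age group, so cohort-estimated SES mortality
hazard ratios are used to disaggregate each cell across SES strata in
proportion to population share times hazard ratio.  Attributable deaths
are then the split counts times the subgroup AAFs.  Step 3 divides by
SES-split population counts and age-standardises with the WHO world
standard population.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter

from .codebooks import AGE_GROUPS_5Y, SES_LEVELS, band_of_age_group


@dataclass
class HazardRatioSet:
    """HRs per (cause category, SES) with 95% CIs; reference high = 1."""

    hr: dict[str, dict[str, tuple[float, float, float]]] = field(default_factory=dict)

    def add(self, category: str, entries: dict[str, tuple[float, float, float]]) -> None:
        entries = dict(entries)
        entries.setdefault("high", (1.0, 1.0, 1.0))
        for ses, (point, lo, hi) in entries.items():
            if point <= 0 or not lo <= point <= hi:
                raise ValueError(f"invalid HR for {category}/{ses}: {(point, lo, hi)}")
        self.hr[category] = entries

    def point(self, category: str, ses: str) -> float:
        return self.hr[category][ses][0]


def cox_hr(
    cohort: pd.DataFrame,
    cause_category: str | None = None,
    ses_col: str = "ses",
    registry=None,
) -> dict[str, tuple[float, float, float]]:
    """Low/middle-vs-high SES hazard ratios by Cox partial likelihood.

    Deaths from the requested cause category count as events; deaths from
    other causes are censored at their event time.  ``cause_category``
    None means all-cause.  Covariates: SES indicators (reference high),
    baseline age, sex.  Returns {ses: (hr, lo95, hi95)} including the
    reference.
    """
    df = cohort.copy()
    if cause_category is None or cause_category == "all":
        ev = df["event"].astype(bool)
    else:
        cats = df["cause_cat"].astype(str)
        if registry is not None:
            cats = cats.map(lambda c: registry.broader.get(c, c))
        ev = df["event"].astype(bool) & (cats == cause_category)
    if ev.sum() == 0:
        raise ValueError(f"no events for cause category {cause_category!r}")
    ses = df[ses_col].astype(str)
    present = set(ses[ev])
    if "high" not in set(ses):
        raise ValueError("reference (high SES) group absent")
    fit_df = pd.DataFrame(
        dict(
            duration=(df["exit"] - df["entry"]).astype(float),
            event=ev.astype(int),
            ses_low=(ses == "low").astype(float),
            ses_middle=(ses == "middle").astype(float),
            age0=df["age0"].astype(float),
            sex=(df["sex"] == "female").astype(float),
        )
    )
    cph = CoxPHFitter()
    cph.fit(fit_df, duration_col="duration", event_col="event")
    out: dict[str, tuple[float, float, float]] = {"high": (1.0, 1.0, 1.0)}
    ci = cph.confidence_intervals_
    for ses_level, cov in (("low", "ses_low"), ("middle", "ses_middle")):
        hr = float(np.exp(cph.params_[cov]))
        lo = float(np.exp(ci.loc[cov].iloc[0]))
        hi = float(np.exp(ci.loc[cov].iloc[1]))
        out[ses_level] = (hr, lo, hi)
    return out


def estimate_hazard_ratios(
    cohort: pd.DataFrame,
    registry,
    ses_col: str = "ses",
    categories: tuple[str, ...] = ("infectious", "chronic", "injuries", "all"),
) -> HazardRatioSet:
    """HazardRatioSet over broader cause categories (plus all-cause)."""
    hrs = HazardRatioSet()
    for cat in categories:
        entries = cox_hr(
            cohort, None if cat == "all" else cat, ses_col=ses_col, registry=registry
        )
        hrs.add(cat, entries)
    return hrs


def split_deaths(
    national: pd.DataFrame,
    ses_population_shares: pd.DataFrame,
    hrs: HazardRatioSet,
    registry,
) -> pd.DataFrame:
    """Disaggregate national death counts across SES strata.

    D(ses) = D_total * pi(ses) hr(ses) / sum_s' pi(s') hr(s') per
    (cause, sex, age group) cell; totals are conserved exactly.
    ``ses_population_shares``: columns sex, age_group, ses, share with
    shares summing to 1 per (sex, age_group).
    """
    shares = ses_population_shares.set_index(["sex", "age_group", "ses"])["share"]
    chk = shares.groupby(level=[0, 1]).sum()
    if not np.allclose(chk, 1.0, atol=1e-9):
        raise ValueError("SES population shares do not sum to 1 per (sex, age) cell")
    rows = []
    for _, row in national.iterrows():
        cat = registry.broader.get(row["cause"], "all")
        weights = {
            s: shares[(row["sex"], row["age_group"], s)] * hrs.point(cat, s)
            for s in SES_LEVELS
        }
        denom = sum(weights.values())
        for s in SES_LEVELS:
            rows.append(
                dict(
                    cause=row["cause"], sex=row["sex"], age_group=row["age_group"],
                    ses=s, count=row["count"] * weights[s] / denom,
                )
            )
    return pd.DataFrame(rows)


def split_population(
    populations: pd.DataFrame, ses_proportions: pd.DataFrame
) -> pd.DataFrame:
    """Population per (ses, sex, age group) from totals and proportions."""
    props = ses_proportions.set_index(["sex", "age_group", "ses"])["share"]
    if (props < 0).any():
        raise ValueError("negative SES proportion")
    rows = []
    for _, row in populations.iterrows():
        for s in SES_LEVELS:
            rows.append(
                dict(
                    ses=s, sex=row["sex"], age_group=row["age_group"],
                    population=row["population"] * props[(row["sex"], row["age_group"], s)],
                )
            )
    return pd.DataFrame(rows)


def attributable_deaths(
    split: pd.DataFrame, aafs: pd.DataFrame, registry=None
) -> pd.DataFrame:
    """Attributable death counts: split counts times matching AAFs.

    AAFs are resolved at (ses, sex, exposure band, cause), with 5-year
    age groups mapped onto the exposure bands by their lower bound.
    Counts stay real-valued; negative attributable counts are legitimate
    for net-protective strata.
    """
    df = split.copy()
    df["age_band"] = df["age_group"].map(band_of_age_group)
    merged = df.merge(
        aafs[["ses", "sex", "age_band", "cause", "aaf"]],
        on=["ses", "sex", "age_band", "cause"],
        how="left",
        validate="many_to_one",
    )
    if merged["aaf"].isna().any():
        missing = merged.loc[merged["aaf"].isna(), ["ses", "sex", "age_band", "cause"]]
        raise KeyError(
            "no AAF for cells:\n" + missing.drop_duplicates().to_string(index=False)
        )
    merged["attributable"] = merged["count"] * merged["aaf"]
    if registry is not None:
        merged["broader_category"] = merged["cause"].map(registry.broader)
    return merged.drop(columns=["age_band"])


def load_standard_population() -> pd.DataFrame:
    """WHO world standard weights renormalised over the 15+ age groups."""
    ref = resources.files("sescra.data").joinpath("who_standard_population.csv")
    with ref.open() as fh:
        std = pd.read_csv(fh, comment="#")
    std = std[std["age_group"].isin(AGE_GROUPS_5Y)].copy()
    std["weight"] = std["weight_pct"] / std["weight_pct"].sum()
    return std[["age_group", "weight"]]


def age_standardize(
    deaths: pd.DataFrame,
    populations: pd.DataFrame,
    standard: pd.DataFrame | None = None,
    group_cols: tuple[str, ...] = ("ses",),
    value_col: str = "attributable",
) -> pd.DataFrame:
    """Age-standardised rates per 100,000.

    rate = sum_a w_a (deaths_a / pop_a) * 100,000 per group, with w the
    standard weights over 5-year age groups.  Zero population with
    nonzero deaths in a cell is an error.
    """
    if standard is None:
        standard = load_standard_population()
    w = standard.set_index("age_group")["weight"]
    d = (
        deaths.groupby([*group_cols, "age_group"], as_index=False)[value_col].sum()
    )
    p = populations.groupby(
        [c for c in (*group_cols, "age_group") if c in populations.columns],
        as_index=False,
    )["population"].sum()
    m = d.merge(p, on=[c for c in (*group_cols, "age_group") if c in p.columns])
    bad = (m["population"] <= 0) & (m[value_col] != 0)
    if bad.any():
        raise ValueError("zero population with nonzero deaths")
    m["rate_a"] = np.where(
        m["population"] > 0, m[value_col] / m["population"], 0.0
    ) * m["age_group"].map(w)
    out = (
        m.groupby(list(group_cols), as_index=False)["rate_a"].sum()
        .rename(columns={"rate_a": "rate_per_100k"})
    )
    out["rate_per_100k"] *= 100_000
    return out
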