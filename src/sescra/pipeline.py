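"""End-to-end orchestration of the three calculation steps.

Step 1: asset scoring and tertiles on the survey; subgroup exposure
profiles; triangulation to the coverage-adjusted per-capita envelope;
AAFs per subgroup and cause.  Step 2: SES hazard ratios from the cohort
(with the cohort's asset score projected onto the national distribution,
or plain within-cohort tertiles for the sensitivity variant); national
death counts split by SES; attributable deaths.  Step 3: SES-split
populations, crude and WHO-age-standardised attributable mortality
rates.  Monte Carlo uncertainty propagation re-runs the parametric part
of the chain per draw.

All randomness flows from a single root seed split per stage.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import asset_score as ascore
from .attribution import aaf_array, aaf_table
from .codebooks import (
    AGE_GROUPS_5Y,
    EXPOSURE_AGE_BANDS,
    SES_LEVELS,
    SEXES,
    band_of_age,
    band_of_age_group,
)
from .exposure import (
    ConsumptionEnvelope,
    profiles_to_frame,
    subgroup_profiles,
    triangulate,
)
from .mortality import (
    HazardRatioSet,
    age_standardize,
    attributable_deaths,
    estimate_hazard_ratios,
    load_standard_population,
    split_deaths,
    split_population,
)
from .risk import RiskFunction, former_se_log, load_default_risk_config
from .synthetic import ASSET_COLUMNS, SyntheticScenario, generate_cohort, generate_death_table, generate_survey
from .uncertainty import MCSettings, MCResult, ParamSpec, monte_carlo

_HR_CATEGORIES = ("infectious", "chronic", "injuries", "all")


@dataclass
class RunConfig:
    """Inputs and switches for a full run.

    With a scenario, all inputs are generated; alternatively CSV paths
    may be supplied for survey/cohort/deaths/populations.  ``mode``
    selects the projected (main) or unprojected (sensitivity) asset
    score for the cohort.
    """

    scenario: SyntheticScenario | None = None
    survey_path: str | None = None
    cohort_path: str | None = None
    deaths_path: str | None = None
    populations_path: str | None = None
    risk_config_path: str | None = None
    n_survey: int = 22_741
    n_cohort: int = 87_029
    followup_years: float = 15.0
    envelope: ConsumptionEnvelope = field(default_factory=ConsumptionEnvelope)
    mode: str = "projected"  # or "unprojected"
    mc: MCSettings | None = None
    out_dir: str | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mode not in ("projected", "unprojected"):
            raise ValueError(f"unknown asset-score mode {self.mode!r}")
        for p in (self.survey_path, self.cohort_path, self.deaths_path,
                  self.populations_path, self.risk_config_path):
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(p)
        if self.scenario is None and self.survey_path is None:
            raise ValueError("need a scenario or input files")


@dataclass
class ResultBundle:
    """All tables a run produces."""

    profiles: pd.DataFrame
    triangulation_factor: float
    national_cutoffs: tuple[float, float]
    cohort_cutoffs: tuple[float, float]
    aafs: pd.DataFrame
    hazard_ratios: HazardRatioSet
    deaths_split: pd.DataFrame
    attributable: pd.DataFrame
    attributable_by_ses: pd.DataFrame
    attributable_by_ses_category: pd.DataFrame
    populations_split: pd.DataFrame
    rates_by_ses: pd.DataFrame
    rates_by_ses_sex: pd.DataFrame
    uncertainty: MCResult | None = None
    log: dict = field(default_factory=dict)


def _ses_shares_from_survey(survey: pd.DataFrame, min_cell: int = 10) -> pd.DataFrame:
    """Weighted SES shares per (sex, 5-year age group) from the survey.

    Sparse cells (< ``min_cell`` records) fall back to the sex-level
    shares so the split stays well defined at small survey sizes.
    """
    df = survey.copy()
    df["age_group"] = [
        "85+" if a >= 85 else f"{int(a) - (int(a) - 15) % 5}-{int(a) - (int(a) - 15) % 5 + 4}"
        for a in df["age"]
    ]
    sex_tot = df.groupby(["sex", "ses"])["weight"].sum().unstack(fill_value=0.0)
    sex_share = sex_tot.div(sex_tot.sum(axis=1), axis=0)
    rows = []
    for sex in SEXES:
        for g in AGE_GROUPS_5Y:
            cell = df[(df["sex"] == sex) & (df["age_group"] == g)]
            if len(cell) >= min_cell:
                tot = cell.groupby("ses")["weight"].sum()
                share = (tot / tot.sum()).reindex(SES_LEVELS).fillna(0.0)
            else:
                share = sex_share.loc[sex].reindex(SES_LEVELS).fillna(0.0)
            for s in SES_LEVELS:
                rows.append(dict(sex=sex, age_group=g, ses=s, share=float(share[s])))
    return pd.DataFrame(rows)


def _population_by_age(config: RunConfig) -> pd.DataFrame:
    """National population per (sex, 5-year age group)."""
    if config.populations_path is not None:
        return pd.read_csv(config.populations_path)
    sc = config.scenario
    w = pd.Series(sc.age_group_weights)
    w = w / w.sum()
    rows = []
    for sex in SEXES:
        total = sum(sc.population_counts[(s, sex)] for s in SES_LEVELS)
        for g in AGE_GROUPS_5Y:
            rows.append(dict(sex=sex, age_group=g, population=total * w[g]))
    return pd.DataFrame(rows)


def _band_population(
    survey: pd.DataFrame, population_counts: dict[tuple[str, str], int]
) -> dict[tuple, float]:
    """Population per (ses, sex, band), spreading the (ses, sex) totals
    over exposure bands by the survey's weighted band shares."""
    df = survey.copy()
    df["band"] = [band_of_age(a) for a in df["age"]]
    out: dict[tuple, float] = {}
    for (ses, sex), total in population_counts.items():
        sub = df[(df["ses"] == ses) & (df["sex"] == sex)]
        if len(sub):
            shares = sub.groupby("band")["weight"].sum()
            shares = (shares / shares.sum()).reindex(EXPOSURE_AGE_BANDS).fillna(0.0)
        else:
            shares = pd.Series(1 / 3, index=EXPOSURE_AGE_BANDS)
        for band in EXPOSURE_AGE_BANDS:
            out[(ses, sex, band)] = total * float(shares[band])
    return out


def run_main(config: RunConfig) -> ResultBundle:
    """Execute the full assessment; deterministic under a fixed seed."""
    sc = config.scenario
    if sc is not None and config.seed != sc.seed:
        sc = replace_seed(sc, config.seed)

    # ---- inputs ------------------------------------------------------
    if config.survey_path is not None:
        survey = pd.read_csv(config.survey_path)
    else:
        survey = generate_survey(sc, config.n_survey)
    if config.cohort_path is not None:
        cohort = pd.read_csv(config.cohort_path)
    else:
        cohort = generate_cohort(sc, config.n_cohort, config.followup_years)
    if config.deaths_path is not None:
        national = pd.read_csv(config.deaths_path)
    else:
        national = generate_death_table(sc)
    if config.risk_config_path is not None:
        from .risk import load_risk_config

        registry, riskfns = load_risk_config(config.risk_config_path)
    else:
        registry, riskfns = load_default_risk_config()
    population_counts = dict(sc.population_counts) if sc is not None else None
    if population_counts is None:
        raise ValueError("file-based population totals per (ses, sex) not provided")

    # ---- step 1: asset score, exposure, AAFs -------------------------
    scores = ascore.mca_score(survey[ASSET_COLUMNS])
    national_split = ascore.tertile_split(scores, survey["weight"].to_numpy(float))
    survey = survey.copy()
    survey["ses"] = national_split.label

    profiles = subgroup_profiles(survey)
    band_pop = _band_population(survey, population_counts)
    if any(p.p_current > 0 and not p.missing for p in profiles):
        profiles, c_factor = triangulate(profiles, band_pop, config.envelope)
    else:
        # an all-abstainer world has nothing to triangulate
        c_factor = float("nan")
    aafs = aaf_table(profiles, registry, riskfns)

    # ---- step 2: cohort SES, HRs, death splitting --------------------
    cohort = cohort.copy()
    cohort_scores = ascore.mca_score(cohort[ASSET_COLUMNS])
    if config.mode == "projected":
        if "region" in survey.columns:
            ref_mask = (survey["region"] == "rural").to_numpy()
        else:
            ref_mask = np.ones(len(survey), dtype=bool)
        cutoffs = ascore.project_cutoffs(
            scores[ref_mask],
            survey.loc[ref_mask, "weight"].to_numpy(float),
            national_split.cutoffs,
            cohort_scores,
        )
        cohort["ses"] = ascore.labels_from_cutoffs(cohort_scores, cutoffs)
    else:
        split = ascore.tertile_split(cohort_scores)
        cutoffs = split.cutoffs
        cohort["ses"] = split.label

    hrs = estimate_hazard_ratios(cohort, registry)
    shares = _ses_shares_from_survey(survey)
    deaths_split = split_deaths(national, shares, hrs, registry)
    attrib = attributable_deaths(deaths_split, aafs, registry)

    # ---- step 3: populations, rates ----------------------------------
    pop_age = _population_by_age(config)
    pop_split = split_population(pop_age, shares)
    std = load_standard_population()
    rates_ses = age_standardize(attrib, pop_split, std, group_cols=("ses",))
    rates_ses_sex = age_standardize(attrib, pop_split, std, group_cols=("ses", "sex"))

    by_ses = (
        attrib.groupby("ses", as_index=False)["attributable"].sum()
    )
    by_ses_cat = (
        attrib.groupby(["ses", "broader_category"], as_index=False)["attributable"].sum()
    )

    # ---- uncertainty -------------------------------------------------
    mc_result = None
    if config.mc is not None:
        engine = BurdenEngine(
            profiles, registry, riskfns, hrs, national, shares, pop_split, std
        )
        mc_result = monte_carlo(engine.evaluate, engine.specs(), config.mc)

    bundle = ResultBundle(
        profiles=profiles_to_frame(profiles),
        triangulation_factor=c_factor,
        national_cutoffs=national_split.cutoffs,
        cohort_cutoffs=cutoffs,
        aafs=aafs,
        hazard_ratios=hrs,
        deaths_split=deaths_split,
        attributable=attrib,
        attributable_by_ses=by_ses,
        attributable_by_ses_category=by_ses_cat,
        populations_split=pop_split,
        rates_by_ses=rates_ses,
        rates_by_ses_sex=rates_ses_sex,
        uncertainty=mc_result,
        log=_run_log(config),
    )
    if config.out_dir is not None:
        write_bundle(bundle, config.out_dir)
    return bundle


def run_sensitivity(config: RunConfig) -> ResultBundle:
    """Main pipeline with the unprojected within-cohort tertile score."""
    cfg = replace_mode(config, "unprojected")
    return run_main(cfg)


def replace_mode(config: RunConfig, mode: str) -> RunConfig:
    from dataclasses import replace

    return replace(config, mode=mode)


def replace_seed(scenario: SyntheticScenario, seed: int) -> SyntheticScenario:
    from dataclasses import replace

    return replace(scenario, seed=seed)


def _run_log(config: RunConfig) -> dict:
    scalars = dict(
        apc_litres=config.envelope.apc_litres,
        coverage=config.envelope.coverage,
        density=config.envelope.density_g_per_litre,
        mode=config.mode,
        seed=config.seed,
        n_survey=config.n_survey,
        n_cohort=config.n_cohort,
        followup_years=config.followup_years,
    )
    digest = hashlib.sha256(
        json.dumps(scalars, sort_keys=True).encode()
    ).hexdigest()[:16]
    return dict(config_hash=digest, **scalars)


def write_bundle(bundle: ResultBundle, out_dir: str | Path) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    bundle.profiles.to_csv(out / "exposure_profiles.csv", index=False)
    bundle.aafs.to_csv(out / "aaf_table.csv", index=False)
    bundle.deaths_split.to_csv(out / "deaths_split.csv", index=False)
    bundle.attributable.to_csv(out / "attributable_deaths.csv", index=False)
    bundle.attributable_by_ses.to_csv(out / "attributable_by_ses.csv", index=False)
    bundle.attributable_by_ses_category.to_csv(
        out / "attributable_by_ses_category.csv", index=False
    )
    bundle.populations_split.to_csv(out / "populations_split.csv", index=False)
    bundle.rates_by_ses.to_csv(out / "rates_by_ses.csv", index=False)
    bundle.rates_by_ses_sex.to_csv(out / "rates_by_ses_sex.csv", index=False)
    hr_rows = [
        dict(category=cat, ses=s, hr=v[0], lo=v[1], hi=v[2])
        for cat, d in bundle.hazard_ratios.hr.items()
        for s, v in d.items()
    ]
    pd.DataFrame(hr_rows).to_csv(out / "hazard_ratios.csv", index=False)
    with open(out / "run_log.json", "w") as fh:
        json.dump(bundle.log, fh, indent=2)
    if bundle.uncertainty is not None:
        rows = []
        for k in bundle.uncertainty.point:
            pt = bundle.uncertainty.point[k]
            lo = bundle.uncertainty.lower[k]
            hi = bundle.uncertainty.upper[k]
            for i in range(pt.size):
                rows.append(
                    dict(quantity=k, index=i, point=pt[i], lower=lo[i], upper=hi[i])
                )
        pd.DataFrame(rows).to_csv(out / "uncertainty_intervals.csv", index=False)


# ---------------------------------------------------------------------
# Monte Carlo engine


class BurdenEngine:
    """Vectorised Step 1->3 chain as a pure function of a parameter draw.

    Precomputes every fixed input (national death counts, population
    shares and counts, standard weights, age-band mapping, subgroup
    index) so a draw only re-evaluates AAF integrals, the HR-based
    split, and the rate aggregation.  National death counts are treated
    as fixed by default.
    """

    def __init__(
        self, profiles, registry, riskfns, hrs, national, shares, pop_split, std
    ) -> None:
        self.registry = registry
        self.riskfns = riskfns
        self.subgroups = [
            (ses, sex, band)
            for ses in SES_LEVELS
            for sex in SEXES
            for band in EXPOSURE_AGE_BANDS
        ]
        pmap = {p.key(): p for p in profiles}
        self.profiles = [pmap[k] for k in self.subgroups]
        self.ses_of_subgroup = np.array([k[0] for k in self.subgroups], dtype=object)
        self.sex_ratio = np.array(
            [1.171 if k[1] == "male" else 1.258 for k in self.subgroups]
        )
        self.sub_index = {k: i for i, k in enumerate(self.subgroups)}

        causes = list(registry.causes)
        self.causes = causes
        self.cat_idx = {c: _HR_CATEGORIES.index(registry.category_of(c)) for c in causes}
        n_age = len(AGE_GROUPS_5Y)
        self.deaths = np.zeros((len(causes), len(SEXES), n_age))
        nat = national.set_index(["cause", "sex", "age_group"])["count"]
        for ci, c in enumerate(causes):
            for si, sx in enumerate(SEXES):
                for ai, g in enumerate(AGE_GROUPS_5Y):
                    self.deaths[ci, si, ai] = nat.get((c, sx, g), 0.0)
        sh = shares.set_index(["sex", "age_group", "ses"])["share"]
        self.share = np.zeros((len(SES_LEVELS), len(SEXES), n_age))
        for li, ses in enumerate(SES_LEVELS):
            for si, sx in enumerate(SEXES):
                for ai, g in enumerate(AGE_GROUPS_5Y):
                    self.share[li, si, ai] = sh.get((sx, g, ses), 0.0)
        pop = pop_split.set_index(["ses", "sex", "age_group"])["population"]
        self.pop = np.zeros_like(self.share)
        for li, ses in enumerate(SES_LEVELS):
            for si, sx in enumerate(SEXES):
                for ai, g in enumerate(AGE_GROUPS_5Y):
                    self.pop[li, si, ai] = pop.get((ses, sx, g), 0.0)
        self.std_w = np.array(
            [std.set_index("age_group")["weight"][g] for g in AGE_GROUPS_5Y]
        )
        self.band_idx = np.array(
            [EXPOSURE_AGE_BANDS.index(band_of_age_group(g)) for g in AGE_GROUPS_5Y]
        )
        # subgroup index per (ses, sex, age-band) triple for AAF lookup
        self.sub_of = np.zeros((len(SES_LEVELS), len(SEXES), n_age), dtype=int)
        for li, ses in enumerate(SES_LEVELS):
            for si, sx in enumerate(SEXES):
                for ai in range(n_age):
                    band = EXPOSURE_AGE_BANDS[self.band_idx[ai]]
                    self.sub_of[li, si, ai] = self.sub_index[(ses, sx, band)]
        self.hr_central = np.ones((len(_HR_CATEGORIES), len(SES_LEVELS)))
        self.hr_ci = (
            np.ones_like(self.hr_central),
            np.ones_like(self.hr_central),
        )
        for ci, cat in enumerate(_HR_CATEGORIES):
            for li, ses in enumerate(SES_LEVELS):
                point, lo, hi = hrs.hr[cat][ses]
                self.hr_central[ci, li] = point
                self.hr_ci[0][ci, li] = lo
                self.hr_ci[1][ci, li] = hi

    # -- parameter specs ----------------------------------------------
    def specs(self) -> dict[str, ParamSpec]:
        pr = self.profiles
        specs: dict[str, ParamSpec] = {
            "p_abstainer": ParamSpec(
                np.array([p.p_abstainer for p in pr]), "logit",
                se=np.array([p.se_p_abstainer for p in pr]),
            ),
            "p_current": ParamSpec(
                np.array([p.p_current for p in pr]), "logit",
                se=np.array([p.se_p_current for p in pr]),
            ),
            "p_binge": ParamSpec(
                np.array([p.p_binge for p in pr]), "logit",
                se=np.array([p.se_p_binge for p in pr]),
            ),
            "mean_gpd": ParamSpec(
                np.array([p.mean_gpd if p.p_current > 0 else 0.0 for p in pr]),
                "truncated_normal",
                se=np.array([p.se_mean_gpd for p in pr]),
            ),
            "hr": ParamSpec(self.hr_central.ravel(), "lognormal",
                            ci=(self.hr_ci[0].ravel(), self.hr_ci[1].ravel())),
            "rr_former": ParamSpec(
                np.array([self.riskfns[c].rr_former for c in self.causes]),
                "lognormal",
                se=np.array([former_se_log(self.riskfns[c]) for c in self.causes]),
            ),
        }
        for c in self.causes:
            fn = self.riskfns[c]
            se = np.array(fn.coefficient_se) if fn.coefficient_se else np.zeros(
                len(fn.coefficients)
            )
            specs[f"coef_{c}"] = ParamSpec(np.array(fn.coefficients), "normal", se=se)
        return specs

    # -- one evaluation ------------------------------------------------
    def evaluate(self, params: dict[str, np.ndarray]) -> dict[str, np.ndarray]:
        a = np.clip(params["p_abstainer"], 0.0, 1.0)
        cur = np.clip(params["p_current"], 0.0, 1.0)
        over = a + cur
        scalefix = np.where(over > 1.0, 1.0 / over, 1.0)
        a, cur = a * scalefix, cur * scalefix
        former = np.clip(1.0 - a - cur, 0.0, 1.0)
        binge = np.minimum(np.clip(params["p_binge"], 0.0, 1.0), cur)
        mean = params["mean_gpd"]
        sd = self.sex_ratio * mean
        with np.errstate(divide="ignore", invalid="ignore"):
            shape = np.where(mean > 0, (mean / np.where(sd > 0, sd, 1)) ** 2, np.nan)
            scale = np.where(mean > 0, sd**2 / np.where(mean > 0, mean, 1), np.nan)

        n_sub = len(self.subgroups)
        aafs = np.zeros((n_sub, len(self.causes)))
        for ci, c in enumerate(self.causes):
            fn = self.riskfns[c].with_coefficients(
                params[f"coef_{c}"], rr_former=float(params["rr_former"][ci])
            )
            aafs[:, ci] = aaf_array(
                a, former, cur, binge, shape, scale, fn, self.ses_of_subgroup
            )

        hr = params["hr"].reshape(len(_HR_CATEGORIES), len(SES_LEVELS))
        cat_of_cause = np.array([self.cat_idx[c] for c in self.causes])
        # split weights: share[ses, sex, age] * hr[cat(cause), ses]
        w = self.share[None, :, :, :] * hr[cat_of_cause][:, :, None, None]
        w = w / w.sum(axis=1, keepdims=True)
        split = self.deaths[:, None, :, :] * w  # (cause, ses, sex, age)
        # AAF per (cause, ses, sex, age) via the subgroup index
        aaf_cell = aafs[self.sub_of, :]  # (ses, sex, age, cause)
        attrib = split * np.moveaxis(aaf_cell, -1, 0)
        by_ses = attrib.sum(axis=(0, 2, 3))
        cat_sum = np.zeros((3, len(SES_LEVELS)))  # infectious/chronic/injuries
        for ci in range(len(self.causes)):
            cat_sum[cat_of_cause[ci]] += attrib[ci].sum(axis=(1, 2))
        attr_age = attrib.sum(axis=(0, 2))  # (ses, age)
        pop_age = self.pop.sum(axis=1)  # (ses, age)
        with np.errstate(divide="ignore", invalid="ignore"):
            rate_a = np.where(pop_age > 0, attr_age / pop_age, 0.0)
        rates = (rate_a * self.std_w[None, :]).sum(axis=1) * 100_000
        return dict(
            total=np.array([by_ses.sum()]),
            by_ses=by_ses,
            by_ses_category=cat_sum.ravel(),
            rate_by_ses=rates,
            aaf=aafs.ravel(),
        )
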