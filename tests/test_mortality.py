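"""Cox hazard ratios, death splitting, attribution, age standardisation."""

import numpy as np
import pandas as pd
import pytest

from sescra.codebooks import AGE_GROUPS_5Y, SES_LEVELS
from sescra.mortality import (
    HazardRatioSet,
    age_standardize,
    attributable_deaths,
    cox_hr,
    load_standard_population,
    split_deaths,
    split_population,
)
from sescra.synthetic import SyntheticScenario, generate_cohort


def _hrs(low=1.0, middle=1.0, categories=("infectious", "chronic", "injuries", "all")):
    hrs = HazardRatioSet()
    for cat in categories:
        hrs.add(cat, {"low": (low, low * 0.9, low * 1.1),
                      "middle": (middle, middle * 0.9, middle * 1.1)})
    return hrs


class TestCoxHr:
    def test_exchangeable_groups_give_unit_hazard_ratio(self):
        rng = np.random.default_rng(21)
        n = 600
        t = rng.exponential(5, n)
        block = pd.DataFrame(
            dict(
                entry=0.0, exit=np.minimum(t, 8.0),
                event=(t < 8.0).astype(int), cause_cat="x",
                age0=rng.uniform(20, 60, n), sex=rng.choice(["male", "female"], n),
            )
        )
        cohort = pd.concat(
            [block.assign(ses=s) for s in ("low", "middle", "high")],
            ignore_index=True,
        )
        out = cox_hr(cohort, None)
        assert out["low"][0] == pytest.approx(1.0, abs=1e-6)
        assert out["middle"][0] == pytest.approx(1.0, abs=1e-6)

    def test_recovers_generating_hazard_ratio_of_two(self):
        sc = SyntheticScenario(
            hr_by_cause_category={
                cat: {"low": 2.0, "middle": 1.5, "high": 1.0}
                for cat in ("infectious", "chronic", "injuries", "all")
            },
            seed=77,
        )
        cohort = generate_cohort(sc, 50_000, 10.0)
        cohort = cohort.rename(columns={"_latent_ses": "ses"})
        out = cox_hr(cohort, None)
        assert 1.9 <= out["low"][0] <= 2.1

    def test_no_events_is_an_error(self):
        cohort = pd.DataFrame(
            dict(entry=[0.0] * 3, exit=[1.0] * 3, event=[0] * 3,
                 cause_cat=[""] * 3, age0=[30.0] * 3,
                 sex=["male"] * 3, ses=["low", "middle", "high"])
        )
        with pytest.raises(ValueError, match="no events"):
            cox_hr(cohort, None)


class TestSplitDeaths:
    def _national(self, count=600.0):
        return pd.DataFrame(
            [dict(cause="c", sex="male", age_group="35-39", count=count)]
        )

    def _shares(self, low=1 / 3, middle=1 / 3):
        high = 1 - low - middle
        return pd.DataFrame(
            [
                dict(sex="male", age_group="35-39", ses="low", share=low),
                dict(sex="male", age_group="35-39", ses="middle", share=middle),
                dict(sex="male", age_group="35-39", ses="high", share=high),
            ]
        )

    class _Reg:
        broader = {"c": "chronic"}

    def test_forced_arithmetic_with_hr_one_two_three(self):
        hrs = HazardRatioSet()
        hrs.add("chronic", {"low": (3.0, 2.9, 3.1), "middle": (2.0, 1.9, 2.1)})
        out = split_deaths(self._national(600.0), self._shares(), hrs, self._Reg())
        got = out.set_index("ses")["count"]
        assert got["high"] == pytest.approx(100.0)
        assert got["middle"] == pytest.approx(200.0)
        assert got["low"] == pytest.approx(300.0)

    def test_unit_hazard_ratios_split_by_population_share(self):
        out = split_deaths(
            self._national(900.0), self._shares(0.5, 0.3), _hrs(), self._Reg()
        )
        got = out.set_index("ses")["count"]
        assert got["low"] == pytest.approx(450.0)
        assert got["middle"] == pytest.approx(270.0)
        assert got["high"] == pytest.approx(180.0)

    def test_conservation_on_random_tables(self):
        rng = np.random.default_rng(31)
        rows = [
            dict(cause="c", sex=s, age_group=g, count=float(rng.uniform(0, 500)))
            for s in ("male", "female")
            for g in AGE_GROUPS_5Y
        ]
        national = pd.DataFrame(rows)
        share_rows = []
        for s in ("male", "female"):
            for g in AGE_GROUPS_5Y:
                raw = rng.dirichlet([2, 2, 2])
                for ses, v in zip(SES_LEVELS, raw):
                    share_rows.append(dict(sex=s, age_group=g, ses=ses, share=v))
        shares = pd.DataFrame(share_rows)
        out = split_deaths(national, shares, _hrs(2.73, 2.07), self._Reg())
        merged = (
            out.groupby(["cause", "sex", "age_group"])["count"].sum().reset_index()
        )
        chk = merged.merge(national, on=["cause", "sex", "age_group"])
        np.testing.assert_allclose(chk["count_x"], chk["count_y"], atol=1e-9)

    def test_invalid_shares_rejected(self):
        bad = self._shares()
        bad.loc[0, "share"] = 0.9
        with pytest.raises(ValueError, match="sum to 1"):
            split_deaths(self._national(), bad, _hrs(), self._Reg())


class TestSplitPopulation:
    def test_proportional_multiplication(self):
        pops = pd.DataFrame([dict(sex="male", age_group="20-24", population=1000.0)])
        props = pd.DataFrame(
            [
                dict(sex="male", age_group="20-24", ses="low", share=0.4),
                dict(sex="male", age_group="20-24", ses="middle", share=0.3),
                dict(sex="male", age_group="20-24", ses="high", share=0.3),
            ]
        )
        out = split_population(pops, props).set_index("ses")["population"]
        assert out["low"] == 400.0 and out["middle"] == 300.0 and out["high"] == 300.0

    def test_zero_population_cell_propagates_zeros(self):
        pops = pd.DataFrame([dict(sex="male", age_group="20-24", population=0.0)])
        props = pd.DataFrame(
            [
                dict(sex="male", age_group="20-24", ses=s, share=v)
                for s, v in zip(SES_LEVELS, (0.4, 0.3, 0.3))
            ]
        )
        assert (split_population(pops, props)["population"] == 0).all()


class TestAttributableDeaths:
    def _aafs(self, value):
        rows = [
            dict(ses=s, sex=x, age_band=b, cause="c", aaf=value)
            for s in SES_LEVELS
            for x in ("male", "female")
            for b in ("15-34", "35-54", "55+")
        ]
        return pd.DataFrame(rows)

    def test_zero_aaf_gives_zero_attributable(self):
        split = pd.DataFrame(
            [dict(cause="c", sex="male", age_group="40-44", ses="low", count=500.0)]
        )
        out = attributable_deaths(split, self._aafs(0.0))
        assert (out["attributable"] == 0).all()

    def test_quarter_aaf_of_thousand_is_250(self):
        split = pd.DataFrame(
            [dict(cause="c", sex="male", age_group="40-44", ses="low", count=1000.0)]
        )
        out = attributable_deaths(split, self._aafs(0.25))
        assert out["attributable"].iloc[0] == pytest.approx(250.0)

    def test_unmapped_cell_is_an_error(self):
        split = pd.DataFrame(
            [dict(cause="other", sex="male", age_group="40-44", ses="low", count=10.0)]
        )
        with pytest.raises(KeyError):
            attributable_deaths(split, self._aafs(0.1))


class TestAgeStandardize:
    def _pops(self, ses="low", pop=10_000.0):
        return pd.DataFrame(
            [dict(ses=ses, sex="male", age_group=g, population=pop) for g in AGE_GROUPS_5Y]
        )

    def test_identical_age_specific_rates_are_invariant(self):
        deaths = pd.DataFrame(
            [dict(ses="low", sex="male", age_group=g, attributable=20.0)
             for g in AGE_GROUPS_5Y]
        )
        out = age_standardize(deaths, self._pops())
        assert out["rate_per_100k"].iloc[0] == pytest.approx(20.0 / 10_000 * 1e5)

    def test_two_age_equal_weight_average(self):
        std = pd.DataFrame(
            dict(age_group=["15-19", "20-24"], weight=[0.5, 0.5])
        )
        deaths = pd.DataFrame(
            [
                dict(ses="low", age_group="15-19", attributable=10.0),
                dict(ses="low", age_group="20-24", attributable=30.0),
            ]
        )
        pops = pd.DataFrame(
            [
                dict(ses="low", age_group="15-19", population=100_000.0),
                dict(ses="low", age_group="20-24", population=100_000.0),
            ]
        )
        out = age_standardize(deaths, pops, std)
        assert out["rate_per_100k"].iloc[0] == pytest.approx(20.0)

    def test_rate_bounded_by_age_specific_extremes(self):
        rng = np.random.default_rng(55)
        std = load_standard_population()
        for _ in range(1000):
            rates = rng.uniform(0, 50, len(AGE_GROUPS_5Y))  # per 10,000
            pops = rng.uniform(1000, 50_000, len(AGE_GROUPS_5Y))
            deaths = pd.DataFrame(
                dict(ses="low", age_group=list(AGE_GROUPS_5Y),
                     attributable=rates * pops / 10_000)
            )
            popdf = pd.DataFrame(
                dict(ses="low", age_group=list(AGE_GROUPS_5Y), population=pops)
            )
            out = age_standardize(deaths, popdf, std)["rate_per_100k"].iloc[0]
            age_rates = rates / 10_000 * 1e5
            assert age_rates.min() - 1e-9 <= out <= age_rates.max() + 1e-9

    def test_zero_population_with_deaths_is_an_error(self):
        deaths = pd.DataFrame(
            [dict(ses="low", age_group="15-19", attributable=5.0)]
        )
        pops = pd.DataFrame([dict(ses="low", age_group="15-19", population=0.0)])
        std = pd.DataFrame(dict(age_group=["15-19"], weight=[1.0]))
        with pytest.raises(ValueError, match="zero population"):
            age_standardize(deaths, pops, std)
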