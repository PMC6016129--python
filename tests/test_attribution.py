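"""Attributable-fraction integration against Monte Carlo oracles."""

import numpy as np
import pytest

from sescra.attribution import aaf, aaf_array, aaf_monte_carlo, aaf_table
from sescra.exposure import ExposureProfile, with_gamma
from sescra.risk import CauseRegistry, RiskFunction


def _profile(p_abst=0.5, p_former=0.0, p_current=0.5, p_binge=0.0,
             mean=20.0, sex="male", ses="low", band="35-54"):
    return with_gamma(
        ExposureProfile(
            ses=ses, sex=sex, age_band=band,
            p_abstainer=p_abst, p_former=p_former, p_current=p_current,
            p_binge=p_binge, mean_gpd=mean,
        )
    )


def _linear_fn(beta=0.02, **kw):
    return RiskFunction(
        cause="c", broader_category="chronic", curve_type="polynomial",
        coefficients=(beta,), **kw,
    )


class TestAafLimits:
    def test_universal_abstention_gives_zero(self):
        p = ExposureProfile("low", "male", "15-34", 1.0, 0.0, 0.0, 0.0, float("nan"))
        assert aaf(p, _linear_fn()).value == 0.0

    def test_null_risk_gives_zero(self):
        p = _profile(p_abst=0.3, p_former=0.2, p_current=0.5, mean=40.0)
        fn = _linear_fn(0.0, rr_former=1.0)
        assert aaf(p, fn).value == pytest.approx(0.0, abs=1e-12)

    def test_protective_exposure_gives_negative_aaf(self):
        p = _profile(mean=15.0)
        fn = RiskFunction(
            cause="ihd", broader_category="chronic", curve_type="polynomial",
            coefficients=(-0.012, 0.00002),
        )
        assert aaf(p, fn).value < 0

    def test_missing_gamma_with_drinkers_is_an_error(self):
        p = ExposureProfile("low", "male", "15-34", 0.5, 0.0, 0.5, 0.0, 20.0)
        with pytest.raises(ValueError, match="gamma"):
            aaf(p, _linear_fn())


class TestQuadratureAgainstMonteCarlo:
    def test_reference_case_to_three_decimals(self):
        p = _profile()
        fn = _linear_fn(0.02)
        oracle = aaf_monte_carlo(p, fn, n_draws=10**7, seed=101)
        assert aaf(p, fn).value == pytest.approx(oracle, abs=1e-3)

    def test_twenty_random_profile_curve_pairs(self):
        rng = np.random.default_rng(42)
        for i in range(20):
            p = _profile(
                p_abst=(a := rng.uniform(0.2, 0.6)),
                p_former=(f := rng.uniform(0.0, 0.2)),
                p_current=1 - a - f,
                p_binge=rng.uniform(0, 1 - a - f) * 0.5,
                mean=rng.uniform(10, 70),
                sex=rng.choice(["male", "female"]),
            )
            fn = _linear_fn(
                rng.uniform(0.002, 0.02),
                rr_former=rng.uniform(0.9, 1.4),
                binge_protection_lost=bool(rng.integers(0, 2)),
            )
            oracle = aaf_monte_carlo(p, fn, n_draws=10**6, seed=1000 + i)
            assert aaf(p, fn).value == pytest.approx(oracle, abs=1e-3)

    def test_adaptive_quadrature_cross_check_agrees(self):
        p = _profile(mean=55.0)
        fn = _linear_fn(0.015)
        assert aaf(p, fn).value == pytest.approx(
            aaf(p, fn, check_quadrature=True, rtol=1e-8).value, rel=1e-8
        )


class TestFormulaStructure:
    def test_no_binge_no_former_reduces_to_two_category_form(self):
        from scipy import integrate, stats

        p = _profile(p_abst=0.55, p_former=0.0, p_current=0.45, mean=35.0)
        fn = _linear_fn(0.012, rr_former=1.0)
        dist = stats.gamma(p.gamma_shape, scale=p.gamma_scale)
        mass = dist.cdf(150) - dist.cdf(0.1)
        mean_rr, _ = integrate.quad(
            lambda x: dist.pdf(x) / mass * np.exp(0.012 * x), 0.1, 150, limit=200
        )
        d = 0.55 + 0.45 * mean_rr
        assert aaf(p, fn).value == pytest.approx((d - 1) / d, rel=1e-8)

    def test_binge_mixture_raises_aaf_for_protective_curve(self):
        fn = RiskFunction(
            cause="ihd", broader_category="chronic", curve_type="polynomial",
            coefficients=(-0.012, 0.00012), binge_protection_lost=True,
        )
        no_binge = _profile(mean=25.0, p_binge=0.0)
        half_binge = _profile(mean=25.0, p_binge=0.25)
        assert aaf(half_binge, fn).value > aaf(no_binge, fn).value

    def test_vectorised_path_matches_scalar(self):
        profiles = [_profile(mean=m, p_binge=b, ses=s)
                    for m, b, s in [(20, 0.0, "low"), (45, 0.1, "middle"), (70, 0.2, "high")]]
        fn = _linear_fn(0.01, rr_former=1.2, binge_protection_lost=True,
                        ses_interaction={"low": 1.5})
        vec = aaf_array(
            np.array([p.p_abstainer for p in profiles]),
            np.array([p.p_former for p in profiles]),
            np.array([p.p_current for p in profiles]),
            np.array([p.p_binge for p in profiles]),
            np.array([p.gamma_shape for p in profiles]),
            np.array([p.gamma_scale for p in profiles]),
            fn,
            np.array([p.ses for p in profiles], dtype=object),
        )
        for i, p in enumerate(profiles):
            assert vec[i] == pytest.approx(aaf(p, fn).value, rel=1e-10)


class TestAafTable:
    def _registry(self, causes):
        return CauseRegistry(
            causes=tuple(c.cause for c in causes),
            broader={c.cause: c.broader_category for c in causes},
        )

    def test_one_cause_gives_one_entry_per_subgroup(self):
        profiles = [
            _profile(ses=s, sex=x, band=b)
            for s in ("low", "middle", "high")
            for x in ("male", "female")
            for b in ("15-34", "35-54", "55+")
        ]
        fn = _linear_fn()
        table = aaf_table(profiles, self._registry([fn]), {"c": fn})
        assert len(table) == 18

    def test_ses_interaction_separates_hiv_only(self):
        hiv = RiskFunction(
            cause="hiv", broader_category="infectious", curve_type="polynomial",
            coefficients=(0.004,), ses_interaction={"low": 1.5},
        )
        other = _linear_fn(0.004)
        profiles = [_profile(ses=s) for s in ("low", "middle", "high")]
        table = aaf_table(
            profiles, self._registry([hiv, other]), {"hiv": hiv, "c": other}
        )
        hiv_rows = table[table.cause == "hiv"].set_index("ses")["aaf"]
        oth_rows = table[table.cause == "c"].set_index("ses")["aaf"]
        assert hiv_rows["low"] > hiv_rows["high"]
        assert oth_rows["low"] == pytest.approx(oth_rows["high"], rel=1e-12)

    def test_heavier_drinking_outweighs_lower_prevalence_under_convex_curve(self):
        # the published pattern: low SES drinks less often but more heavily
        low = _profile(p_abst=0.41, p_current=0.45, p_former=0.14, mean=67.4, ses="low")
        high = _profile(p_abst=0.35, p_current=0.51, p_former=0.14, mean=47.7, ses="high")
        fn = _linear_fn(0.012)
        assert aaf(low, fn).value > aaf(high, fn).value

    def test_missing_risk_function_is_an_error(self):
        fn = _linear_fn()
        registry = CauseRegistry(causes=("c", "d"), broader={"c": "chronic", "d": "chronic"})
        with pytest.raises(KeyError, match="d"):
            aaf_table([_profile()], registry, {"c": fn})
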