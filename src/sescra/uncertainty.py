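"""Monte Carlo propagation of parameter uncertainty.

Every lowest-level parameter (subgroup prevalences, drinker means,
hazard ratios, risk-curve coefficients, former-drinker risks) is
re-sampled from its assumed distribution — logit-normal for
prevalences, zero-truncated normal for consumption means, lognormal for
ratio-scale quantities, plain normal for curve coefficients — and the
full calculation chain is re-run per draw.  The 95% uncertainty
interval is the 2.5th-97.5th percentile range of the resulting output
distribution; the reported point estimate is the pipeline evaluated at
the central (un-sampled) parameters, so percentile intervals are not
guaranteed to bracket it and violations are flagged rather than hidden.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Mapping

import numpy as np

_Z95 = 1.959963984540054


@dataclass(frozen=True)
class MCSettings:
    """Draw count, percentile bounds and seed for the simulation."""

    n_draws: int = 100_000
    lower_pct: float = 2.5
    upper_pct: float = 97.5
    seed: int = 0
    max_failure_fraction: float = 0.01

    def __post_init__(self) -> None:
        if self.n_draws < 2:
            raise ValueError("n_draws must be >= 2")
        if not 0 < self.lower_pct < self.upper_pct < 100:
            raise ValueError("percentile bounds must satisfy 0 < lower < upper < 100")


@dataclass(frozen=True)
class ParamSpec:
    """Sampling specification for one (possibly vector) parameter.

    family:
      fixed            value returned unchanged
      logit            proportion; normal on the logit scale (delta-method SE)
      truncated_normal normal truncated at zero (positive quantities)
      normal           plain normal (e.g. curve coefficients)
      lognormal        ratio-scale; normal on the log scale.  ``ci`` may be
                       given instead of ``se``; the log-SE is then
                       ln(hi/lo) / (2 * 1.96).
    """

    value: np.ndarray
    family: str = "fixed"
    se: np.ndarray | None = None
    ci: tuple[np.ndarray, np.ndarray] | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "value", np.atleast_1d(np.asarray(self.value, float)))
        if self.se is not None:
            object.__setattr__(self, "se", np.broadcast_to(
                np.asarray(self.se, float), self.value.shape).copy())
        if self.family not in ("fixed", "logit", "truncated_normal", "normal", "lognormal"):
            raise ValueError(f"unknown sampling family {self.family!r}")
        if self.family != "fixed" and self.se is None and self.ci is None:
            raise ValueError("stochastic parameter needs an SE or a CI")


def _log_se_from_ci(lo: np.ndarray, hi: np.ndarray) -> np.ndarray:
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.log(np.asarray(hi, float) / np.asarray(lo, float)) / (2 * _Z95)
    return np.where(np.asarray(hi, float) > np.asarray(lo, float), out, 0.0)


def draw_parameters(
    rng: np.random.Generator, specs: Mapping[str, ParamSpec]
) -> dict[str, np.ndarray]:
    """One independent draw of every parameter from its distribution.

    Zero SEs reproduce the point estimates exactly; draws are independent
    across parameters and across vector components.
    """
    out: dict[str, np.ndarray] = {}
    for name, spec in specs.items():
        v = spec.value
        if spec.family == "fixed":
            out[name] = v.copy()
            continue
        if spec.family == "lognormal":
            if spec.se is not None:
                se = spec.se
            else:
                se = _log_se_from_ci(*spec.ci)  # type: ignore[misc]
            z = rng.standard_normal(v.shape)
            out[name] = np.where(se > 0, np.exp(np.log(np.maximum(v, 1e-300)) + se * z), v)
            continue
        se = spec.se if spec.se is not None else (
            (np.asarray(spec.ci[1], float) - np.asarray(spec.ci[0], float)) / (2 * _Z95)
        )
        z = rng.standard_normal(v.shape)
        if spec.family == "normal":
            out[name] = v + se * z
        elif spec.family == "truncated_normal":
            draw = v + se * z
            # resample the rare negative draws (simple rejection)
            bad = (draw <= 0) & (se > 0)
            tries = 0
            while bad.any() and tries < 100:
                draw = np.where(bad, v + se * rng.standard_normal(v.shape), draw)
                bad = (draw <= 0) & (se > 0)
                tries += 1
            out[name] = np.where(se > 0, np.maximum(draw, 1e-12), v)
        else:  # logit
            p = np.clip(v, 1e-12, 1 - 1e-12)
            se_logit = np.where((v > 0) & (v < 1), se / (p * (1 - p)), 0.0)
            logit = np.log(p / (1 - p)) + se_logit * z
            drawn = 1.0 / (1.0 + np.exp(-logit))
            out[name] = np.where((se > 0) & (v > 0) & (v < 1), drawn, v)
    return out


@dataclass
class MCResult:
    """Point estimates, interval bounds and bookkeeping per output."""

    point: dict[str, np.ndarray]
    lower: dict[str, np.ndarray]
    upper: dict[str, np.ndarray]
    n_draws_used: int
    n_failures: int
    bracket_violations: dict[str, np.ndarray] = field(default_factory=dict)


def monte_carlo(
    pipeline: Callable[[dict[str, np.ndarray]], dict[str, np.ndarray]],
    specs: Mapping[str, ParamSpec],
    settings: MCSettings,
) -> MCResult:
    """Propagate parameter uncertainty through a pipeline closure.

    ``pipeline`` must be a pure function of a parameter draw, returning a
    dict of named numpy arrays.  Failing draws are recorded and excluded;
    more than ``max_failure_fraction`` failures aborts.  The point
    estimate is the pipeline at the central parameters.
    """
    rng = np.random.default_rng(int(settings.seed) % 2**31)
    central = {name: spec.value.copy() for name, spec in specs.items()}
    point = pipeline(central)
    sums: dict[str, list[np.ndarray]] = {k: [] for k in point}
    n_fail = 0
    for _ in range(settings.n_draws):
        params = draw_parameters(rng, specs)
        try:
            res = pipeline(params)
        except (FloatingPointError, ValueError, ZeroDivisionError):
            n_fail += 1
            if n_fail > settings.max_failure_fraction * settings.n_draws:
                raise RuntimeError(
                    f"{n_fail} failed draws out of {settings.n_draws}; aborting"
                )
            continue
        for k in sums:
            sums[k].append(np.atleast_1d(np.asarray(res[k], float)))
    lower, upper, violations = {}, {}, {}
    for k, draws in sums.items():
        stack = np.stack(draws)
        lower[k] = np.percentile(stack, settings.lower_pct, axis=0)
        upper[k] = np.percentile(stack, settings.upper_pct, axis=0)
        pt = np.atleast_1d(np.asarray(point[k], float))
        viol = (pt < lower[k]) | (pt > upper[k])
        if viol.any():
            violations[k] = viol
    return MCResult(
        point={k: np.atleast_1d(np.asarray(v, float)) for k, v in point.items()},
        lower=lower,
        upper=upper,
        n_draws_used=settings.n_draws - n_fail,
        n_failures=n_fail,
        bracket_violations=violations,
    )


def lognormal_se_from_ci(lo: float, hi: float) -> float:
    """Log-scale SE implied by a 95% CI of a ratio: ln(hi/lo)/3.92."""
    if lo <= 0 or hi < lo:
        raise ValueError("need 0 < lo <= hi")
    return math.log(hi / lo) / (2 * _Z95)
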