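"""Cause-specific relative-risk functions for alcohol consumption.

Each cause of death carries a continuous relative-risk curve RR(x) over
average consumption x (grams of pure alcohol/day), anchored at RR(0) = 1,
plus a former-drinker relative risk, an optional binge-pattern
modification (protective portions of the curve removed for binge
drinkers), and an optional SES interaction expressed as a multiplicative
modifier on the current-drinker RR.  Coefficient values are configuration,
not code: the default set shipped with the package is a documented
placeholder patterned on the dose-response literature.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import IO, Iterable

import numpy as np
import yaml

from .codebooks import BROADER_CATEGORIES

DEFAULT_CAP_GPD = 150.0
DEFAULT_LOWER_GPD = 0.1


@dataclass(frozen=True)
class RiskFunction:
    """Relative-risk specification for one cause of death."""

    cause: str
    broader_category: str
    curve_type: str  # "polynomial" | "piecewise_linear"
    coefficients: tuple[float, ...]  # poly: b_k for x^(k+1); pw: ln RR at knots
    coefficient_se: tuple[float, ...] = ()
    knots: tuple[float, ...] = ()  # piecewise_linear only; first knot must be 0
    rr_former: float = 1.0
    rr_former_ci: tuple[float, float] | None = None
    binge_protection_lost: bool = False
    ses_interaction: dict[str, float] | None = None
    cap_gpd: float = DEFAULT_CAP_GPD

    def __post_init__(self) -> None:
        if self.rr_former <= 0:
            raise ValueError(f"{self.cause}: rr_former must be positive")
        if self.broader_category not in BROADER_CATEGORIES:
            raise ValueError(
                f"{self.cause}: unknown broader category "
                f"{self.broader_category!r}"
            )
        if self.curve_type == "piecewise_linear":
            if not self.knots or self.knots[0] != 0.0:
                raise ValueError(f"{self.cause}: piecewise curve must start at knot 0")
            if self.coefficients[0] != 0.0:
                raise ValueError(f"{self.cause}: ln RR at x=0 must be 0")
        elif self.curve_type != "polynomial":
            raise ValueError(f"{self.cause}: unknown curve type {self.curve_type!r}")
        if self.ses_interaction is not None and any(
            m <= 0 for m in self.ses_interaction.values()
        ):
            raise ValueError(f"{self.cause}: SES multipliers must be positive")

    def ln_rr(self, x: np.ndarray | float) -> np.ndarray | float:
        """ln RR(x) of the continuous curve, no modifiers applied."""
        x = np.asarray(x, dtype=float)
        if self.curve_type == "polynomial":
            out = np.zeros_like(x)
            for k, b in enumerate(self.coefficients):
                out = out + b * x ** (k + 1)
            return out
        return np.interp(x, self.knots, self.coefficients)

    def with_coefficients(
        self, coefficients: Iterable[float], rr_former: float | None = None
    ) -> "RiskFunction":
        """Copy with perturbed coefficients (used by Monte Carlo draws)."""
        return RiskFunction(
            cause=self.cause,
            broader_category=self.broader_category,
            curve_type=self.curve_type,
            coefficients=tuple(coefficients),
            coefficient_se=self.coefficient_se,
            knots=self.knots,
            rr_former=self.rr_former if rr_former is None else rr_former,
            rr_former_ci=self.rr_former_ci,
            binge_protection_lost=self.binge_protection_lost,
            ses_interaction=self.ses_interaction,
            cap_gpd=self.cap_gpd,
        )


def rr_current(
    riskfn: RiskFunction,
    x: np.ndarray | float,
    binge: bool = False,
    ses: str | None = None,
) -> np.ndarray | float:
    """Relative risk for a current drinker at consumption x g/day.

    Consumption above the cap is evaluated at the cap (documented
    clamping); negative consumption is rejected.  If the cause removes
    cardiometabolic protection under a binge pattern, binge drinkers get
    RR = max(1, RR(x)).  An SES interaction multiplies the result.
    """
    x = np.asarray(x, dtype=float)
    if np.any(x < 0):
        raise ValueError("negative consumption")
    x = np.minimum(x, riskfn.cap_gpd)
    rr = np.exp(riskfn.ln_rr(x))
    if binge and riskfn.binge_protection_lost:
        rr = np.maximum(1.0, rr)
    if ses is not None and riskfn.ses_interaction:
        rr = rr * riskfn.ses_interaction.get(ses, 1.0)
    return rr if rr.shape else float(rr)


@dataclass
class CauseRegistry:
    """Ordered cause set with broader-category tags."""

    causes: tuple[str, ...]
    broader: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(set(self.causes)) != len(self.causes):
            raise ValueError("duplicate cause in registry")
        missing = [c for c in self.causes if c not in self.broader]
        if missing:
            raise ValueError(f"causes without broader category: {missing}")

    def __len__(self) -> int:
        return len(self.causes)

    def category_of(self, cause: str) -> str:
        return self.broader[cause]


def _lognormal_se(ci: tuple[float, float]) -> float:
    lo, hi = ci
    if lo <= 0 or hi <= 0 or hi < lo:
        raise ValueError(f"invalid CI {ci}")
    return math.log(hi / lo) / (2 * 1.959963984540054)


def load_risk_config(
    source: str | Path | IO[str],
) -> tuple[CauseRegistry, dict[str, RiskFunction]]:
    """Parse a risk configuration into a registry and risk functions.

    Validates uniqueness of causes, broader-category membership, and the
    RR(0) = 1 anchor of every curve.
    """
    if hasattr(source, "read"):
        raw = yaml.safe_load(source)
    else:
        with open(source) as fh:
            raw = yaml.safe_load(fh)
    if not raw or "causes" not in raw or not raw["causes"]:
        raise ValueError("empty or malformed risk configuration")
    cap = float(raw.get("cap_gpd", DEFAULT_CAP_GPD))
    riskfns: dict[str, RiskFunction] = {}
    causes: list[str] = []
    broader: dict[str, str] = {}
    for entry in raw["causes"]:
        cause = entry["cause"]
        if cause in riskfns:
            raise ValueError(f"duplicate cause {cause!r}")
        curve = entry["curve"]
        former = entry.get("rr_former", {"value": 1.0})
        fn = RiskFunction(
            cause=cause,
            broader_category=entry["broader_category"],
            curve_type=curve["type"],
            coefficients=tuple(float(c) for c in curve["coefficients"]),
            coefficient_se=tuple(float(s) for s in curve.get("se", ())),
            knots=tuple(float(k) for k in curve.get("knots", ())),
            rr_former=float(former["value"]),
            rr_former_ci=tuple(former["ci"]) if "ci" in former else None,
            binge_protection_lost=bool(entry.get("binge_protection_lost", False)),
            ses_interaction=entry.get("ses_interaction"),
            cap_gpd=float(entry.get("cap_gpd", cap)),
        )
        if abs(float(np.exp(fn.ln_rr(0.0))) - 1.0) > 1e-12:
            raise ValueError(f"{cause}: RR(0) != 1")
        riskfns[cause] = fn
        causes.append(cause)
        broader[cause] = fn.broader_category
    registry = CauseRegistry(causes=tuple(causes), broader=broader)
    return registry, riskfns


def dump_risk_config(
    registry: CauseRegistry, riskfns: dict[str, RiskFunction], path: str | Path
) -> None:
    """Serialise a risk configuration back to YAML (round-trip safe)."""
    entries = []
    for cause in registry.causes:
        fn = riskfns[cause]
        entry: dict = {
            "cause": cause,
            "broader_category": fn.broader_category,
            "curve": {
                "type": fn.curve_type,
                "coefficients": list(fn.coefficients),
                "se": list(fn.coefficient_se),
            },
            "rr_former": {"value": fn.rr_former},
            "cap_gpd": fn.cap_gpd,
        }
        if fn.knots:
            entry["curve"]["knots"] = list(fn.knots)
        if fn.rr_former_ci:
            entry["rr_former"]["ci"] = list(fn.rr_former_ci)
        if fn.binge_protection_lost:
            entry["binge_protection_lost"] = True
        if fn.ses_interaction:
            entry["ses_interaction"] = dict(fn.ses_interaction)
        entries.append(entry)
    with open(path, "w") as fh:
        yaml.safe_dump({"causes": entries}, fh, sort_keys=False)


def load_default_risk_config() -> tuple[CauseRegistry, dict[str, RiskFunction]]:
    """The 19-cause default configuration shipped with the package."""
    ref = resources.files("sescra.data").joinpath("risk_default.yaml")
    with ref.open() as fh:
        return load_risk_config(fh)


def former_se_log(fn: RiskFunction) -> float:
    """Log-scale SE of the former-drinker RR derived from its CI width."""
    if fn.rr_former_ci is None:
        return 0.0
    lo, hi = fn.rr_former_ci
    if lo == hi:
        return 0.0
    return _lognormal_se((lo, hi))
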