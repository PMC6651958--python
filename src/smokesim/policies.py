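"""Tobacco-control scenarios as constant per-age rate multipliers.

Every scenario is reduced to two per-age multiplier curves, one on the
initiation rate and one on the cessation rate, held constant over the whole
projection horizon. Cessation-side interventions follow the coverage rule

    multiplier = 1 + coverage * success_rate

and independent policies combine multiplicatively.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .ages import AGES, N_AGES
from .errors import ConfigurationError

#: shipped intervention parameters: quit-line reaches at most 12% of
#: smokers with 19.5% twelve-month effectiveness; clinician brief advice
#: reaches 30% of smokers with a 66% effect on the cessation rate.
QUITLINE_COVERAGE, QUITLINE_SUCCESS = 0.12, 0.195
BRIEF_ADVICE_COVERAGE, BRIEF_ADVICE_SUCCESS = 0.30, 0.66

#: shipped tax parameters: 15%/year real price increase, price elasticity
#: of consumption -0.5, half of the consumption drop realised as quitting,
#: and a doubled effect below age 25.
TAX_PRICE_INCREASE, TAX_ELASTICITY = 0.15, -0.5
TAX_QUITTING_SHARE, TAX_YOUTH_FACTOR = 0.5, 2.0

YOUTH_ACCESS_REDUCTION = 0.5
YOUTH_AGE_RANGE = (15, 24)


@dataclass(frozen=True)
class PolicyScenario:
    """Constant per-age multipliers on initiation and cessation rates."""

    label: str
    initiation_mult: np.ndarray = field(default_factory=lambda: np.ones(N_AGES))
    cessation_mult: np.ndarray = field(default_factory=lambda: np.ones(N_AGES))

    def __post_init__(self) -> None:
        for name in ("initiation_mult", "cessation_mult"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape != (N_AGES,):
                raise ConfigurationError(f"{name} must have one entry per single age")
            if np.any(arr < 0) or not np.all(np.isfinite(arr)):
                raise ConfigurationError(f"{name} must be finite and >= 0")
            object.__setattr__(self, name, arr)

    def is_identity(self) -> bool:
        return bool(np.all(self.initiation_mult == 1.0) and np.all(self.cessation_mult == 1.0))


def identity_scenario(label: str = "baseline") -> PolicyScenario:
    """The neutral scenario: all multipliers 1, reproduces the baseline."""
    return PolicyScenario(label=label)


def coverage_effect(coverage: float, success: float) -> float:
    """Cessation multiplier of a cessation programme: 1 + coverage x success."""
    if not 0.0 <= coverage <= 1.0:
        raise ConfigurationError(f"coverage must be in [0,1], got {coverage}")
    if not 0.0 <= success <= 1.0:
        raise ConfigurationError(f"success rate must be in [0,1], got {success}")
    return 1.0 + coverage * success


def coverage_scenario(label: str, coverage: float, success: float) -> PolicyScenario:
    """A cessation programme applied uniformly across ages."""
    mult = coverage_effect(coverage, success)
    return PolicyScenario(label=label, cessation_mult=np.full(N_AGES, mult))


def quitline_scenario(coverage: float = QUITLINE_COVERAGE,
                      success: float = QUITLINE_SUCCESS) -> PolicyScenario:
    return coverage_scenario("quit_line", coverage, success)


def brief_advice_scenario(coverage: float = BRIEF_ADVICE_COVERAGE,
                          success: float = BRIEF_ADVICE_SUCCESS) -> PolicyScenario:
    return coverage_scenario("brief_advice", coverage, success)


def youth_access_scenario(
    reduction: float = YOUTH_ACCESS_REDUCTION,
    ages: tuple[int, int] = YOUTH_AGE_RANGE,
    label: str = "youth_access",
) -> PolicyScenario:
    """Restrict youth access to tobacco: scales down initiation on ``ages``.

    ``reduction`` is the proportional cut in the initiation rate (0.5 means
    halved); cessation is untouched.
    """
    if not 0.0 <= reduction <= 1.0:
        raise ConfigurationError(f"reduction must be in [0,1], got {reduction}")
    init = np.ones(N_AGES)
    mask = (AGES >= ages[0]) & (AGES <= ages[1])
    init[mask] = 1.0 - reduction
    return PolicyScenario(label=label, initiation_mult=init)


def tax_scenario(
    annual_price_increase: float = TAX_PRICE_INCREASE,
    elasticity: float = TAX_ELASTICITY,
    quitting_share: float = TAX_QUITTING_SHARE,
    youth_factor: float = TAX_YOUTH_FACTOR,
    label: str = "tax",
) -> PolicyScenario:
    """Sustained annual price increases acting through the price elasticity.

    The relative cessation increase is
    ``annual_price_increase * |elasticity| * quitting_share`` for ages 25+,
    multiplied by ``youth_factor`` below 25 (young smokers are more
    price-sensitive). Initiation is left unchanged: price effects on youth
    initiation are taken as negligible. The multiplier is per annual cycle
    and constant over the horizon (each year's price rise sustains the same
    relative boost; it does not compound).
    """
    if annual_price_increase < 0:
        raise ConfigurationError("annual_price_increase must be >= 0")
    if elasticity > 0:
        raise ConfigurationError(f"price elasticity must be <= 0, got {elasticity}")
    if not 0.0 <= quitting_share <= 1.0:
        raise ConfigurationError("quitting_share must be in [0,1]")
    if youth_factor < 0:
        raise ConfigurationError("youth_factor must be >= 0")
    adult_boost = annual_price_increase * abs(elasticity) * quitting_share
    cess = np.where(AGES >= 25, 1.0 + adult_boost, 1.0 + adult_boost * youth_factor)
    return PolicyScenario(label=label, cessation_mult=cess)


def combine_scenarios(scenarios: list[PolicyScenario], label: str | None = None) -> PolicyScenario:
    """Multiplicative (order-invariant) combination of scenarios."""
    if not scenarios:
        raise ConfigurationError("cannot combine an empty list of scenarios")
    init = np.ones(N_AGES)
    cess = np.ones(N_AGES)
    for s in scenarios:
        init = init * s.initiation_mult
        cess = cess * s.cessation_mult
    if label is None:
        label = "+".join(s.label for s in scenarios)
    return PolicyScenario(label=label, initiation_mult=init, cessation_mult=cess)


def combined_scenario() -> PolicyScenario:
    """The shipped combined package: youth access + tax + quit-line + brief advice."""
    return combine_scenarios(
        [youth_access_scenario(), tax_scenario(), quitline_scenario(), brief_advice_scenario()],
        label="combined",
    )


def theoretical_scenario(include_tax: bool = True,
                         quitline_success: float = QUITLINE_SUCCESS,
                         brief_success: float = BRIEF_ADVICE_SUCCESS) -> PolicyScenario:
    """Theoretical maximum: zero initiation everywhere, full-coverage
    cessation interventions, optionally composed with the tax effect."""
    parts = [
        coverage_scenario("quit_line_full", 1.0, quitline_success),
        coverage_scenario("brief_advice_full", 1.0, brief_success),
    ]
    if include_tax:
        parts.append(tax_scenario())
    base = combine_scenarios(parts, label="theoretical")
    return PolicyScenario(
        label="theoretical",
        initiation_mult=np.zeros(N_AGES),
        cessation_mult=base.cessation_mult,
    )


def preset_scenarios() -> dict[str, PolicyScenario]:
    """The six shipped scenarios, baseline first."""
    return {
        "baseline": identity_scenario(),
        "youth_access": youth_access_scenario(),
        "tax": tax_scenario(),
        "quit_line": quitline_scenario(),
        "brief_advice": brief_advice_scenario(),
        "combined": combined_scenario(),
        "theoretical": theoretical_scenario(),
    }


def scenario_from_config(block: dict) -> PolicyScenario:
    """Build a scenario from a config block {name, type, params}."""
    kind = block.get("type")
    params = dict(block.get("params") or {})
    name = block.get("name")
    try:
        if kind == "identity":
            return identity_scenario(name or "baseline")
        if kind == "youth_access":
            ages = tuple(params.pop("ages", YOUTH_AGE_RANGE))
            return youth_access_scenario(label=name or "youth_access", ages=ages, **params)
        if kind == "tax":
            return tax_scenario(label=name or "tax", **params)
        if kind == "coverage":
            return coverage_scenario(name or "coverage", **params)
        if kind == "combined":
            names = params.pop("components", None)
            presets = preset_scenarios()
            if names:
                missing = [c for c in names if c not in presets]
                if missing:
                    raise ConfigurationError(f"unknown combined components {missing}")
                return combine_scenarios([presets[c] for c in names], label=name or "combined")
            return combined_scenario()
        if kind == "theoretical":
            return theoretical_scenario(**params)
    except TypeError as exc:
        raise ConfigurationError(f"bad parameters for scenario {name!r}: {exc}") from exc
    raise ConfigurationError(f"unknown scenario type {kind!r}")


__all__ = [
    "PolicyScenario",
    "identity_scenario",
    "coverage_effect",
    "coverage_scenario",
    "quitline_scenario",
    "brief_advice_scenario",
    "youth_access_scenario",
    "tax_scenario",
    "combine_scenarios",
    "combined_scenario",
    "theoretical_scenario",
    "preset_scenarios",
    "scenario_from_config",
]
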