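"""Synthetic demography and survey generator.

Generates every input the projection pipeline needs — population counts by
single age and year, an all-cause mortality schedule, relative-risk curves,
and duration-stratified survey counts with known true transition rates — so
the whole pipeline runs and is testable without any restricted data. The
generator matches the structure and orders of magnitude of a middle-income
country's male population; it makes no claim of demographic fidelity.

Randomness contract: one run-level seed deterministically derives per-stream
sub-seeds (population, mortality, survey) via ``numpy.random.SeedSequence``,
so each stream can be regenerated independently and a fixed seed yields
byte-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .ages import AGES, BANDS, band_ages, band_lower_age
from .rates import RateSchedule, SURVEY_COLUMNS

_STREAMS = ("population", "mortality", "survey")


@dataclass
class SynthParams:
    """Knobs of the synthetic world (defaults are the shipped study setup).

    The population has an asymmetric-Gaussian age pyramid (middle-aged-heavy,
    small youth cohorts) and grows slowly; mortality is Gompertz in age;
    relative risks for smokers decline towards 1 at the oldest ages, as
    observed in large prospective cohorts.
    """

    base_year: int = 2015
    horizon_end: int = 2025
    #: living population aged 15+ at the base year, per sex
    base_population: dict = field(default_factory=lambda: {"male": 27_000_000, "female": 28_000_000})
    #: annual total growth rate of the 15+ population
    growth_rate: float = 0.003
    #: asymmetric-Gaussian age pyramid: modal age, spread below the mode and
    #: (smaller) spread above it — a middle-aged-heavy, aging population with
    #: small entering youth cohorts
    age_mode: float = 45.0
    age_spread_young: float = 20.0
    age_spread_old: float = 12.0
    #: Gompertz all-cause mortality: rate(age) = level * exp(slope * (age - 15))
    gompertz_level: float = 0.0010
    gompertz_slope: float = 0.068
    #: relative-risk curves: rr(age) = 1 + excess / (1 + exp((age - mid)/scale))
    rr_current_excess: float = 1.4
    rr_former_excess: float = 0.45
    rr_age_midpoint: float = 78.0
    rr_age_scale: float = 6.0
    seed: int = 0

    def subseeds(self) -> dict[str, int]:
        """Per-stream sub-seeds derived deterministically from the run seed."""
        children = np.random.SeedSequence(self.seed).spawn(len(_STREAMS))
        return {name: int(c.generate_state(1)[0] % (2**31)) for name, c in zip(_STREAMS, children)}

    def to_dict(self) -> dict:
        return asdict(self)


def _age_shares(params: SynthParams) -> np.ndarray:
    spread = np.where(AGES < params.age_mode, params.age_spread_young, params.age_spread_old)
    shape = np.exp(-0.5 * ((AGES - params.age_mode) / spread) ** 2)
    return shape / shape.sum()


def generate_population(params: SynthParams) -> pd.DataFrame:
    """Deterministic population counts (year, sex, age, count), 15+ only.

    The base-year age profile is scaled by compound growth; each year's
    age-15 row is the entrant cohort for that year.
    """
    shares = _age_shares(params)
    rows = []
    for sex, base in params.base_population.items():
        for year in range(params.base_year, params.horizon_end + 1):
            scale = base * (1.0 + params.growth_rate) ** (year - params.base_year)
            counts = scale * shares
            for age, count in zip(AGES, counts):
                rows.append({"year": year, "sex": sex, "age": int(age), "count": count})
    return pd.DataFrame(rows)


def entrants_from_population(population: pd.DataFrame, sex: str) -> dict[int, float]:
    """Per-year cohort of new 15-year-olds for one sex."""
    sub = population[(population["sex"] == sex) & (population["age"] == 15)]
    return {int(r["year"]): float(r["count"]) for _, r in sub.iterrows()}


def population_age_profile(population: pd.DataFrame, sex: str, year: int) -> np.ndarray:
    """Per-single-age counts for one sex and year, aligned with ``AGES``."""
    sub = population[(population["sex"] == sex) & (population["year"] == year)]
    by_age = dict(zip(sub["age"], sub["count"]))
    return np.array([float(by_age[int(a)]) for a in AGES])


def gompertz_rate(age: float, level: float, slope: float) -> float:
    """Closed-form Gompertz all-cause rate at one age, capped at 0.7."""
    return float(min(0.7, level * np.exp(slope * (age - 15.0))))


def _band_midpoint(band: str) -> float:
    lo = band_lower_age(band)
    return 82.0 if band.endswith("+") else lo + 2.0


def generate_mortality_schedule(params: SynthParams) -> pd.DataFrame:
    """All-cause rates (year, sex, age_group, all_cause_rate); Gompertz in
    age (evaluated at band midpoints, so non-decreasing in age), constant
    across years and sexes."""
    rows = []
    for sex in params.base_population:
        for year in range(params.base_year, params.horizon_end + 1):
            for band in BANDS:
                rate = gompertz_rate(_band_midpoint(band), params.gompertz_level, params.gompertz_slope)
                rows.append({"year": year, "sex": sex, "age_group": band, "all_cause_rate": rate})
    return pd.DataFrame(rows)


def generate_rr_table(params: SynthParams) -> pd.DataFrame:
    """Smooth age-declining relative risks (sex, age_group, rr_current,
    rr_former). Synthetic stand-in shaped like prospective-cohort estimates;
    not measured values."""
    rows = []
    for sex in params.base_population:
        for band in BANDS:
            mid = _band_midpoint(band)
            damp = 1.0 / (1.0 + np.exp((mid - params.rr_age_midpoint) / params.rr_age_scale))
            rows.append({
                "sex": sex, "age_group": band,
                "rr_current": 1.0 + params.rr_current_excess * damp,
                "rr_former": 1.0 + params.rr_former_excess * damp,
            })
    return pd.DataFrame(rows)


def generate_survey_microdata(
    true_rates: RateSchedule,
    n: int,
    seed: int,
    sex: str = "male",
    prevalences: pd.DataFrame | None = None,
    durations: tuple[float, float, float] | None = None,
) -> pd.DataFrame:
    """Draw duration-stratified survey counts with known true rates.

    Each respondent falls into one of the seven duration categories with
    probabilities that encode one year of transition history at the band's
    true rates: never smokers initiate into ``current_lt12``; smokers of at
    least a year's standing quit into ``former_12_23`` (their survivors are
    ``current_ge24``) — so the ratio estimators recover the true rates in
    expectation. Former smokers who relapse re-enter ``current_ge24`` (their
    lifetime smoking duration exceeds two years).

    ``prevalences`` gives the (p_never, p_current, p_former) mix per band as
    percentages (defaults to the packaged 2014 survey table). If
    ``durations`` (target shares of former smokers by quit duration
    <12 / 12-23 / >=24 months) is supplied, long-standing former smokers are
    redistributed so the aggregate quit-duration mix matches it — emulating
    the duration heaping of real surveys at the cost of strict estimator
    unbiasedness.

    Returns one row per band with the SurveyCounts columns; sampling is a
    single multinomial per band, so output is deterministic under ``seed``.
    """
    if n <= 0:
        raise ValueError("n must be positive")
    if prevalences is None:
        from .fixtures import load_prevalence_2014

        prevalences = load_prevalence_2014()
    rng = np.random.default_rng(seed)
    init_by_age = true_rates.initiation(sex)
    cess_by_age = true_rates.cessation(sex)
    rel = true_rates.relapse

    prev = prevalences[(prevalences["sex"] == sex) & (prevalences["age_group"] != "overall")]
    rows = []
    for _, r in prev.iterrows():
        band = str(r["age_group"]).replace("–", "-")
        ages = band_ages(band)
        idx = np.isin(AGES, ages)
        i = float(np.mean(init_by_age[idx]))
        c = float(np.mean(cess_by_age[idx]))
        total = float(r["p_never"]) + float(r["p_current"]) + float(r["p_former"])
        p_n, p_c, p_f = (float(r[k]) / total for k in ("p_never", "p_current", "p_former"))

        mass = {
            "never": p_n * (1.0 - i),
            "current_lt12": p_n * i,
            "current_12_23": p_n * i,          # last year's initiators, still smoking
            "current_ge24": p_c * (1.0 - c) + p_f * rel,
            "former_lt12": p_c * c,            # quit within the last year
            "former_12_23": p_c * c,           # quit the year before
            "former_ge24": p_f * (1.0 - rel),  # long-standing quitters
        }
        if durations is not None:
            mass = _retarget_durations(mass, durations)
        cats = list(mass)
        probs = np.array([mass[k] for k in cats])
        probs = probs / probs.sum()
        counts = rng.multinomial(n, probs)
        row = {"sex": sex, "age_group": band}
        row.update(dict(zip(cats, (int(v) for v in counts))))
        rows.append(row)
    return pd.DataFrame(rows, columns=["sex", "age_group", *SURVEY_COLUMNS])


def _retarget_durations(mass: dict[str, float], durations: tuple[float, float, float]) -> dict[str, float]:
    """Move long-standing former-smoker mass between quit-duration bins so
    their aggregate shares match ``durations`` (<12, 12-23, >=24 months),
    where feasible given the transition-generated bins."""
    t = np.asarray(durations, dtype=float)
    t = t / t.sum()
    gen = np.array([mass["former_lt12"], mass["former_12_23"], 0.0])
    total_f = gen.sum() + mass["former_ge24"]
    target = t * total_f
    extra = np.clip(target - gen, 0.0, None)
    if extra.sum() > 0:
        extra = extra / extra.sum() * mass["former_ge24"]
    out = dict(mass)
    out["former_lt12"] = gen[0] + extra[0]
    out["former_12_23"] = gen[1] + extra[1]
    out["former_ge24"] = extra[2]
    return out


def generate_all_inputs(params: SynthParams) -> dict[str, pd.DataFrame]:
    """Population, mortality, relative-risk and survey tables in one call."""
    seeds = params.subseeds()
    from .fixtures import load_cessation_2014, load_initiation_2014, load_prevalence_2014
    from .rates import build_rate_schedule

    schedule = build_rate_schedule(
        load_cessation_2014(), load_initiation_2014(), relapse=0.0, sex="male"
    )
    return {
        "population": generate_population(params),
        "mortality": generate_mortality_schedule(params),
        "rr": generate_rr_table(params),
        "survey_counts": generate_survey_microdata(
            schedule, n=50_000, seed=seeds["survey"], sex="male",
            prevalences=load_prevalence_2014(),
        ),
    }


__all__ = [
    "SynthParams",
    "generate_population",
    "generate_mortality_schedule",
    "generate_rr_table",
    "generate_survey_microdata",
    "generate_all_inputs",
    "entrants_from_population",
    "population_age_profile",
    "gompertz_rate",
]
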