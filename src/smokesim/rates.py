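"""Annual transition-rate estimation from survey-style duration counts.

A cross-sectional survey that records how long current smokers have smoked
and how long former smokers have abstained identifies one-year transition
probabilities:

* annual cessation rate
    ``former_12_23 / (former_12_23 + current_ge24)`` — former smokers who
    quit 12-23 months before the survey, over themselves plus the current
    smokers of at least 24 months' standing (the survivors of the same
    at-risk cohort);
* annual initiation rate
    ``current_lt12 / (current_lt12 + never)`` — current smokers who started
    within the last 12 months, over themselves plus the remaining never
    smokers.

Initiation is modelled for ages 15-24 only; at 25 and above the estimator
returns 0 by convention (with a logged notice) unless the caller overrides
the schedule explicitly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .ages import BANDS, SEXES, band_lower_age, expand_band_values
from .errors import ConfigurationError, UndefinedRateError

logger = logging.getLogger(__name__)

#: oldest age at which smoking initiation is modelled
INITIATION_MAX_AGE = 24

SURVEY_COLUMNS = (
    "never", "current_lt12", "current_12_23", "current_ge24",
    "former_lt12", "former_12_23", "former_ge24",
)


@dataclass(frozen=True)
class SurveyCounts:
    """Counts for one sex/age-band stratum of a duration-stratified survey."""

    sex: str
    age_group: str
    never: float
    current_lt12: float
    current_12_23: float
    current_ge24: float
    former_lt12: float
    former_12_23: float
    former_ge24: float

    def __post_init__(self) -> None:
        for name in SURVEY_COLUMNS:
            v = getattr(self, name)
            if not np.isfinite(v) or v < 0:
                raise ValueError(f"survey count {name!r} must be finite and >= 0, got {v}")


def estimate_cessation_rate(counts: SurveyCounts) -> float:
    """Annual probability that a current smoker quits, from one stratum."""
    denom = counts.former_12_23 + counts.current_ge24
    if denom <= 0:
        raise UndefinedRateError(
            f"cessation denominator is zero for {counts.sex} {counts.age_group}"
        )
    return counts.former_12_23 / denom


def estimate_initiation_rate(counts: SurveyCounts) -> float:
    """Annual probability that a never smoker starts smoking, from one stratum.

    Strata whose age band starts at 25 or older return 0.0 (initiation is
    modelled at ages 15-24 only); the convention is logged, not silent.
    """
    if band_lower_age(counts.age_group) > INITIATION_MAX_AGE:
        logger.info(
            "initiation fixed at 0 for %s %s (initiation modelled at ages 15-24)",
            counts.sex, counts.age_group,
        )
        return 0.0
    denom = counts.current_lt12 + counts.never
    if denom <= 0:
        raise UndefinedRateError(
            f"initiation denominator is zero for {counts.sex} {counts.age_group}"
        )
    return counts.current_lt12 / denom


class RateSchedule:
    """Lookup of (sex, single age) -> (initiation, cessation, relapse).

    Built from per-band tables; each single year of age receives the rate of
    the 5-year band it belongs to. Relapse (former -> current) is a single
    annual probability applied uniformly across ages.
    """

    def __init__(
        self,
        initiation_by_band: dict[str, dict[str, float]],
        cessation_by_band: dict[str, dict[str, float]],
        relapse: float,
    ) -> None:
        if not 0.0 <= relapse <= 1.0:
            raise ConfigurationError(f"relapse rate must be in [0,1], got {relapse}")
        self.relapse = float(relapse)
        self._initiation: dict[str, np.ndarray] = {}
        self._cessation: dict[str, np.ndarray] = {}
        for sex in initiation_by_band:
            table = dict(initiation_by_band[sex])
            # initiation defaults to 0 for any band not supplied; bands at
            # 25+ are therefore 0 unless the caller overrides them explicitly
            full = {b: table.get(b, 0.0) for b in BANDS}
            self._initiation[sex] = expand_band_values(full)
        for sex in cessation_by_band:
            self._cessation[sex] = expand_band_values(dict(cessation_by_band[sex]))
        for name, tables in (("initiation", self._initiation), ("cessation", self._cessation)):
            for sex, arr in tables.items():
                if np.any((arr < 0) | (arr > 1)):
                    raise ConfigurationError(f"{name} rates for {sex} outside [0,1]")

    def initiation(self, sex: str) -> np.ndarray:
        """Per-single-age initiation probabilities for one sex."""
        return self._initiation[sex].copy()

    def cessation(self, sex: str) -> np.ndarray:
        """Per-single-age cessation probabilities for one sex."""
        return self._cessation[sex].copy()

    def sexes(self) -> tuple[str, ...]:
        return tuple(self._cessation)


def build_rate_schedule(
    cessation_table: pd.DataFrame | dict,
    initiation_table: pd.DataFrame | dict | None,
    relapse: float,
    sex: str = "male",
) -> RateSchedule:
    """Assemble a RateSchedule for one sex from band-level rate tables.

    ``cessation_table`` must cover every band 15-19 ... 75+ (a missing band
    is a configuration error); ``initiation_table`` may cover only the young
    bands, the rest default to 0. Tables are DataFrames with columns
    (age_group, rate) — or (age_group, cessation/initiation) — or plain
    {band: rate} dicts. Rates are proportions in [0,1].
    """
    cess = _table_to_dict(cessation_table, ("cessation", "rate"))
    init = _table_to_dict(initiation_table, ("initiation", "rate")) if initiation_table is not None else {}
    return RateSchedule({sex: init}, {sex: cess}, relapse)


def _table_to_dict(table: pd.DataFrame | dict, value_cols: tuple[str, ...]) -> dict[str, float]:
    if isinstance(table, dict):
        return {str(k).replace("–", "-"): float(v) for k, v in table.items()}
    col = next((c for c in value_cols if c in table.columns), None)
    if col is None:
        raise ConfigurationError(f"rate table needs one of the columns {value_cols}")
    out = {}
    for _, row in table.iterrows():
        band = str(row["age_group"]).replace("–", "-")
        if band.lower().startswith(("all", "overall", "30+")):
            continue
        out[band] = float(row[col])
    return out


def estimate_rates_from_survey(survey: pd.DataFrame) -> pd.DataFrame:
    """Apply both estimators to every stratum of a survey-counts table.

    Input columns: sex, age_group, and the seven duration-count columns.
    Returns a tidy frame (sex, age_group, initiation, cessation).
    """
    rows = []
    for _, r in survey.iterrows():
        sc = SurveyCounts(
            sex=r["sex"], age_group=str(r["age_group"]),
            **{c: float(r[c]) for c in SURVEY_COLUMNS},
        )
        rows.append(
            {
                "sex": sc.sex,
                "age_group": sc.age_group,
                "initiation": estimate_initiation_rate(sc),
                "cessation": estimate_cessation_rate(sc),
            }
        )
    return pd.DataFrame(rows)


__all__ = [
    "SurveyCounts",
    "RateSchedule",
    "estimate_cessation_rate",
    "estimate_initiation_rate",
    "estimate_rates_from_survey",
    "build_rate_schedule",
    "INITIATION_MAX_AGE",
    "SURVEY_COLUMNS",
    "SEXES",
]
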