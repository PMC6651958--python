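"""Status-specific death probabilities and smoking-attributable mortality.

The model receives all-cause mortality rates (life-table style, by sex and
5-year age band) and relative risks of death for current and former smokers
versus never smokers. These are combined with the prevailing smoking-state
shares of each stratum through the prevalence-weighted partition

    pdying_never   = all_cause / (p_never + p_current * RRc + p_former * RRf)
    pdying_current = RRc * pdying_never
    pdying_former  = RRf * pdying_never

which is the unique assignment that honours the relative-risk ratios while
keeping the prevalence-weighted mean of the three probabilities equal to
the all-cause rate.

Smoking-attributable deaths are the excess over the never-smoker
counterfactual: current and former smokers are charged the difference
between their own death probability and the never-smoker one.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import TYPE_CHECKING

import numpy as np
import pandas as pd

from .ages import BAND_OF_AGE, BANDS
from .errors import ConfigurationError, ContractViolationError

if TYPE_CHECKING:  # pragma: no cover
    from .engine import ProjectionResult, StateArrays


@dataclass(frozen=True)
class MortalityPartition:
    """Per-status annual death probabilities (scalars or per-age arrays)."""

    pdying_never: float | np.ndarray
    pdying_current: float | np.ndarray
    pdying_former: float | np.ndarray


class RelativeRiskTable:
    """Relative risks of death for current/former vs never smokers.

    Built from a tidy frame (sex, age_group, rr_current, rr_former). A band
    where rr_former exceeds rr_current is unusual and triggers a warning,
    not an error.
    """

    def __init__(self, table: pd.DataFrame) -> None:
        self._by_sex: dict[str, tuple[np.ndarray, np.ndarray]] = {}
        for sex, grp in table.groupby("sex"):
            rc = {str(r["age_group"]).replace("–", "-"): float(r["rr_current"]) for _, r in grp.iterrows()}
            rf = {str(r["age_group"]).replace("–", "-"): float(r["rr_former"]) for _, r in grp.iterrows()}
            missing = [b for b in BANDS if b not in rc]
            if missing:
                raise ConfigurationError(f"relative-risk table for {sex} missing bands {missing}")
            for band in BANDS:
                if not (np.isfinite(rc[band]) and np.isfinite(rf[band])) or rc[band] < 0 or rf[band] < 0:
                    raise ConfigurationError(f"relative risks for {sex} {band} must be finite and >= 0")
                if rf[band] > rc[band]:
                    warnings.warn(
                        f"rr_former > rr_current for {sex} {band}; unusual but accepted",
                        stacklevel=2,
                    )
            rr_c = np.array([rc[b] for b in BAND_OF_AGE])
            rr_f = np.array([rf[b] for b in BAND_OF_AGE])
            self._by_sex[str(sex)] = (rr_c, rr_f)

    @classmethod
    def uniform(cls, rr_current: float = 1.0, rr_former: float = 1.0,
                sexes: tuple[str, ...] = ("male", "female")) -> "RelativeRiskTable":
        rows = [
            {"sex": s, "age_group": b, "rr_current": rr_current, "rr_former": rr_former}
            for s in sexes for b in BANDS
        ]
        return cls(pd.DataFrame(rows))

    def arrays(self, sex: str) -> tuple[np.ndarray, np.ndarray]:
        """(rr_current, rr_former) per single year of age for one sex."""
        rc, rf = self._by_sex[sex]
        return rc.copy(), rf.copy()


class MortalitySchedule:
    """All-cause annual mortality rates by year, sex and age band.

    Built from a tidy frame (year, sex, age_group, all_cause_rate); a year
    absent from the table is an error when queried, never an extrapolation.
    """

    def __init__(self, table: pd.DataFrame) -> None:
        self._by_key: dict[tuple[int, str], np.ndarray] = {}
        for (year, sex), grp in table.groupby(["year", "sex"]):
            rates = {str(r["age_group"]).replace("–", "-"): float(r["all_cause_rate"]) for _, r in grp.iterrows()}
            missing = [b for b in BANDS if b not in rates]
            if missing:
                raise ConfigurationError(
                    f"mortality table for {sex} {year} missing bands {missing}"
                )
            arr = np.array([rates[b] for b in BAND_OF_AGE])
            if np.any((arr < 0) | (arr > 1)):
                raise ConfigurationError(f"mortality rates for {sex} {year} outside [0,1]")
            self._by_key[(int(year), str(sex))] = arr

    def all_cause(self, year: int, sex: str) -> np.ndarray:
        """Per-single-age all-cause rate for one sex and calendar year."""
        try:
            return self._by_key[(int(year), sex)].copy()
        except KeyError:
            raise ConfigurationError(
                f"no all-cause mortality for {sex} in {year}; "
                "supply every year of the projection horizon"
            ) from None

    def years(self, sex: str) -> list[int]:
        return sorted(y for (y, s) in self._by_key if s == sex)


def partition_mortality(
    all_cause: float | np.ndarray,
    prevalences: tuple[np.ndarray | float, np.ndarray | float, np.ndarray | float],
    rr: tuple[np.ndarray | float, np.ndarray | float],
) -> MortalityPartition:
    """Split an all-cause rate into never/current/former death probabilities.

    ``prevalences`` are the (never, current, former) shares of the living
    stratum (must be non-negative and sum to 1); ``rr`` is (rr_current,
    rr_former). Scalars and aligned arrays are both accepted.
    """
    p_n, p_c, p_f = (np.asarray(p, dtype=float) for p in prevalences)
    rr_c, rr_f = (np.asarray(r, dtype=float) for r in rr)
    m = np.asarray(all_cause, dtype=float)

    if np.any(p_n < 0) or np.any(p_c < 0) or np.any(p_f < 0):
        raise ContractViolationError("prevalences must be non-negative")
    total = p_n + p_c + p_f
    if np.any(np.abs(total - 1.0) > 1e-9):
        raise ContractViolationError("prevalences must sum to 1 per stratum")
    if np.any((m < 0) | (m > 1)):
        raise ContractViolationError("all-cause rate must be in [0,1]")

    denom = p_n + p_c * rr_c + p_f * rr_f
    if np.any(denom <= 0):
        raise ContractViolationError("degenerate partition denominator (no living population)")
    pd_n = m / denom
    pd_c = rr_c * pd_n
    pd_f = rr_f * pd_n
    for name, arr in (("never", pd_n), ("current", pd_c), ("former", pd_f)):
        if np.any(arr > 1.0 + 1e-12):
            bad = np.nonzero(np.atleast_1d(arr) > 1.0 + 1e-12)[0]
            raise ContractViolationError(
                f"pdying_{name} exceeds 1 at age offsets {bad.tolist()}"
            )

    def _unwrap(a: np.ndarray) -> float | np.ndarray:
        return float(a) if a.ndim == 0 else a

    return MortalityPartition(_unwrap(pd_n), _unwrap(pd_c), _unwrap(pd_f))


def attributable_deaths(states: "StateArrays", partition: MortalityPartition) -> float:
    """Smoking-attributable deaths for one cycle: the excess of current and
    former smokers' deaths over the never-smoker counterfactual, floored at
    0 per age before summation."""
    excess = (
        states.current * (np.asarray(partition.pdying_current) - np.asarray(partition.pdying_never))
        + states.former * (np.asarray(partition.pdying_former) - np.asarray(partition.pdying_never))
    )
    return float(np.sum(np.clip(excess, 0.0, None)))


def cumulative_lives_saved(baseline: "ProjectionResult", intervention: "ProjectionResult") -> float:
    """Cumulative attributable deaths under baseline minus those under the
    intervention, over the common (and required-identical) horizon."""
    if baseline.years != intervention.years or baseline.sex != intervention.sex:
        raise ConfigurationError(
            "baseline and intervention projections must share horizon and sex"
        )
    return float(baseline.cumulative_attributable() - intervention.cumulative_attributable())


def mortality_schedule_from_csv(path) -> MortalitySchedule:
    return MortalitySchedule(pd.read_csv(path))


def rr_table_from_csv(path) -> RelativeRiskTable:
    return RelativeRiskTable(pd.read_csv(path))


__all__ = [
    "MortalityPartition",
    "MortalitySchedule",
    "RelativeRiskTable",
    "partition_mortality",
    "attributable_deaths",
    "cumulative_lives_saved",
    "mortality_schedule_from_csv",
    "rr_table_from_csv",
]
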