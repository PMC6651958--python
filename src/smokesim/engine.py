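"""Four-state annual-cycle Markov engine, age-structured.

States are never smoker, current smoker, former smoker, plus an absorbing
death state. Each annual cycle applies, per single year of age, the
transition rows

    never   -> (1 - initiation - pdying_N,  initiation,              0,                       pdying_N)
    current -> (0,                          1 - cessation - pdying_C, cessation,              pdying_C)
    former  -> (0,                          relapse,                  1 - relapse - pdying_F, pdying_F)
    death   -> (0, 0, 0, 1)

after which the population is aged by one year (the open-ended top age
absorbs its predecessor) and a new cohort of 15-year-olds enters the never
state. Structural zeros: no flow never->former, and no flow back to the
never state from anywhere.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .ages import AGE_MIN, BANDS, N_AGES, aggregate_by_band
from .errors import ConfigurationError, ContractViolationError
from .mortality import (
    MortalityPartition,
    MortalitySchedule,
    RelativeRiskTable,
    attributable_deaths,
    partition_mortality,
)
from .policies import PolicyScenario, identity_scenario
from .rates import RateSchedule

STATE_NAMES = ("never", "current", "former")


def _as_age_array(x, name: str) -> np.ndarray:
    arr = np.broadcast_to(np.asarray(x, dtype=float), (N_AGES,)).copy()
    if not np.all(np.isfinite(arr)):
        raise ContractViolationError(f"{name} contains non-finite values")
    return arr


@dataclass
class StateArrays:
    """Living-population counts per single year of age, by smoking state."""

    never: np.ndarray
    current: np.ndarray
    former: np.ndarray

    def __post_init__(self) -> None:
        for name in STATE_NAMES:
            arr = _as_age_array(getattr(self, name), name)
            if np.any(arr < 0):
                raise ContractViolationError(f"negative {name} counts")
            setattr(self, name, arr)

    @property
    def alive(self) -> np.ndarray:
        return self.never + self.current + self.former

    def total_alive(self) -> float:
        return float(np.sum(self.alive))

    def copy(self) -> "StateArrays":
        return StateArrays(self.never.copy(), self.current.copy(), self.former.copy())

    @classmethod
    def zeros(cls) -> "StateArrays":
        return cls(np.zeros(N_AGES), np.zeros(N_AGES), np.zeros(N_AGES))

    @classmethod
    def from_prevalence(cls, population: np.ndarray, p_never, p_current, p_former) -> "StateArrays":
        """Split a per-age population by state shares (shares must sum to 1)."""
        pop = _as_age_array(population, "population")
        pn = _as_age_array(p_never, "p_never")
        pc = _as_age_array(p_current, "p_current")
        pf = _as_age_array(p_former, "p_former")
        if np.any(np.abs(pn + pc + pf - 1.0) > 1e-9):
            raise ContractViolationError("state shares must sum to 1 at every age")
        return cls(pop * pn, pop * pc, pop * pf)

    def shares(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """State shares of the living population; empty ages count as all-never
        so the mortality partition stays well-defined."""
        alive = self.alive
        safe = np.where(alive > 0, alive, 1.0)
        pn = np.where(alive > 0, self.never / safe, 1.0)
        pc = np.where(alive > 0, self.current / safe, 0.0)
        pf = np.where(alive > 0, self.former / safe, 0.0)
        return pn, pc, pf


@dataclass
class DeathCounts:
    """Deaths during one cycle, by smoking state at death."""

    never: np.ndarray
    current: np.ndarray
    former: np.ndarray

    def total(self) -> float:
        return float(np.sum(self.never + self.current + self.former))

    def by_state_totals(self) -> dict[str, float]:
        return {s: float(np.sum(getattr(self, s))) for s in STATE_NAMES}


def build_transition_row(
    state: str,
    *,
    initiation: float = 0.0,
    cessation: float = 0.0,
    relapse: float = 0.0,
    pdying: float = 0.0,
) -> np.ndarray:
    """One row of the annual transition matrix, ordered
    (never, current, former, death).

    Raises ContractViolationError if the competing flows out of the state
    exceed 1 (negative diagonal entry).
    """
    for name, v in (("initiation", initiation), ("cessation", cessation),
                    ("relapse", relapse), ("pdying", pdying)):
        if not (np.isfinite(v) and 0.0 <= v <= 1.0):
            raise ContractViolationError(f"{name} must be in [0,1], got {v}")
    if state == "never":
        stay = 1.0 - initiation - pdying
        row = np.array([stay, initiation, 0.0, pdying])
    elif state == "current":
        stay = 1.0 - cessation - pdying
        row = np.array([0.0, stay, cessation, pdying])
    elif state == "former":
        stay = 1.0 - relapse - pdying
        row = np.array([0.0, relapse, stay, pdying])
    elif state == "death":
        return np.array([0.0, 0.0, 0.0, 1.0])
    else:
        raise ValueError(f"unknown state {state!r}")
    if stay < -1e-12:
        raise ContractViolationError(
            f"flows out of {state!r} exceed 1 (diagonal {stay:.6g}): "
            f"initiation={initiation}, cessation={cessation}, relapse={relapse}, pdying={pdying}"
        )
    row[row < 0] = 0.0  # clamp -0.0 / rounding dust only
    return row


def step_cycle(
    states: StateArrays,
    initiation,
    cessation,
    relapse,
    pdying_never,
    pdying_current,
    pdying_former,
) -> tuple[StateArrays, DeathCounts]:
    """Apply one annual cycle of transitions to every age simultaneously.

    All rate arguments are scalars or per-age arrays. Returns the next-year
    counts at the same ages plus deaths by state of origin.
    """
    init = _as_age_array(initiation, "initiation")
    cess = _as_age_array(cessation, "cessation")
    rel = _as_age_array(relapse, "relapse")
    pd_n = _as_age_array(pdying_never, "pdying_never")
    pd_c = _as_age_array(pdying_current, "pdying_current")
    pd_f = _as_age_array(pdying_former, "pdying_former")

    for name, arr in (("initiation", init), ("cessation", cess), ("relapse", rel),
                      ("pdying_never", pd_n), ("pdying_current", pd_c), ("pdying_former", pd_f)):
        if np.any((arr < 0) | (arr > 1)):
            ages = (np.nonzero((arr < 0) | (arr > 1))[0] + AGE_MIN).tolist()
            raise ContractViolationError(f"{name} outside [0,1] at ages {ages}")
    for name, total in (("never", init + pd_n), ("current", cess + pd_c), ("former", rel + pd_f)):
        if np.any(total > 1.0 + 1e-12):
            ages = (np.nonzero(total > 1.0 + 1e-12)[0] + AGE_MIN).tolist()
            raise ContractViolationError(
                f"flows out of {name!r} exceed 1 at ages {ages}"
            )

    deaths = DeathCounts(
        never=states.never * pd_n,
        current=states.current * pd_c,
        former=states.former * pd_f,
    )
    new = StateArrays(
        never=states.never * (1.0 - init - pd_n),
        current=states.never * init + states.current * (1.0 - cess - pd_c) + states.former * rel,
        former=states.current * cess + states.former * (1.0 - rel - pd_f),
    )
    return new, deaths


def advance_age(states: StateArrays, entrants: float) -> StateArrays:
    """Shift every age up by one year; the top age absorbs its predecessor;
    the vacated age 15 receives ``entrants`` never smokers."""
    if not np.isfinite(entrants) or entrants < 0:
        raise ContractViolationError(f"entrants must be finite and >= 0, got {entrants}")

    def shift(arr: np.ndarray, newcomers: float) -> np.ndarray:
        out = np.empty_like(arr)
        out[0] = newcomers
        out[1:-1] = arr[:-2]
        out[-1] = arr[-2] + arr[-1]
        return out

    return StateArrays(
        never=shift(states.never, entrants),
        current=shift(states.current, 0.0),
        former=shift(states.former, 0.0),
    )


@dataclass
class ProjectionResult:
    """Year-by-year trajectory of one scenario for one sex."""

    sex: str
    scenario_label: str
    base_year: int
    years: list[int]
    states: dict[int, StateArrays]
    deaths: dict[int, DeathCounts] = field(default_factory=dict)
    attributable: dict[int, float] = field(default_factory=dict)
    entrants: dict[int, float] = field(default_factory=dict)
    clipped_strata: int = 0

    def prevalence(self, year: int, state: str = "current") -> float:
        """Prevalence (%) of a smoking state among the living 15+ population."""
        s = self.states[year]
        return 100.0 * float(np.sum(getattr(s, state))) / s.total_alive()

    def prevalence_series(self, state: str = "current") -> pd.Series:
        return pd.Series(
            {y: self.prevalence(y, state) for y in self.years}, name=f"{state}_prevalence_pct"
        )

    def total_deaths(self, year: int) -> float:
        return self.deaths[year].total()

    def death_years(self) -> list[int]:
        return sorted(self.deaths)

    def cumulative_deaths(self) -> float:
        return float(sum(d.total() for d in self.deaths.values()))

    def cumulative_attributable(self) -> float:
        return float(sum(self.attributable.values()))

    def states_df(self) -> pd.DataFrame:
        """Tidy trajectory: year, sex, age_group, state, count, prevalence(%)."""
        rows = []
        for year in self.years:
            s = self.states[year]
            alive_by_band = aggregate_by_band(s.alive)
            for state in STATE_NAMES:
                counts = aggregate_by_band(getattr(s, state))
                for band in BANDS:
                    alive = alive_by_band[band]
                    rows.append({
                        "year": year, "sex": self.sex, "age_group": band,
                        "state": state, "count": counts[band],
                        "prevalence": 100.0 * counts[band] / alive if alive > 0 else 0.0,
                    })
        return pd.DataFrame(rows)

    def deaths_df(self) -> pd.DataFrame:
        """Per-year deaths by smoking state plus attributable deaths."""
        rows = []
        for year in self.death_years():
            d = self.deaths[year]
            totals = d.by_state_totals()
            rows.append({
                "year": year, "sex": self.sex, "scenario": self.scenario_label,
                **{f"deaths_{k}": v for k, v in totals.items()},
                "deaths_total": d.total(),
                "attributable_deaths": self.attributable.get(year, 0.0),
            })
        return pd.DataFrame(rows)


def project(
    initial: StateArrays,
    rates: RateSchedule,
    mortality: MortalitySchedule,
    rr: RelativeRiskTable,
    entrants: Mapping[int, float],
    scenario: PolicyScenario | None = None,
    *,
    base_year: int,
    horizon_end: int,
    sex: str = "male",
) -> ProjectionResult:
    """Run the annual-cycle projection from ``base_year`` to ``horizon_end``.

    Each cycle: (1) the scenario multipliers are applied to the initiation
    and cessation schedules (products clipped into the feasible range, with
    the number of clipped age strata recorded); (2) all-cause mortality for
    the cycle year is partitioned into status-specific death probabilities
    using the stratum's evolving state shares and the relative risks;
    (3) transitions and deaths are applied; (4) the population is aged one
    year and the cohort of new 15-year-olds (``entrants[next_year]``) joins
    as never smokers. Missing mortality or entrant data for any year in the
    horizon is an error, never an extrapolation.
    """
    if horizon_end < base_year:
        raise ConfigurationError("horizon_end must be >= base_year")
    scen = scenario if scenario is not None else identity_scenario()

    init_base = rates.initiation(sex)
    cess_base = rates.cessation(sex)
    rr_c, rr_f = rr.arrays(sex)

    init = init_base * scen.initiation_mult
    cess = cess_base * scen.cessation_mult
    clipped = int(np.sum(init > 1.0) + np.sum(cess > 1.0))
    init = np.clip(init, 0.0, 1.0)
    cess = np.clip(cess, 0.0, 1.0)

    years = list(range(base_year, horizon_end + 1))
    for y in years[1:]:
        if y not in entrants:
            raise ConfigurationError(f"no entrant cohort supplied for year {y}")

    result = ProjectionResult(
        sex=sex, scenario_label=scen.label, base_year=base_year,
        years=years, states={base_year: initial.copy()},
        entrants={y: float(entrants[y]) for y in years[1:]},
    )

    current_states = initial.copy()
    extra_clipped = 0
    for year in years[:-1]:
        m = mortality.all_cause(year, sex)
        shares = current_states.shares()
        part = partition_mortality(m, shares, (rr_c, rr_f))
        pd_n = np.asarray(part.pdying_never)
        pd_c = np.asarray(part.pdying_current)
        pd_f = np.asarray(part.pdying_former)

        # keep the competing flows feasible after scenario scaling
        cess_y = cess
        over = cess + pd_c > 1.0
        if np.any(over):
            extra_clipped += int(np.sum(over))
            cess_y = np.minimum(cess, 1.0 - pd_c)
        init_y = init
        over = init + pd_n > 1.0
        if np.any(over):
            extra_clipped += int(np.sum(over))
            init_y = np.minimum(init, 1.0 - pd_n)

        new_states, deaths = step_cycle(
            current_states, init_y, cess_y, rates.relapse, pd_n, pd_c, pd_f
        )
        attrib = attributable_deaths(current_states, part)

        next_year = year + 1
        current_states = advance_age(new_states, entrants[next_year])
        result.states[next_year] = current_states.copy()
        result.deaths[next_year] = deaths
        result.attributable[next_year] = attrib
    result.clipped_strata = clipped + extra_clipped
    return result


__all__ = [
    "STATE_NAMES",
    "StateArrays",
    "DeathCounts",
    "ProjectionResult",
    "build_transition_row",
    "step_cycle",
    "advance_age",
    "project",
]
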