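"""Age x period rate tables, cohort labelling and direct standardization.

Rates live on a Lexis grid of 5-year age groups (20-24 ... 75-79)
crossed with 5-year calendar periods.  Crossing a 5-year age group with
a 5-year period implies an overlapping ~10-year birth interval; by the
usual synthetic-cohort convention it is labelled by its central 5
years, computed from integer bin midpoints (start + 2), so that e.g.
age 75-79 in period 1989-1993 belongs to cohort 1912-1916.

Age-standardized mortality rates (ASMR) use the direct method: a
weighted mean of age-specific rates under a fixed standard population,
by default Segi's 1960 world standard restricted to ages 20-79.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


@dataclass(frozen=True, order=True)
class AgeGroup:
    """5-year age group; ``start`` is 20, 25, ..., 75."""

    start: int
    width: int = 5

    def __post_init__(self) -> None:
        if self.width != 5 or self.start % 5 or not (20 <= self.start <= 75):
            raise ValueError(f"invalid age group start={self.start} width={self.width}")

    @property
    def midpoint(self) -> int:
        return self.start + 2

    @property
    def label(self) -> str:
        return f"{self.start}-{self.start + self.width - 1}"


@dataclass(frozen=True, order=True)
class PeriodBin:
    """5-year calendar period starting at ``start_year``."""

    start_year: int
    width: int = 5

    @property
    def midpoint(self) -> int:
        return self.start_year + 2

    @property
    def label(self) -> str:
        return f"{self.start_year}-{self.start_year + self.width - 1}"

    @property
    def years(self) -> range:
        return range(self.start_year, self.start_year + self.width)


@dataclass(frozen=True, order=True)
class CohortBin:
    """5-year birth cohort; derived from age x period, never user-supplied."""

    start_year: int
    width: int = 5

    @property
    def midpoint(self) -> int:
        return self.start_year + 2

    @property
    def label(self) -> str:
        return f"{self.start_year}-{self.start_year + self.width - 1}"


#: Segi (1960) world standard population, ages 20-79, in the order
#: 20-24 ... 75-79.  Renormalized over the included groups at use.
SEGI_WORLD_1960_WEIGHTS_20_79 = {
    20: 8000,
    25: 8000,
    30: 6000,
    35: 6000,
    40: 6000,
    45: 6000,
    50: 5000,
    55: 4000,
    60: 4000,
    65: 3000,
    70: 2000,
    75: 1000,
}


@dataclass
class StandardPopulation:
    """Age-group weights for direct standardization, keyed by group start."""

    weights: dict[int, float]

    def __post_init__(self) -> None:
        if any(w < 0 for w in self.weights.values()):
            raise ValueError("standard population weights must be nonnegative")
        if sum(self.weights.values()) <= 0:
            raise ValueError("standard population has zero total weight")

    @classmethod
    def segi_1960(cls) -> "StandardPopulation":
        return cls(dict(SEGI_WORLD_1960_WEIGHTS_20_79))


@dataclass
class RateTable:
    """Death counts and person-years on one country/cancer Lexis grid."""

    country: str
    cancer: str
    age_groups: list[AgeGroup]
    period_bins: list[PeriodBin]
    deaths: np.ndarray
    person_years: np.ndarray
    imputed_years: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.deaths = np.asarray(self.deaths, dtype=float)
        self.person_years = np.asarray(self.person_years, dtype=float)
        A, P = len(self.age_groups), len(self.period_bins)
        if self.deaths.shape != (A, P) or self.person_years.shape != (A, P):
            raise ValueError(
                f"deaths/person_years must be {A}x{P}; got "
                f"{self.deaths.shape} and {self.person_years.shape}"
            )
        if (self.deaths < 0).any():
            raise ValueError("negative death count in rate table")
        if (self.person_years <= 0).any():
            raise ValueError("cells with zero or negative person-years are invalid")

    @property
    def shape(self) -> tuple[int, int]:
        return len(self.age_groups), len(self.period_bins)

    def cohort_bins(self) -> list[CohortBin]:
        """All A+P-1 cohorts, oldest (k=1) first."""
        A, P = self.shape
        oldest = cohort_label(self.age_groups[-1], self.period_bins[0])
        return [CohortBin(oldest.start_year + 5 * k) for k in range(A + P - 1)]


def impute_missing_year(
    series: Mapping[int, float], missing_year: int, k: int = 4
) -> float:
    """Mean of the ``k`` available years nearest in time to ``missing_year``.

    Distance ties are broken toward earlier years.  Raises if fewer
    than ``k`` years are available.
    """
    available = sorted(y for y in series if y != missing_year)
    if len(available) < k:
        raise ValueError(
            f"need {k} available years to impute {missing_year}; "
            f"have {len(available)}"
        )
    nearest = sorted(available, key=lambda y: (abs(y - missing_year), y))[:k]
    return float(np.mean([series[y] for y in nearest]))


def cohort_index(age_position: int, period_position: int, A: int) -> int:
    """1-based cohort index k = A - age_position + period_position.

    Age position 1 is the youngest group; k = 1 is the oldest cohort
    (oldest age group in the earliest period).
    """
    if not 1 <= age_position <= A:
        raise ValueError(f"age position {age_position} out of 1..{A}")
    if period_position < 1:
        raise ValueError(f"period position {period_position} out of range")
    return A - age_position + period_position


def cohort_label(age: AgeGroup, period: PeriodBin) -> CohortBin:
    """Central 5-year birth cohort for one Lexis cell.

    Cohort midpoint = period midpoint - age midpoint; the bin starts
    two years before its midpoint.
    """
    mid = period.midpoint - age.midpoint
    return CohortBin(mid - 2)


def bin_years(
    records: pd.DataFrame,
    bins: list[PeriodBin],
    imputation: str = "none",
    k: int = 4,
    country: str = "",
    cancer: str = "",
) -> RateTable:
    """Aggregate per-year, per-age counts into a RateTable.

    ``records`` must have columns year, age_start, deaths, population.
    Each cell sums its bin's yearly deaths and populations (population
    summed over calendar years is the person-years exposure).  Years
    missing from a bin are filled under ``imputation``:

    - ``"none"``: any missing year is a hard error naming the bin;
    - ``"nearest-mean"``: the missing year's deaths and population are
      each replaced, per age group, by the mean of the ``k`` nearest
      available calendar years.
    """
    if imputation not in ("none", "nearest-mean"):
        raise ValueError(f"unknown imputation policy {imputation!r}")
    age_starts = sorted(records["age_start"].unique())
    age_groups = [AgeGroup(int(a)) for a in age_starts]
    A, P = len(age_groups), len(bins)

    deaths_series: dict[int, dict[int, float]] = {}
    pop_series: dict[int, dict[int, float]] = {}
    for a in age_starts:
        sub = records[records["age_start"] == a]
        deaths_series[a] = dict(zip(sub["year"].astype(int), sub["deaths"].astype(float)))
        pop_series[a] = dict(zip(sub["year"].astype(int), sub["population"].astype(float)))

    years_present = set(records["year"].astype(int))
    deaths = np.zeros((A, P))
    person_years = np.zeros((A, P))
    imputed: set[int] = set()
    for j, pb in enumerate(bins):
        missing = [y for y in pb.years if y not in years_present]
        if missing and imputation == "none":
            raise ValueError(
                f"period bin {pb.label} is missing years {missing} and no "
                "imputation policy is active"
            )
        if len(missing) == pb.width:
            raise ValueError(f"period bin {pb.label} has zero available years")
        for i, ag in enumerate(age_groups):
            a = ag.start
            d = p = 0.0
            for y in pb.years:
                if y in years_present:
                    d += deaths_series[a].get(y, 0.0)
                    p += pop_series[a].get(y, 0.0)
                else:
                    d += impute_missing_year(deaths_series[a], y, k)
                    p += impute_missing_year(pop_series[a], y, k)
                    imputed.add(y)
            deaths[i, j] = d
            person_years[i, j] = p
    if imputed:
        logger.info("imputed calendar years %s", sorted(imputed))

    return RateTable(
        country=country,
        cancer=cancer,
        age_groups=age_groups,
        period_bins=list(bins),
        deaths=deaths,
        person_years=person_years,
        imputed_years=sorted(imputed),
    )


def age_specific_rates(table: RateTable) -> np.ndarray:
    """A x P mortality rates per 100,000 person-years."""
    return 1e5 * table.deaths / table.person_years


def asmr(
    rates_by_age: Mapping[int, float], standard: StandardPopulation
) -> float:
    """Direct age-standardized rate: weighted mean of age-specific rates.

    Weights are the standard population restricted to the age groups
    present, renormalized; a group missing from the standard is an
    error.
    """
    missing = [a for a in rates_by_age if a not in standard.weights]
    if missing:
        raise KeyError(f"standard population lacks weights for age groups {missing}")
    ages = sorted(rates_by_age)
    w = np.array([standard.weights[a] for a in ages], dtype=float)
    r = np.array([rates_by_age[a] for a in ages], dtype=float)
    return float(np.dot(w, r) / w.sum())


def asmr_by_year(
    records: pd.DataFrame, standard: StandardPopulation
) -> pd.DataFrame:
    """Yearly ASMR series from a tidy per-year, per-age frame.

    Returns columns ``year``, ``asmr`` (per 100,000 person-years).
    """
    rows = []
    for year, sub in records.groupby("year"):
        rates = {
            int(a): 1e5 * d / p
            for a, d, p in zip(sub["age_start"], sub["deaths"], sub["population"])
            if p > 0
        }
        rows.append({"year": int(year), "asmr": asmr(rates, standard)})
    return pd.DataFrame(rows).sort_values("year", ignore_index=True)
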