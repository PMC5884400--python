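"""APC-structured synthetic mortality data with known ground truth.

Generates smooth random age/period/cohort effect curves, simulates
Poisson death counts over a Lexis grid, and emits fixture files in the
WHO Mortality Database dialect so the whole pipeline — flat-file
reading, year binning, imputation, standardization, IE fitting — is
testable offline against a known truth.

The effect curves are smooth (random cubic trends plus scaled noise)
rather than white noise, mimicking the monotone age effects and gentle
cohort curves seen in real cancer mortality surfaces.  By default the
stacked effect vector is projected off the design's null vector B0, so
the truth is exactly what the Intrinsic Estimator targets; switching
the projection off makes the identification problem itself observable
(the IE then recovers the projected truth, not the raw truth).
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .ie import build_design
from .lexis import AgeGroup, PeriodBin, RateTable
from .who_io import AGE_2079_COLUMNS, AGE_2079_STARTS, N_AGE_COLUMNS


@dataclass
class SyntheticSpec:
    """True effect curves, exposure surface and seed for one simulation.

    ``first_period_start`` anchors the grid on the calendar so fixture
    files carry real years; the default mirrors a 12 age-group x 5
    period design starting 1989.
    """

    A: int
    P: int
    mu: float
    alpha: np.ndarray
    beta: np.ndarray
    gamma: np.ndarray
    exposure: np.ndarray
    seed: int
    first_age_start: int = 20
    first_period_start: int = 1989
    missing_years: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.alpha = np.asarray(self.alpha, dtype=float)
        self.beta = np.asarray(self.beta, dtype=float)
        self.gamma = np.asarray(self.gamma, dtype=float)
        self.exposure = np.asarray(self.exposure, dtype=float)
        C = self.A + self.P - 1
        if (len(self.alpha), len(self.beta), len(self.gamma)) != (self.A, self.P, C):
            raise ValueError("effect vector lengths must be (A, P, A+P-1)")
        if self.exposure.shape != (self.A, self.P):
            raise ValueError(f"exposure must be {self.A}x{self.P}")
        for name, v in (("alpha", self.alpha), ("beta", self.beta), ("gamma", self.gamma)):
            if abs(v.sum()) > 1e-6:
                raise ValueError(f"{name} must sum to zero (got {v.sum():.3g})")

    @property
    def age_groups(self) -> list[AgeGroup]:
        return [AgeGroup(self.first_age_start + 5 * i) for i in range(self.A)]

    @property
    def period_bins(self) -> list[PeriodBin]:
        return [PeriodBin(self.first_period_start + 5 * j) for j in range(self.P)]

    def log_rate_surface(self) -> np.ndarray:
        """A x P matrix of mu + alpha_i + beta_j + gamma_k."""
        A, P = self.A, self.P
        surf = np.empty((A, P))
        for i in range(A):
            for j in range(P):
                k = A - (i + 1) + (j + 1)  # 1-based cohort index
                surf[i, j] = self.mu + self.alpha[i] + self.beta[j] + self.gamma[k - 1]
        return surf


def _smooth_curve(n: int, smoothness: float, rng: np.random.Generator) -> np.ndarray:
    """Random cubic trend plus noise shrinking with ``smoothness``."""
    t = np.linspace(-1.0, 1.0, n)
    coefs = rng.normal(scale=[1.0, 1.0, 0.5, 0.25], size=4)
    curve = coefs[0] + coefs[1] * t + coefs[2] * t**2 + coefs[3] * t**3
    noise = rng.normal(scale=0.05 / max(smoothness, 1e-6), size=n)
    return curve + noise


def make_effects(
    A: int,
    P: int,
    smoothness: float = 1.0,
    seed: int = 0,
    orthogonalize: bool = True,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Draw centered smooth effect curves, optionally orthogonal to B0.

    Each block is centered to sum zero; with ``orthogonalize`` the
    stacked reduced coefficient vector is projected off the design's
    null vector and re-centered, so the curves are exactly what the IE
    estimates in expectation.
    """
    if A < 3 or P < 3:
        raise ValueError("need A, P >= 3")
    rng = np.random.default_rng(seed)
    C = A + P - 1
    alpha = _smooth_curve(A, smoothness, rng)
    beta = _smooth_curve(P, smoothness, rng)
    gamma = _smooth_curve(C, smoothness, rng)
    alpha -= alpha.mean()
    beta -= beta.mean()
    gamma -= gamma.mean()
    if orthogonalize:
        alpha, beta, gamma = project_off_null(alpha, beta, gamma)
    return alpha, beta, gamma


def project_off_null(
    alpha: np.ndarray, beta: np.ndarray, gamma: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Remove the B0 component from stacked sum-to-zero effect vectors."""
    A, P = len(alpha), len(beta)
    design = build_design(A, P)
    b0 = design.null_vector
    v = np.concatenate([[0.0], alpha[:-1], beta[:-1], gamma[:-1]])
    v = v - (v @ b0) * b0
    idx = design.column_index

    def expand(block: range) -> np.ndarray:
        coefs = v[list(block)]
        full = np.concatenate([coefs, [-coefs.sum()]])
        return full - full.mean()  # re-center against float drift

    return expand(idx["age"]), expand(idx["period"]), expand(idx["cohort"])


#: Default baseline log mortality rate: 200 deaths per 100,000
#: person-years.  High for a single cancer site but keeps every Lexis
#: cell informative — including the single-cell corner cohorts, whose
#: coefficient uncertainty is driven entirely by that one cell's count.
DEFAULT_MU = float(np.log(2e-3))


def make_spec(
    A: int = 12,
    P: int = 5,
    mu: float = DEFAULT_MU,
    exposure_per_cell: float = 1e6,
    smoothness: float = 1.0,
    seed: int = 0,
    orthogonalize: bool = True,
    first_period_start: int = 1989,
    missing_years: list[int] | None = None,
) -> SyntheticSpec:
    """Convenience constructor with a flat exposure surface.

    Defaults mirror the 12 age-group x 5 period study design, with
    expected cell counts in the low thousands at the default exposure.
    """
    alpha, beta, gamma = make_effects(A, P, smoothness, seed, orthogonalize)
    return SyntheticSpec(
        A=A,
        P=P,
        mu=mu,
        alpha=alpha,
        beta=beta,
        gamma=gamma,
        exposure=np.full((A, P), exposure_per_cell),
        seed=seed,
        first_period_start=first_period_start,
        missing_years=list(missing_years or []),
    )


def simulate_counts(spec: SyntheticSpec) -> RateTable:
    """Draw Poisson death counts around the spec's rate surface."""
    if (spec.exposure <= 0).any():
        raise ValueError("exposure must be positive everywhere")
    lam = spec.exposure * np.exp(spec.log_rate_surface())
    rng = np.random.default_rng(spec.seed)
    deaths = rng.poisson(lam).astype(float)
    return RateTable(
        country="synthetic",
        cancer="synthetic",
        age_groups=spec.age_groups,
        period_bins=spec.period_bins,
        deaths=deaths,
        person_years=spec.exposure.copy(),
    )


def yearly_records(spec: SyntheticSpec, table: RateTable) -> pd.DataFrame:
    """Spread a binned table into per-year rows (deterministic split).

    Each 5-year cell's deaths are split integer-evenly across its
    calendar years with the remainder assigned to the earliest years;
    person-years are split evenly.  Binning the result reproduces the
    table exactly.  Years in ``spec.missing_years`` are omitted,
    leaving a gap for the imputation rule to fill.
    """
    rows = []
    for i, ag in enumerate(table.age_groups):
        for j, pb in enumerate(table.period_bins):
            d = int(table.deaths[i, j])
            w = pb.width
            base, rem = divmod(d, w)
            for offset, year in enumerate(pb.years):
                if year in spec.missing_years:
                    continue
                rows.append(
                    {
                        "year": year,
                        "age_start": ag.start,
                        "deaths": base + (1 if offset < rem else 0),
                        "population": table.person_years[i, j] / w,
                    }
                )
    return pd.DataFrame(rows, columns=["year", "age_start", "deaths", "population"])


def write_who_fixture(
    spec: SyntheticSpec,
    out_dir,
    country_code: str = "3325",
    cause_code: str = "C509",
    include_male_row: bool = False,
) -> tuple[Path, Path]:
    """Write deaths + population files in the WHO dialect for ``spec``.

    The files round-trip through the flat-file reader and year binning
    to the same RateTable the spec simulates (exactly for deaths, to
    float precision for person-years).  Optionally adds a male row that
    a correct reader must drop.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    table = simulate_counts(spec)
    records = yearly_records(spec, table)

    deaths_path = out_dir / "synthetic_morticd.csv"
    pop_path = out_dir / "synthetic_pop.csv"
    age_col_of_start = dict(zip(AGE_2079_STARTS, AGE_2079_COLUMNS))

    death_header = (
        ["Country", "Admin1", "SubDiv", "Year", "List", "Cause", "Sex", "Frmat", "IM_Frmat"]
        + [f"Deaths{i}" for i in range(1, N_AGE_COLUMNS + 1)]
    )
    pop_header = (
        ["Country", "Admin1", "SubDiv", "Year", "Sex", "Frmat"]
        + [f"Pop{i}" for i in range(1, N_AGE_COLUMNS + 1)]
    )

    with open(deaths_path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(death_header)
        for year, sub in records.groupby("year"):
            cells = [0] * N_AGE_COLUMNS
            for _, row in sub.iterrows():
                cells[age_col_of_start[int(row["age_start"])] - 1] = int(row["deaths"])
            cells[0] = sum(cells[1:])
            writer.writerow(
                [country_code, "", "", int(year), "10M", cause_code, 2, "01", "01"] + cells
            )
            if include_male_row:
                writer.writerow(
                    [country_code, "", "", int(year), "10M", cause_code, 1, "01", "01"]
                    + [3] * N_AGE_COLUMNS
                )

    with open(pop_path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(pop_header)
        for year, sub in records.groupby("year"):
            cells = [0.0] * N_AGE_COLUMNS
            for _, row in sub.iterrows():
                cells[age_col_of_start[int(row["age_start"])] - 1] = float(row["population"])
            cells[0] = sum(cells[1:])
            writer.writerow([country_code, "", "", int(year), 2, "01"] + [repr(c) for c in cells])

    return deaths_path, pop_path
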