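"""Reader for WHO Mortality Database flat files.

The WHO Mortality Database distributes cause-of-death counts as
comma-separated "Morticd" files with one row per (country, year, cause,
sex) stratum and 26 fixed age columns ``Deaths1..Deaths26`` (column 1 =
all ages, columns 2-6 = single years 0-4, columns 7-25 = 5-year bands
5-9 ... 95+, column 26 = age unknown), and population denominators in a
companion "pop" file with the analogous ``Pop1..Pop26`` layout.  This
module parses both dialects into validated records restricted to a
single country, sex and ICD cause set, and maps the fixed columns onto
the twelve 5-year age groups 20-24 ... 75-79 used throughout the
package (ages below 20 and 80+ are discarded).

Only age formats ("Frmat") 00 and 01 are accepted: both carry full
5-year detail from age 20 upward, so the 20-79 slice occupies columns
10..21 regardless.  Coarser formats would need disaggregation and are
rejected with a per-row warning rather than guessed at.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Number of fixed age columns in the WHO dialect.
N_AGE_COLUMNS = 26

#: 1-based WHO column positions holding ages 20-24 ... 75-79 under
#: Frmat 00/01 (Deaths10..Deaths21 / Pop10..Pop21).
AGE_2079_COLUMNS = tuple(range(10, 22))

#: Age-group start years matching :data:`AGE_2079_COLUMNS`.
AGE_2079_STARTS = tuple(range(20, 80, 5))

#: Frmat codes with full 5-year detail over ages 20-79.
SUPPORTED_AGE_FORMATS = frozenset({"00", "01"})

#: Minimal built-in WHO country code dictionary for the three study
#: populations.  Anything else must be passed as an explicit code.
COUNTRY_CODES = {
    "japan": "3160",
    "republic of korea": "3325",
    "singapore": "3350",
}

SEX_CODES = {"1": "male", "2": "female", "9": "unspecified"}

#: Built-in ICD-10 cause sets; prefix match covers 4-character codes
#: such as C509.
ICD10_CAUSE_SETS = {
    "breast": ("C50",),
    "cervical": ("C53",),
    "ovarian": ("C56",),
}


class WHOFormatError(ValueError):
    """Malformed WHO flat file (missing columns, bad layout)."""


class AgeFormatError(ValueError):
    """Row uses an age format without 5-year detail over 20-79."""


class NoRecordsError(ValueError):
    """A filter matched zero rows — explicit, never silent."""


@dataclass(frozen=True)
class CauseSelector:
    """ICD cause-code set for one cancer site, matched by prefix."""

    cancer_name: str
    icd10_codes: tuple[str, ...]

    @classmethod
    def for_cancer(cls, cancer_name: str) -> "CauseSelector":
        try:
            codes = ICD10_CAUSE_SETS[cancer_name]
        except KeyError:
            raise KeyError(
                f"no built-in ICD-10 code set for {cancer_name!r}; "
                f"known: {sorted(ICD10_CAUSE_SETS)}"
            ) from None
        return cls(cancer_name, codes)

    def matches(self, cause_code: str) -> bool:
        code = cause_code.strip().upper()
        return any(code.startswith(prefix) for prefix in self.icd10_codes)


@dataclass
class RawDeathRecord:
    country_code: str
    year: int
    icd_revision: str
    cause_code: str
    sex: str
    age_format: str
    deaths_by_column: list[int]

    def __post_init__(self) -> None:
        if len(self.deaths_by_column) != N_AGE_COLUMNS:
            raise WHOFormatError(
                f"expected {N_AGE_COLUMNS} deaths columns, "
                f"got {len(self.deaths_by_column)}"
            )
        if any(c < 0 for c in self.deaths_by_column):
            raise WHOFormatError("negative death count")


@dataclass
class RawPopulationRecord:
    country_code: str
    year: int
    sex: str
    age_format: str
    population_by_column: list[float]

    def __post_init__(self) -> None:
        if len(self.population_by_column) != N_AGE_COLUMNS:
            raise WHOFormatError(
                f"expected {N_AGE_COLUMNS} population columns, "
                f"got {len(self.population_by_column)}"
            )
        if any(p < 0 for p in self.population_by_column):
            raise WHOFormatError("negative population count")


@dataclass
class ReadReport:
    """Per-read accounting of rejected rows."""

    n_read: int = 0
    n_kept: int = 0
    n_rejected_age_format: int = 0
    rejected_age_formats: list[str] = field(default_factory=list)


def _norm_columns(df: pd.DataFrame) -> dict[str, str]:
    return {c.strip().lower(): c for c in df.columns}


def _require(colmap: dict[str, str], names: list[str], path) -> None:
    missing = [n for n in names if n.lower() not in colmap]
    if missing:
        raise WHOFormatError(f"{path}: missing required columns {missing}")


def _is_national(row, colmap) -> bool:
    for key in ("admin1", "subdiv"):
        col = colmap.get(key)
        if col is None:
            continue
        val = row[col]
        if pd.notna(val) and str(val).strip() not in ("", "0"):
            return False
    return True


def _cell_counts(row, prefix: str, colmap: dict[str, str]) -> list[float]:
    out = []
    for i in range(1, N_AGE_COLUMNS + 1):
        col = colmap.get(f"{prefix}{i}".lower())
        val = row[col] if col is not None else np.nan
        if pd.isna(val) or str(val).strip() == "":
            out.append(np.nan)
        else:
            out.append(float(val))
    return out


def _fill_missing(counts: list[float], context: str) -> list[float]:
    n_missing = sum(1 for c in counts if np.isnan(c))
    if n_missing:
        logger.warning(
            "%s: %d missing-coded age cells treated as 0", context, n_missing
        )
    return [0.0 if np.isnan(c) else c for c in counts]


def read_deaths(
    path,
    selector: CauseSelector,
    sex: str = "female",
    country: str = "3325",
    include_subnational: bool = False,
    report: ReadReport | None = None,
) -> list[RawDeathRecord]:
    """Read a WHO Morticd deaths file filtered to one stratum.

    Returns records for the requested ``country`` code, ``sex`` and the
    selector's cause set (prefix match), sorted by year; duplicate
    (year, cause) rows within the stratum are summed.  Rows carrying an
    unsupported age format are dropped with a logged warning and
    counted in ``report``.  Zero matching rows raises
    :class:`NoRecordsError`.
    """
    df = pd.read_csv(path, dtype=str)
    colmap = _norm_columns(df)
    _require(colmap, ["Country", "Year", "Cause", "Sex", "Frmat", "Deaths1"], path)

    if report is None:
        report = ReadReport()
    by_key: dict[tuple[int, str], RawDeathRecord] = {}
    for _, row in df.iterrows():
        report.n_read += 1
        if str(row[colmap["country"]]).strip() != str(country):
            continue
        if SEX_CODES.get(str(row[colmap["sex"]]).strip(), "unspecified") != sex:
            continue
        cause = str(row[colmap["cause"]]).strip()
        if not selector.matches(cause):
            continue
        if not include_subnational and not _is_national(row, colmap):
            continue
        frmat = str(row[colmap["frmat"]]).strip().zfill(2)
        if frmat not in SUPPORTED_AGE_FORMATS:
            report.n_rejected_age_format += 1
            report.rejected_age_formats.append(frmat)
            logger.warning(
                "%s: dropped year %s cause %s with age format %s "
                "(no 5-year detail)",
                path,
                row[colmap["year"]],
                cause,
                frmat,
            )
            continue
        year = int(float(row[colmap["year"]]))
        counts = _fill_missing(
            _cell_counts(row, "Deaths", colmap), f"{path} year {year}"
        )
        counts_int = [int(round(c)) for c in counts]
        key = (year, cause)
        if key in by_key:
            prev = by_key[key]
            merged = [a + b for a, b in zip(prev.deaths_by_column, counts_int)]
            by_key[key] = RawDeathRecord(
                prev.country_code, year, prev.icd_revision, cause, sex, frmat, merged
            )
        else:
            icd_rev = str(row[colmap["list"]]).strip() if "list" in colmap else ""
            by_key[key] = RawDeathRecord(
                str(country), year, icd_rev, cause, sex, frmat, counts_int
            )
        report.n_kept += 1

    if not by_key:
        raise NoRecordsError(
            f"{path}: no rows match country={country} sex={sex} "
            f"causes={selector.icd10_codes}"
        )
    return sorted(by_key.values(), key=lambda r: (r.year, r.cause_code))


def read_population(
    path,
    country: str = "3325",
    sex: str = "female",
    include_subnational: bool = False,
) -> list[RawPopulationRecord]:
    """Read a WHO pop file filtered to one country and sex, sorted by year."""
    df = pd.read_csv(path, dtype=str)
    colmap = _norm_columns(df)
    _require(colmap, ["Country", "Year", "Sex", "Frmat", "Pop1"], path)

    by_year: dict[int, RawPopulationRecord] = {}
    for _, row in df.iterrows():
        if str(row[colmap["country"]]).strip() != str(country):
            continue
        if SEX_CODES.get(str(row[colmap["sex"]]).strip(), "unspecified") != sex:
            continue
        if not include_subnational and not _is_national(row, colmap):
            continue
        frmat = str(row[colmap["frmat"]]).strip().zfill(2)
        if frmat not in SUPPORTED_AGE_FORMATS:
            logger.warning("%s: dropped population row with age format %s", path, frmat)
            continue
        year = int(float(row[colmap["year"]]))
        pops = _fill_missing(_cell_counts(row, "Pop", colmap), f"{path} year {year}")
        if year in by_year:
            prev = by_year[year].population_by_column
            pops = [a + b for a, b in zip(prev, pops)]
        by_year[year] = RawPopulationRecord(str(country), year, sex, frmat, pops)

    if not by_year:
        raise NoRecordsError(f"{path}: no population rows match country={country} sex={sex}")
    return [by_year[y] for y in sorted(by_year)]


def columns_to_age_groups(
    record: RawDeathRecord | RawPopulationRecord,
) -> dict[int, float]:
    """Map a record's 26 fixed columns onto the twelve 20-79 age groups.

    Returns ``{20: count, 25: count, ..., 75: count}``.  Columns outside
    20-79 (childhood ages, 80+, age unknown) are discarded.
    """
    frmat = record.age_format.zfill(2)
    if frmat not in SUPPORTED_AGE_FORMATS:
        raise AgeFormatError(
            f"age format {frmat!r} lacks 5-year detail over ages 20-79; "
            f"supported: {sorted(SUPPORTED_AGE_FORMATS)}"
        )
    values = (
        record.deaths_by_column
        if isinstance(record, RawDeathRecord)
        else record.population_by_column
    )
    return {
        start: float(values[col - 1])
        for start, col in zip(AGE_2079_STARTS, AGE_2079_COLUMNS)
    }


def to_long(
    death_records: list[RawDeathRecord],
    population_records: list[RawPopulationRecord],
) -> pd.DataFrame:
    """Join deaths and populations into a tidy per-year, per-age frame.

    Deaths are summed across cause codes within each year (the cause
    filter has already been applied).  Output columns: ``year``,
    ``age_start``, ``deaths``, ``population``.  Years with deaths but no
    population row are dropped with a warning (no denominator).
    """
    deaths_by_year: dict[int, dict[int, float]] = {}
    for rec in death_records:
        by_age = columns_to_age_groups(rec)
        acc = deaths_by_year.setdefault(rec.year, {a: 0.0 for a in AGE_2079_STARTS})
        for a, v in by_age.items():
            acc[a] += v

    pop_by_year = {rec.year: columns_to_age_groups(rec) for rec in population_records}

    rows = []
    for year in sorted(deaths_by_year):
        if year not in pop_by_year:
            logger.warning("year %d has deaths but no population row; dropped", year)
            continue
        for a in AGE_2079_STARTS:
            rows.append(
                {
                    "year": year,
                    "age_start": a,
                    "deaths": deaths_by_year[year][a],
                    "population": pop_by_year[year][a],
                }
            )
    return pd.DataFrame(rows, columns=["year", "age_start", "deaths", "population"])
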