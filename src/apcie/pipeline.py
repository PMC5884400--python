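"""Config-driven orchestration: ASMR series, APC-IE fits, simulations.

Each entry point takes an :class:`~apcie.config.AnalysisConfig` and
writes tidy CSV/JSON outputs plus an optional basic line plot per
country x cancer.  In fixture mode the inputs are synthetic WHO-dialect
files generated on the fly, so the full path — flat file in, tables
out — runs without any download.
"""

from __future__ import annotations

import json
import logging
import zlib
from pathlib import Path

import numpy as np
import pandas as pd

from . import ie, lexis, synthetic, who_io
from .config import AnalysisConfig, CountryConfig

logger = logging.getLogger(__name__)


def _standard(config: AnalysisConfig) -> lexis.StandardPopulation:
    return lexis.StandardPopulation(dict(config.standard_population))


def _selector(config: AnalysisConfig, cancer: str) -> who_io.CauseSelector:
    codes = tuple(config.cause_maps.get("10", {}).get(cancer, ()))
    if not codes:
        raise KeyError(f"no ICD-10 cause codes configured for {cancer!r}")
    return who_io.CauseSelector(cancer, codes)


def _load_long(
    config: AnalysisConfig, country: CountryConfig, cancer: str
) -> pd.DataFrame:
    selector = _selector(config, cancer)
    deaths = who_io.read_deaths(
        config.deaths_file,
        selector,
        sex="female",
        country=country.code,
        include_subnational=config.include_subnational,
    )
    pops = who_io.read_population(
        config.population_file,
        country=country.code,
        sex="female",
        include_subnational=config.include_subnational,
    )
    return who_io.to_long(deaths, pops)


def _fixture_long(
    config: AnalysisConfig, country: CountryConfig, cancer: str, out_dir: Path
) -> pd.DataFrame:
    """Generate a WHO-dialect fixture for this stratum and read it back."""
    lo, hi = config.window_for(country, cancer)
    P = (hi - lo + 1) // 5
    # stable per-stratum seed offset (hash() is salted per process)
    offset = zlib.crc32(f"{country.name}/{cancer}".encode()) % 10_000
    spec = synthetic.make_spec(
        A=12,
        P=P,
        seed=config.seed + offset,
        first_period_start=lo,
    )
    fix_dir = out_dir / "fixtures" / f"{country.name}_{cancer}".replace(" ", "_")
    deaths_path, pop_path = synthetic.write_who_fixture(
        spec, fix_dir, country_code=country.code
    )
    sub = AnalysisConfig(
        countries=[country],
        cancers=[cancer],
        cause_maps={"10": {cancer: ["C50"]}},  # fixture cause is C509
        standard_population=config.standard_population,
        deaths_file=str(deaths_path),
        population_file=str(pop_path),
        include_subnational=config.include_subnational,
    )
    return _load_long(sub, country, cancer)


def _period_bins(lo: int, hi: int) -> list[lexis.PeriodBin]:
    return [lexis.PeriodBin(start) for start in range(lo, hi, 5)]


def run_asmr(
    config: AnalysisConfig, fixture_mode: bool = False, plots: bool = False
) -> dict[str, Path]:
    """Yearly ASMR series per country x cancer, written as tidy CSV."""
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    standard = _standard(config)
    outputs: dict[str, Path] = {}
    if not config.cancers:
        logger.warning("empty cancer list: nothing to do")
        return outputs
    for country in config.countries:
        for cancer in config.cancers:
            key = f"{country.name}_{cancer}".replace(" ", "_")
            long_df = (
                _fixture_long(config, country, cancer, out_dir)
                if fixture_mode
                else _load_long(config, country, cancer)
            )
            lo, hi = config.window_for(country, cancer)
            in_window = long_df[(long_df.year >= lo) & (long_df.year <= hi)]
            missing = sorted(set(range(lo, hi + 1)) - set(in_window.year))
            if missing and config.imputation == "none":
                raise ValueError(
                    f"{key}: window years {missing} absent from data and "
                    "imputation is off"
                )
            if missing:
                logger.info("%s: years %s excluded from ASMR series", key, missing)
            series = lexis.asmr_by_year(in_window, standard)
            series.insert(0, "cancer", cancer)
            series.insert(0, "country", country.name)
            path = out_dir / f"asmr_{key}.csv"
            series.to_csv(path, index=False)
            outputs[key] = path
            if plots:
                _line_plot(
                    series["year"], series["asmr"],
                    f"{country.name} {cancer} ASMR per 100,000",
                    out_dir / f"asmr_{key}.png",
                )
    return outputs


def run_apc(
    config: AnalysisConfig, fixture_mode: bool = False, plots: bool = False
) -> dict[str, dict[str, Path]]:
    """APC-IE fit per country x cancer: coefficient table + fit stats.

    Long series are fitted on their full window and additionally
    displayed on the common display window (default 1989-2013); the
    display never refits, it selects rows of the full fit.  The full
    period-effect series of long fits is written separately.
    """
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    outputs: dict[str, dict[str, Path]] = {}
    for country in config.countries:
        for cancer in config.cancers:
            key = f"{country.name}_{cancer}".replace(" ", "_")
            long_df = (
                _fixture_long(config, country, cancer, out_dir)
                if fixture_mode
                else _load_long(config, country, cancer)
            )
            lo, hi = config.window_for(country, cancer)
            bins = _period_bins(lo, hi + 1)
            table = lexis.bin_years(
                long_df[(long_df.year >= lo) & (long_df.year <= hi)],
                bins,
                imputation=config.imputation,
                k=config.imputation_k,
                country=country.name,
                cancer=cancer,
            )
            try:
                fit = ie.fit_ie(table)
            except ie.ConvergenceError as err:
                raise RuntimeError(f"{key}: APC-IE fit did not converge") from err

            dlo, dhi = config.display_window
            display_periods = [
                pb for pb in table.period_bins if dlo <= pb.start_year <= dhi
            ] or table.period_bins
            display_cohorts = _display_cohorts(table, display_periods)
            coef = ie.display_subset(fit, display_periods, display_cohorts)
            intercept_row = pd.DataFrame(
                [{"block": "intercept", "category": "", "coef": fit.intercept,
                  "se": fit.intercept_se}]
            )
            coef = pd.concat([intercept_row, coef], ignore_index=True)

            paths: dict[str, Path] = {}
            paths["coefficients"] = out_dir / f"apc_{key}_coefficients.csv"
            coef.to_csv(paths["coefficients"], index=False)
            paths["stats"] = out_dir / f"apc_{key}_stats.json"
            paths["stats"].write_text(
                json.dumps(
                    {
                        "deviance": fit.stats.deviance,
                        "aic": fit.stats.aic,
                        "bic": fit.stats.bic,
                        "n_obs": fit.stats.n_obs,
                        "model_rank": fit.stats.model_rank,
                    },
                    indent=2,
                )
            )
            if len(table.period_bins) > len(display_periods):
                full = ie.display_subset(fit)
                paths["full_periods"] = out_dir / f"apc_{key}_period_series.csv"
                full[full.block == "period"].to_csv(paths["full_periods"], index=False)
            if plots:
                _effect_plot(fit, f"{country.name} {cancer}", out_dir / f"apc_{key}.png")
            outputs[key] = paths
    return outputs


def _display_cohorts(
    table: lexis.RateTable, display_periods: list[lexis.PeriodBin]
) -> list[lexis.CohortBin]:
    """Cohorts spanned by the display-window periods across all ages."""
    oldest = lexis.cohort_label(table.age_groups[-1], display_periods[0])
    newest = lexis.cohort_label(table.age_groups[0], display_periods[-1])
    return [
        cb
        for cb in table.cohort_bins()
        if oldest.start_year <= cb.start_year <= newest.start_year
    ]


def run_simulation_study(
    R: int = 20,
    exposures: tuple[float, ...] = (1e4, 1e5, 1e6, 1e7),
    A: int = 12,
    P: int = 5,
    seed: int = 0,
    out_path=None,
) -> dict:
    """Parameter-recovery study: bias and RMSE per block vs exposure.

    Simulates ``R`` replicate tables at each per-cell exposure from one
    fixed truth (orthogonalized to B0) and refits by IE; deterministic
    under ``seed``.
    """
    truth_alpha, truth_beta, truth_gamma = synthetic.make_effects(A, P, seed=seed)
    report: dict = {"R": R, "A": A, "P": P, "seed": seed, "exposures": {}}
    for exposure in exposures:
        errs = {"age": [], "period": [], "cohort": []}
        for r in range(R):
            spec = synthetic.SyntheticSpec(
                A=A,
                P=P,
                mu=synthetic.DEFAULT_MU,
                alpha=truth_alpha,
                beta=truth_beta,
                gamma=truth_gamma,
                exposure=np.full((A, P), exposure),
                seed=seed + 1000 * r + int(np.log10(exposure)),
            )
            fit = ie.fit_ie(synthetic.simulate_counts(spec))
            errs["age"].append(fit.age_effects - truth_alpha)
            errs["period"].append(fit.period_effects - truth_beta)
            errs["cohort"].append(fit.cohort_effects - truth_gamma)
        entry = {}
        for block, e in errs.items():
            e = np.array(e)
            entry[block] = {
                "bias": float(np.mean(e)),
                "rmse": float(np.sqrt(np.mean(e**2))),
                "max_abs_error": float(np.abs(e).max()),
            }
            if R > 1:
                entry[block]["error_sd"] = float(e.std())
        report["exposures"][f"{exposure:g}"] = entry
    if out_path is not None:
        Path(out_path).write_text(json.dumps(report, indent=2))
    return report


def _line_plot(x, y, title: str, path: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    ax.plot(x, y, marker="o", ms=3)
    ax.set_title(title)
    ax.set_xlabel("year")
    ax.set_ylabel("rate per 100,000")
    fig.tight_layout()
    fig.savefig(path, dpi=100)
    plt.close(fig)


def _effect_plot(fit: ie.IEFit, title: str, path: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(1, 3, figsize=(12, 3.5))
    table = fit.table
    for ax, labels, effects, name in (
        (axes[0], [a.label for a in table.age_groups], fit.age_effects, "age"),
        (axes[1], [p.label for p in table.period_bins], fit.period_effects, "period"),
        (axes[2], [c.label for c in table.cohort_bins()], fit.cohort_effects, "cohort"),
    ):
        ax.plot(range(len(effects)), effects, marker="o", ms=3)
        ax.set_xticks(range(len(effects)))
        ax.set_xticklabels(labels, rotation=90, fontsize=6)
        ax.set_title(f"{name} effect")
        ax.axhline(0.0, color="grey", lw=0.5)
    fig.suptitle(title)
    fig.tight_layout()
    fig.savefig(path, dpi=100)
    plt.close(fig)
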