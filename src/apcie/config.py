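"""Declarative analysis configuration.

A single YAML document drives the full analysis: study countries with
their calendar windows, cancer sites, ICD cause maps, standard
population, imputation policy, and I/O paths.  The built-in default
encodes the three-country East Asian study design — Japan 1954-2013,
Republic of Korea 1989-2013, Singapore 1964-2013, with every ovarian
series restricted to 1994-2013 — so the default run reproduces that
design and any variant is a config edit.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .lexis import SEGI_WORLD_1960_WEIGHTS_20_79

#: Calendar window forced for ovarian series (data quality before 1994).
OVARIAN_WINDOW = (1994, 2013)


@dataclass
class CountryConfig:
    name: str
    code: str
    window: tuple[int, int]


@dataclass
class AnalysisConfig:
    countries: list[CountryConfig] = field(
        default_factory=lambda: [
            CountryConfig("Japan", "3160", (1954, 2013)),
            CountryConfig("Republic of Korea", "3325", (1989, 2013)),
            CountryConfig("Singapore", "3350", (1964, 2013)),
        ]
    )
    cancers: list[str] = field(default_factory=lambda: ["breast", "cervical", "ovarian"])
    cause_maps: dict[str, dict[str, list[str]]] = field(
        default_factory=lambda: {
            "10": {"breast": ["C50"], "cervical": ["C53"], "ovarian": ["C56"]}
        }
    )
    standard_population: dict[int, float] = field(
        default_factory=lambda: dict(SEGI_WORLD_1960_WEIGHTS_20_79)
    )
    imputation: str = "none"
    imputation_k: int = 4
    deaths_file: str | None = None
    population_file: str | None = None
    output_dir: str = "out"
    seed: int = 0
    display_window: tuple[int, int] = (1989, 2013)
    include_subnational: bool = False

    def __post_init__(self) -> None:
        for c in self.countries:
            c.window = tuple(c.window)
            lo, hi = c.window
            if (hi - lo + 1) % 5:
                raise ValueError(
                    f"{c.name}: window {c.window} does not span whole 5-year periods"
                )
        self.display_window = tuple(self.display_window)

    def window_for(self, country: CountryConfig, cancer: str) -> tuple[int, int]:
        """Country study window; ovarian is clamped to 1994-2013."""
        if cancer == "ovarian":
            lo = max(country.window[0], OVARIAN_WINDOW[0])
            hi = min(country.window[1], OVARIAN_WINDOW[1])
            return (lo, hi)
        return country.window

    @classmethod
    def from_yaml(cls, path) -> "AnalysisConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        kwargs = dict(raw)
        if "countries" in kwargs:
            kwargs["countries"] = [
                CountryConfig(d["name"], str(d["code"]), tuple(d["window"]))
                for d in kwargs["countries"]
            ]
        if "standard_population" in kwargs:
            kwargs["standard_population"] = {
                int(k): float(v) for k, v in kwargs["standard_population"].items()
            }
        return cls(**kwargs)

    def to_yaml(self, path) -> None:
        doc = {
            "countries": [
                {"name": c.name, "code": c.code, "window": list(c.window)}
                for c in self.countries
            ],
            "cancers": list(self.cancers),
            "cause_maps": self.cause_maps,
            "standard_population": self.standard_population,
            "imputation": self.imputation,
            "imputation_k": self.imputation_k,
            "deaths_file": self.deaths_file,
            "population_file": self.population_file,
            "output_dir": self.output_dir,
            "seed": self.seed,
            "display_window": list(self.display_window),
            "include_subnational": self.include_subnational,
        }
        Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))
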