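"""The air-pollution -> hospitalization fuzzy model.

Four daily exposures — particulate matter (PM10), ozone (O3), sulfur dioxide
(SO2), all in ug/m3, and apparent temperature (degC) — each described by two
linguistic terms, *good* and *bad*; one output, the daily number of
hospitalizations for asthma and pneumonia, described by five terms from
*very low* to *very high*.  The complete rule base has 2^4 = 16 conjunctive
rules, one per combination of good/bad across the four inputs, with the
consequent determined by how many inputs are bad.

Membership breakpoints default to values anchored on the regulatory
references for each pollutant (CETESB moderate-air band for PM10, the CONAMA
160 ug/m3 ozone standard, the WHO 24-h guideline of 20 ug/m3 for SO2) and
are fully overridable through :class:`ModelConfig`.  Cold apparent
temperature is treated as the harmful ("bad") direction, following the
winter excess of respiratory admissions; this too is configurable.
"""

from __future__ import annotations

import itertools
import json
import math
from dataclasses import dataclass, field, replace
from datetime import date as _date
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from .engine import (
    FuzzyInferenceSystem,
    FuzzyRule,
    LinguisticVariable,
    MembershipFunction,
    infer,
)
from .errors import ConfigurationError, InvalidInputError

__all__ = [
    "INPUT_VARIABLES",
    "OUTPUT_TERMS",
    "DailyRecord",
    "ModelConfig",
    "apparent_temperature",
    "build_default_system",
    "build_rule_base",
    "predict_day",
    "predict_series",
]

#: Input variable names in canonical order.
INPUT_VARIABLES: tuple[str, ...] = ("pm10", "o3", "so2", "temp_apparent")

#: Output severity terms, ordered from least to most severe.  The Portuguese
#: acronyms used in the source figures are MBX, BX, MED, ALTO, MALTO.
OUTPUT_TERMS: tuple[str, ...] = (
    "very_low", "low", "medium", "high", "very_high")

Breakpoints = tuple[float, float, float, float]

_DEFAULT_UNIVERSES: dict[str, tuple[float, float]] = {
    "pm10": (0.0, 120.0),
    "o3": (0.0, 200.0),
    "so2": (0.0, 30.0),
    "temp_apparent": (0.0, 30.0),
}

_DEFAULT_INPUT_TERMS: dict[str, dict[str, Breakpoints]] = {
    # CETESB flags 51-100 ug/m3 PM10 as moderate air: "good" fades over 25-50.
    "pm10": {"good": (0, 0, 25, 50), "bad": (25, 50, 120, 120)},
    # CONAMA ozone standard: acceptable up to 160 ug/m3.
    "o3": {"good": (0, 0, 80, 160), "bad": (80, 160, 200, 200)},
    # WHO 24-h SO2 guideline: up to 20 ug/m3.
    "so2": {"good": (0, 0, 10, 20), "bad": (10, 20, 30, 30)},
    # Cold aggravates respiratory disease: "bad" is the cold end.
    "temp_apparent": {"good": (12, 18, 30, 30), "bad": (0, 0, 12, 18)},
}

_DEFAULT_OUTPUT_UNIVERSE: tuple[float, float] = (0.0, 16.0)

_DEFAULT_OUTPUT_TERMS: dict[str, Breakpoints] = {
    "very_low": (0, 0, 2, 4),
    "low": (2, 4, 4, 6),
    "medium": (5, 8, 8, 11),
    "high": (10, 12, 12, 14),
    "very_high": (12, 14, 16, 16),
}

#: Number of "bad" antecedents -> output severity term.
_DEFAULT_SEVERITY_MAP: dict[int, str] = {
    0: "very_low", 1: "low", 2: "medium", 3: "high", 4: "very_high"}


@dataclass(frozen=True)
class DailyRecord:
    """One day of exposures and (optionally) the observed admission count.

    Either ``temp_apparent`` or both ``temp_ambient`` and ``rel_humidity``
    must be present; apparent temperature is computed on the fly when absent.
    """

    date: _date
    pm10: float
    o3: float
    so2: float
    temp_ambient: Optional[float] = None
    rel_humidity: Optional[float] = None
    temp_apparent: Optional[float] = None
    admissions: Optional[int] = None

    def __post_init__(self) -> None:
        for name in ("pm10", "o3", "so2"):
            v = getattr(self, name)
            if v is not None and np.isfinite(v) and v < 0:
                raise InvalidInputError(f"{name} must be >= 0, got {v}")
        if self.rel_humidity is not None and not (
                0 <= self.rel_humidity <= 100):
            raise InvalidInputError(
                f"relative humidity must be in [0, 100], got {self.rel_humidity}")
        if self.admissions is not None and self.admissions < 0:
            raise InvalidInputError("admissions count must be non-negative")

    def resolved_temp_apparent(self) -> float:
        """Apparent temperature, computed from Ta and RH if not given."""
        if self.temp_apparent is not None:
            return float(self.temp_apparent)
        if self.temp_ambient is None or self.rel_humidity is None:
            raise InvalidInputError(
                f"{self.date}: need temp_apparent, or temp_ambient and "
                "rel_humidity to derive it")
        return apparent_temperature(self.temp_ambient, self.rel_humidity)

    def exposures(self) -> dict[str, float]:
        """The four crisp model inputs for this day."""
        values = {
            "pm10": self.pm10,
            "o3": self.o3,
            "so2": self.so2,
            "temp_apparent": self.resolved_temp_apparent(),
        }
        for name, v in values.items():
            if v is None or not np.isfinite(v):
                raise InvalidInputError(
                    f"{self.date}: exposure {name!r} is missing or non-finite")
        return values


@dataclass(frozen=True)
class ModelConfig:
    """Universe bounds, term breakpoints and the severity map of the model.

    The defaults reproduce the shipped model: two terms (good/bad) per input
    variable, five output terms spanning the 0-16 admissions universe, and a
    severity map sending the count of bad antecedents monotonically onto the
    output terms.
    """

    input_universes: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(_DEFAULT_UNIVERSES))
    input_terms: dict[str, dict[str, Breakpoints]] = field(
        default_factory=lambda: {
            v: dict(t) for v, t in _DEFAULT_INPUT_TERMS.items()})
    output_universe: tuple[float, float] = _DEFAULT_OUTPUT_UNIVERSE
    output_terms: dict[str, Breakpoints] = field(
        default_factory=lambda: dict(_DEFAULT_OUTPUT_TERMS))
    severity_map: dict[int, str] = field(
        default_factory=lambda: dict(_DEFAULT_SEVERITY_MAP))
    resolution: int = 1001

    def __post_init__(self) -> None:
        for var, terms in self.input_terms.items():
            if var not in self.input_universes:
                raise ConfigurationError(f"no universe for input {var!r}")
            if len(terms) != 2:
                raise ConfigurationError(
                    f"input {var!r} must have exactly 2 terms, got {len(terms)}")
            if set(terms) != {"good", "bad"}:
                raise ConfigurationError(
                    f"input {var!r} terms must be named 'good' and 'bad', "
                    f"got {sorted(terms)}")
        if len(self.output_terms) != 5:
            raise ConfigurationError(
                f"output must have exactly 5 terms, got {len(self.output_terms)}")
        order = list(self.output_terms)
        if sorted(self.severity_map) != list(range(len(self.input_terms) + 1)):
            raise ConfigurationError(
                "severity map must cover 0..n_inputs bad antecedents")
        ranks = [order.index(self.severity_map[k])
                 for k in sorted(self.severity_map)]
        if any(b < a for a, b in zip(ranks, ranks[1:])):
            raise ConfigurationError(
                "severity map must be monotone non-decreasing in the count "
                "of bad antecedents")
        for k, term in self.severity_map.items():
            if term not in self.output_terms:
                raise ConfigurationError(
                    f"severity map points to unknown output term {term!r}")

    # -- persistence -------------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "input_universes": {k: list(v) for k, v in self.input_universes.items()},
            "input_terms": {
                v: {t: list(bp) for t, bp in terms.items()}
                for v, terms in self.input_terms.items()},
            "output_universe": list(self.output_universe),
            "output_terms": {t: list(bp) for t, bp in self.output_terms.items()},
            "severity_map": {str(k): v for k, v in self.severity_map.items()},
            "resolution": self.resolution,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "ModelConfig":
        try:
            return cls(
                input_universes={k: tuple(v) for k, v in d["input_universes"].items()},
                input_terms={
                    v: {t: tuple(bp) for t, bp in terms.items()}
                    for v, terms in d["input_terms"].items()},
                output_universe=tuple(d["output_universe"]),
                output_terms={t: tuple(bp) for t, bp in d["output_terms"].items()},
                severity_map={int(k): v for k, v in d["severity_map"].items()},
                resolution=int(d.get("resolution", 1001)),
            )
        except KeyError as exc:
            raise ConfigurationError(f"model config missing field {exc}") from exc

    def save(self, path) -> None:
        d = self.to_dict()
        text = (json.dumps(d, indent=2) if str(path).endswith(".json")
                else yaml.safe_dump(d, sort_keys=False))
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(text)

    @classmethod
    def load(cls, path) -> "ModelConfig":
        with open(path, encoding="utf-8") as fh:
            d = (json.load(fh) if str(path).endswith(".json")
                 else yaml.safe_load(fh))
        return cls.from_dict(d)


def apparent_temperature(temp_ambient: float, rel_humidity: float) -> float:
    """Steadman-type apparent temperature from ambient temperature and RH.

    Dew point ``Td`` comes from the Magnus approximation (constants 17.27
    and 237.7 degC); apparent temperature is then

        AT = -2.653 + 0.994 * Ta + 0.0153 * Td**2

    Monotone increasing in both arguments over the physiological range.

    Parameters
    ----------
    temp_ambient
        Ambient (dry-bulb) temperature, degC.
    rel_humidity
        Relative humidity, percent, in (0, 100].
    """
    if not np.isfinite(temp_ambient):
        raise InvalidInputError("ambient temperature must be finite")
    if not (0 < rel_humidity <= 100):
        raise InvalidInputError(
            f"relative humidity must be in (0, 100], got {rel_humidity}")
    gamma = (17.27 * temp_ambient / (237.7 + temp_ambient)
             + math.log(rel_humidity / 100.0))
    dew_point = 237.7 * gamma / (17.27 - gamma)
    return -2.653 + 0.994 * temp_ambient + 0.0153 * dew_point ** 2


def _input_variable(config: ModelConfig, name: str) -> LinguisticVariable:
    lo, hi = config.input_universes[name]
    terms = [MembershipFunction(t, *bp)
             for t, bp in config.input_terms[name].items()]
    return LinguisticVariable(name, lo, hi, terms)


def build_rule_base(config: ModelConfig) -> list[FuzzyRule]:
    """All 2^n good/bad combinations, consequent from the severity map.

    For four inputs this enumerates the complete 16-rule table; the two
    extreme rules are always all-good -> very low and all-bad -> very high
    (the severity map is validated to be monotone).
    """
    variables = list(config.input_terms)
    term_choices = [list(config.input_terms[v]) for v in variables]
    rules = []
    for combo in itertools.product(*term_choices):
        n_bad = sum(term == "bad" for term in combo)
        consequent = config.severity_map[n_bad]
        rules.append(FuzzyRule(dict(zip(variables, combo)), consequent))
    return rules


def build_default_system(config: Optional[ModelConfig] = None
                         ) -> FuzzyInferenceSystem:
    """Assemble the full inference system from a (default) configuration."""
    config = config or ModelConfig()
    inputs = [_input_variable(config, name) for name in config.input_terms]
    lo, hi = config.output_universe
    output = LinguisticVariable(
        "admissions", lo, hi,
        [MembershipFunction(t, *bp) for t, bp in config.output_terms.items()])
    return FuzzyInferenceSystem(
        inputs=inputs, output=output, rules=build_rule_base(config),
        resolution=config.resolution)


def predict_day(system: FuzzyInferenceSystem, record: DailyRecord) -> float:
    """Predicted daily admissions for one day's exposures."""
    return infer(system, record.exposures())


def predict_series(system: FuzzyInferenceSystem,
                   series: pd.DataFrame) -> pd.DataFrame:
    """Element-wise prediction over a date-indexed exposure table.

    ``series`` needs columns ``date, pm10, o3, so2`` and either
    ``temp_apparent`` or both ``temp`` and ``rh``.  Days with missing or
    invalid exposures are emitted with a missing prediction (NaN), never
    silently dropped; the returned frame carries an ``error`` column with
    the reason for each skipped day.
    """
    if "date" not in series.columns:
        raise InvalidInputError("series must have a 'date' column")
    out_dates, out_pred, out_err = [], [], []
    for row in series.itertuples(index=False):
        d = getattr(row, "date")
        out_dates.append(d)
        try:
            record = DailyRecord(
                date=d,
                pm10=_opt(row, "pm10"),
                o3=_opt(row, "o3"),
                so2=_opt(row, "so2"),
                temp_ambient=_opt(row, "temp"),
                rel_humidity=_opt(row, "rh"),
                temp_apparent=_opt(row, "temp_apparent"),
            )
            out_pred.append(predict_day(system, record))
            out_err.append("")
        except InvalidInputError as exc:
            out_pred.append(np.nan)
            out_err.append(str(exc))
    return pd.DataFrame(
        {"date": out_dates, "predicted": out_pred, "error": out_err})


def _opt(row, name: str) -> Optional[float]:
    v = getattr(row, name, None)
    if v is None:
        return None
    v = float(v)
    return None if math.isnan(v) else v
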