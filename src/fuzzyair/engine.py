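"""Generic Mamdani fuzzy inference.

This module is independent of the epidemiological application: it provides
piecewise-linear (trapezoidal) membership functions, linguistic variables,
conjunctive IF-THEN rules, and the classic Mamdani pipeline

    fuzzify -> fire rules (min) -> aggregate consequents (clip + max)
            -> defuzzify (area center / centroid)

on a discretized output universe.  Implication is truncation (minimum with
the firing strength) and aggregation is the pointwise maximum; no product or
sum variants are offered.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import yaml

from .errors import (
    ConfigurationError,
    DegenerateAggregationError,
    InvalidInputError,
)

__all__ = [
    "MembershipFunction",
    "LinguisticVariable",
    "FuzzyRule",
    "FuzzyInferenceSystem",
    "AggregatedOutput",
    "membership",
    "fuzzify",
    "fire_strength",
    "aggregate",
    "defuzzify_centroid",
    "infer",
    "system_to_dict",
    "system_from_dict",
    "save_system",
    "load_system",
]


@dataclass(frozen=True)
class MembershipFunction:
    """A trapezoidal fuzzy set over one variable.

    Membership is 0 at or below ``a``, rises linearly to 1 at ``b``, stays
    at 1 on ``[b, c]`` and falls linearly to 0 at or beyond ``d``.  A
    triangle has ``b == c``; an open shoulder (membership held at 1 past the
    universe edge) has ``a == b`` at the lower end or ``c == d`` at the
    upper end.
    """

    name: str
    a: float
    b: float
    c: float
    d: float

    def __post_init__(self) -> None:
        if not (np.isfinite(self.a) and np.isfinite(self.b)
                and np.isfinite(self.c) and np.isfinite(self.d)):
            raise ConfigurationError(
                f"term {self.name!r}: breakpoints must be finite")
        if not (self.a <= self.b <= self.c <= self.d):
            raise ConfigurationError(
                f"term {self.name!r}: breakpoints must satisfy a <= b <= c <= d, "
                f"got ({self.a}, {self.b}, {self.c}, {self.d})")
        if self.a == self.d:
            raise ConfigurationError(
                f"term {self.name!r}: degenerate (zero-width) fuzzy set")

    @property
    def breakpoints(self) -> tuple[float, float, float, float]:
        return (self.a, self.b, self.c, self.d)

    def __call__(self, x):
        """Evaluate the membership degree at ``x`` (scalar or array)."""
        arr = np.asarray(x, dtype=float)
        if not np.all(np.isfinite(arr)):
            raise InvalidInputError(
                f"term {self.name!r}: membership input must be finite")
        y = np.zeros_like(arr)
        # np.where evaluates both branches; the division can overflow on
        # points the mask discards, so silence spurious warnings.
        with np.errstate(over="ignore", invalid="ignore"):
            if self.b > self.a:
                rising = (arr > self.a) & (arr < self.b)
                y = np.where(rising, (arr - self.a) / (self.b - self.a), y)
            y = np.where((arr >= self.b) & (arr <= self.c), 1.0, y)
            if self.d > self.c:
                falling = (arr > self.c) & (arr < self.d)
                y = np.where(falling, (self.d - arr) / (self.d - self.c), y)
        y = np.clip(y, 0.0, 1.0)
        # Open shoulders stay at full height beyond the flat edge.
        if self.a == self.b:
            y = np.where(arr <= self.b, 1.0, y)
        if self.c == self.d:
            y = np.where(arr >= self.c, 1.0, y)
        if arr.ndim == 0:
            return float(y)
        return y


@dataclass(frozen=True)
class LinguisticVariable:
    """A named quantity with a universe of discourse and named fuzzy terms."""

    name: str
    lo: float
    hi: float
    terms: tuple[MembershipFunction, ...]

    def __init__(self, name: str, lo: float, hi: float,
                 terms: Iterable[MembershipFunction]):
        object.__setattr__(self, "name", name)
        object.__setattr__(self, "lo", float(lo))
        object.__setattr__(self, "hi", float(hi))
        object.__setattr__(self, "terms", tuple(terms))
        if not self.lo < self.hi:
            raise ConfigurationError(
                f"variable {name!r}: universe requires lo < hi")
        if not self.terms:
            raise ConfigurationError(f"variable {name!r}: needs at least one term")
        names = [t.name for t in self.terms]
        if len(set(names)) != len(names):
            raise ConfigurationError(
                f"variable {name!r}: duplicate term names {names}")

    def term(self, term_name: str) -> MembershipFunction:
        for t in self.terms:
            if t.name == term_name:
                return t
        raise ConfigurationError(
            f"variable {self.name!r} has no term {term_name!r}")

    def term_names(self) -> tuple[str, ...]:
        return tuple(t.name for t in self.terms)

    def covers_universe(self, n_check: int = 1001, eps: float = 1e-12) -> bool:
        """True if at least one term has nonzero membership everywhere."""
        grid = np.linspace(self.lo, self.hi, n_check)
        best = np.zeros(n_check)
        for t in self.terms:
            best = np.maximum(best, t(grid))
        return bool(np.all(best > eps))

    def clamp(self, x: float) -> float:
        return min(max(float(x), self.lo), self.hi)


@dataclass(frozen=True)
class FuzzyRule:
    """A conjunctive IF-THEN rule: AND of one term per named input variable."""

    antecedent: Mapping[str, str]
    consequent: str

    def __init__(self, antecedent: Mapping[str, str], consequent: str):
        object.__setattr__(self, "antecedent", dict(antecedent))
        object.__setattr__(self, "consequent", str(consequent))
        if not self.antecedent:
            raise ConfigurationError("rule has an empty antecedent")

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        cond = " AND ".join(f"{v} IS {t}" for v, t in self.antecedent.items())
        return f"IF {cond} THEN {self.consequent}"


@dataclass(frozen=True)
class AggregatedOutput:
    """The aggregated output fuzzy set sampled on an even grid."""

    grid: np.ndarray
    degrees: np.ndarray

    def __post_init__(self) -> None:
        grid = np.asarray(self.grid, dtype=float)
        degrees = np.asarray(self.degrees, dtype=float)
        object.__setattr__(self, "grid", grid)
        object.__setattr__(self, "degrees", degrees)
        if grid.shape != degrees.shape or grid.ndim != 1:
            raise ConfigurationError("grid and degrees must be 1-d and aligned")
        if not np.all(np.diff(grid) > 0):
            raise ConfigurationError("grid must be strictly increasing")
        if np.any(degrees < 0) or np.any(degrees > 1):
            raise ConfigurationError("degrees must lie in [0, 1]")


class FuzzyInferenceSystem:
    """A complete Mamdani system: input variables, output variable, rules.

    Parameters
    ----------
    inputs
        Input linguistic variables.  Each must cover its universe (some term
        has nonzero membership at every point) unless ``validate_coverage``
        is disabled; coverage plus a complete rule base guarantees at least
        one rule fires for every input.
    output
        The output linguistic variable whose terms the rules' consequents
        reference.
    rules
        Conjunctive rules; every referenced variable and term must exist.
    resolution
        Number of evenly spaced discretization points on the output
        universe used for aggregation and centroid defuzzification.
    """

    def __init__(self, inputs: Iterable[LinguisticVariable],
                 output: LinguisticVariable,
                 rules: Iterable[FuzzyRule],
                 resolution: int = 1001,
                 validate_coverage: bool = True):
        self.inputs = tuple(inputs)
        self.output = output
        self.rules = tuple(rules)
        self.resolution = int(resolution)
        if self.resolution < 101:
            raise ConfigurationError("resolution must be >= 101")
        input_names = [v.name for v in self.inputs]
        if len(set(input_names)) != len(input_names):
            raise ConfigurationError(f"duplicate input variables: {input_names}")
        by_name = {v.name: v for v in self.inputs}
        out_terms = set(self.output.term_names())
        for rule in self.rules:
            for var, term in rule.antecedent.items():
                if var not in by_name:
                    raise ConfigurationError(
                        f"rule references unknown variable {var!r}")
                if term not in by_name[var].term_names():
                    raise ConfigurationError(
                        f"rule references unknown term {term!r} of {var!r}")
            if rule.consequent not in out_terms:
                raise ConfigurationError(
                    f"rule consequent {rule.consequent!r} is not an output term")
        if validate_coverage:
            for v in self.inputs:
                if not v.covers_universe():
                    raise ConfigurationError(
                        f"input variable {v.name!r} does not cover its universe")
        self._by_name = by_name
        self._grid = np.linspace(self.output.lo, self.output.hi, self.resolution)
        self._consequent_grids = {
            t.name: t(self._grid) for t in self.output.terms
        }

    @property
    def grid(self) -> np.ndarray:
        return self._grid

    def input_variable(self, name: str) -> LinguisticVariable:
        try:
            return self._by_name[name]
        except KeyError:
            raise ConfigurationError(f"no input variable named {name!r}") from None


# ---------------------------------------------------------------------------
# Operations (functional surface; all pure)
# ---------------------------------------------------------------------------

def membership(mf: MembershipFunction, x: float) -> float:
    """Piecewise-linear membership degree of ``x`` in the trapezoid ``mf``."""
    return mf(x)


def fuzzify(var: LinguisticVariable, x: float) -> dict[str, float]:
    """Map a crisp value to a degree per term of ``var``.

    Values outside the declared universe are clamped to ``[lo, hi]`` first:
    real-world readings can exceed the historical range the universe was
    drawn from, and clamping keeps every membership well-defined.
    """
    if not np.isfinite(x):
        raise InvalidInputError(
            f"variable {var.name!r}: cannot fuzzify non-finite value {x!r}")
    xc = var.clamp(x)
    return {t.name: float(t(xc)) for t in var.terms}


def fire_strength(rule: FuzzyRule,
                  fuzzified: Mapping[str, Mapping[str, float]]) -> float:
    """Degree of activation: the minimum of the rule's antecedent degrees."""
    degrees = []
    for var, term in rule.antecedent.items():
        if var not in fuzzified:
            raise ConfigurationError(
                f"rule needs variable {var!r} but it was not fuzzified")
        var_degrees = fuzzified[var]
        if term not in var_degrees:
            raise ConfigurationError(
                f"variable {var!r} has no fuzzified degree for term {term!r}")
        degrees.append(var_degrees[term])
    return float(min(degrees))


def aggregate(system: FuzzyInferenceSystem,
              strengths: Sequence[float]) -> AggregatedOutput:
    """Clip each rule's consequent at its strength; take the pointwise max.

    ``strengths`` is aligned with ``system.rules`` (one strength per rule).
    Rules with zero strength contribute nothing.
    """
    if len(strengths) != len(system.rules):
        raise ConfigurationError(
            f"expected {len(system.rules)} strengths, got {len(strengths)}")
    degrees = np.zeros(system.resolution)
    for rule, s in zip(system.rules, strengths):
        s = float(s)
        if s < 0 or s > 1:
            raise ConfigurationError(f"rule strength {s} outside [0, 1]")
        if s == 0.0:
            continue
        clipped = np.minimum(s, system._consequent_grids[rule.consequent])
        np.maximum(degrees, clipped, out=degrees)
    return AggregatedOutput(grid=system.grid, degrees=degrees)


def defuzzify_centroid(agg: AggregatedOutput) -> float:
    """Area-center (centroid) defuzzification of an aggregated set.

    Returns sum(grid * degrees) / sum(degrees) over the discretized
    universe.  With positive-width activation the centroid lies strictly
    inside the universe: mass on both sides of any candidate endpoint pulls
    the center of area inward, which is why Mamdani outputs cannot reach
    the universe extremes.
    """
    total = float(np.sum(agg.degrees))
    if total <= 0.0:
        raise DegenerateAggregationError(
            "aggregated output is identically zero (no rule fired)")
    return float(np.sum(agg.grid * agg.degrees) / total)


def infer(system: FuzzyInferenceSystem,
          crisp_inputs: Mapping[str, float]) -> float:
    """Full Mamdani pipeline from crisp inputs to a crisp output value."""
    fuzzified = {}
    for var in system.inputs:
        if var.name not in crisp_inputs:
            raise InvalidInputError(f"missing input for variable {var.name!r}")
        fuzzified[var.name] = fuzzify(var, float(crisp_inputs[var.name]))
    strengths = [fire_strength(rule, fuzzified) for rule in system.rules]
    return defuzzify_centroid(aggregate(system, strengths))


# ---------------------------------------------------------------------------
# Serialization (YAML or JSON, by file extension)
# ---------------------------------------------------------------------------

def _variable_to_dict(var: LinguisticVariable) -> dict:
    return {
        "name": var.name,
        "universe": [var.lo, var.hi],
        "terms": {t.name: list(t.breakpoints) for t in var.terms},
    }


def _variable_from_dict(d: Mapping) -> LinguisticVariable:
    lo, hi = d["universe"]
    terms = [MembershipFunction(name, *map(float, bp))
             for name, bp in d["terms"].items()]
    return LinguisticVariable(d["name"], lo, hi, terms)


def system_to_dict(system: FuzzyInferenceSystem) -> dict:
    return {
        "inputs": [_variable_to_dict(v) for v in system.inputs],
        "output": _variable_to_dict(system.output),
        "rules": [
            {"if": dict(r.antecedent), "then": r.consequent}
            for r in system.rules
        ],
        "resolution": system.resolution,
    }


def system_from_dict(d: Mapping) -> FuzzyInferenceSystem:
    try:
        return FuzzyInferenceSystem(
            inputs=[_variable_from_dict(v) for v in d["inputs"]],
            output=_variable_from_dict(d["output"]),
            rules=[FuzzyRule(r["if"], r["then"]) for r in d["rules"]],
            resolution=int(d.get("resolution", 1001)),
        )
    except KeyError as exc:
        raise ConfigurationError(f"system definition missing field {exc}") from exc


def save_system(system: FuzzyInferenceSystem, path) -> None:
    """Write a system definition to a ``.yaml``/``.yml`` or ``.json`` file."""
    d = system_to_dict(system)
    text = (json.dumps(d, indent=2) if str(path).endswith(".json")
            else yaml.safe_dump(d, sort_keys=False))
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(text)


def load_system(path) -> FuzzyInferenceSystem:
    """Load a system definition written by :func:`save_system`."""
    with open(path, encoding="utf-8") as fh:
        d = json.load(fh) if str(path).endswith(".json") else yaml.safe_load(fh)
    return system_from_dict(d)
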