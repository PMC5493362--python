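"""Synthetic daily exposure/admission series.

Real station exposures and hospital admission counts for this problem are
not publicly deposited, so the generator emulates their marginal structure:
each exposure is a Gaussian AR(1) process rescaled to a target mean and
standard deviation and truncated to the observed min/max; admissions are
Poisson counts whose log rate is a baseline plus per-standard-deviation
effects of (possibly lagged) standardized exposures, capped at the maximum
observed daily count.

Defaults reproduce the 2007 Sao Jose dos Campos marginals: PM10 mean 26.0,
SD 11.3, range 8-89 ug/m3; O3 91.0/67.9, 17-162; SO2 3.8/3.3, 0.9-27;
apparent temperature mean 17.9 degC over 5.7-20.2 (its SD floats to a
plausible 2.5 degC: the printed 0.9 is inconsistent with the printed range);
admissions mean 4.9, max 16/day.  A planted association is specified as
``betas={"pm10": {1: 0.3}}``: +0.3 on the log rate per SD of PM10 one day
earlier.  With all betas zero the admissions are independent of exposures,
which calibrates null behaviour of the validation pipeline.

The default AR(1) persistence is deliberately mild (rho = 0.2): the
generator's contract is that a single planted lag is identifiable by the
validation pipeline, and strong day-to-day persistence smears an
association across neighbouring lags (as it does in real exposure series —
a known limit of lag-specific validation).  Raise ``rho`` to study that
smearing.

Seasonality, day-of-week structure and overdispersion are deliberately
absent; the series exercise the inference and validation machinery, they are
not an epidemiological simulation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from datetime import date, timedelta
from pathlib import Path
from typing import Mapping, Optional

import numpy as np
import pandas as pd

from .errors import ConfigurationError
from .io import write_series

__all__ = ["Marginal", "GeneratorSpec", "generate_exposures",
           "generate_admissions", "make_fixture"]


@dataclass(frozen=True)
class Marginal:
    """Target mean/SD and truncation bounds for one generated series."""

    mean: float
    sd: float
    min: float
    max: float

    def __post_init__(self) -> None:
        if self.sd <= 0:
            raise ConfigurationError(f"sd must be > 0, got {self.sd}")
        if not (self.min < self.max):
            raise ConfigurationError(
                f"need min < max, got [{self.min}, {self.max}]")
        if not (self.min <= self.mean <= self.max):
            raise ConfigurationError(
                f"mean {self.mean} outside truncation bounds "
                f"[{self.min}, {self.max}]")


_DEFAULT_MARGINALS: dict[str, Marginal] = {
    "pm10": Marginal(26.0, 11.3, 8.0, 89.0),
    "o3": Marginal(91.0, 67.9, 17.0, 162.0),
    "so2": Marginal(3.8, 3.3, 0.9, 27.0),
    "temp_apparent": Marginal(17.9, 2.5, 5.7, 20.2),
}


@dataclass(frozen=True)
class GeneratorSpec:
    """Everything needed to generate one reproducible series.

    Parameters
    ----------
    n_days
        Series length; a year by default.
    seed
        Seed for all randomness; identical specs give identical series.
    marginals
        Per-variable target mean/SD/min/max.
    rho
        AR(1) day-to-day autocorrelation shared by all exposure series.
    betas
        Planted log-rate effects: ``{variable: {lag: beta}}``, beta per SD
        of the exposure ``lag`` days before the admission day.
    beta0
        Baseline log admission rate; default log(4.9) matches the observed
        mean of 4.9 admissions/day.
    admissions_cap
        Daily counts are capped here (observed maximum 16).
    start
        Calendar date of the first day.
    """

    n_days: int = 365
    seed: int = 0
    marginals: Mapping[str, Marginal] = field(
        default_factory=lambda: dict(_DEFAULT_MARGINALS))
    rho: float = 0.2
    betas: Mapping[str, Mapping[int, float]] = field(default_factory=dict)
    beta0: float = float(np.log(4.9))
    admissions_cap: int = 16
    start: date = date(2007, 1, 1)

    def __post_init__(self) -> None:
        if self.n_days < 30:
            raise ConfigurationError(f"n_days must be >= 30, got {self.n_days}")
        if not (0 <= self.rho < 1):
            raise ConfigurationError(f"rho must be in [0, 1), got {self.rho}")
        for var, lags in self.betas.items():
            if var not in self.marginals:
                raise ConfigurationError(f"beta for unknown variable {var!r}")
            for lag in lags:
                if int(lag) < 0:
                    raise ConfigurationError(f"beta lag must be >= 0, got {lag}")

    def to_dict(self) -> dict:
        return {
            "n_days": self.n_days,
            "seed": self.seed,
            "marginals": {
                v: {"mean": m.mean, "sd": m.sd, "min": m.min, "max": m.max}
                for v, m in self.marginals.items()},
            "rho": self.rho,
            "betas": {v: {str(l): b for l, b in lags.items()}
                      for v, lags in self.betas.items()},
            "beta0": self.beta0,
            "admissions_cap": self.admissions_cap,
            "start": self.start.isoformat(),
        }


def _ar1(rng: np.random.Generator, n: int, rho: float) -> np.ndarray:
    """Standard-normal stationary AR(1) path of length n."""
    z = np.empty(n)
    z[0] = rng.standard_normal()
    innov = rng.standard_normal(n - 1) * np.sqrt(1.0 - rho ** 2)
    for t in range(1, n):
        z[t] = rho * z[t - 1] + innov[t - 1]
    return z


def generate_exposures(spec: GeneratorSpec) -> pd.DataFrame:
    """Daily exposure table: date, pm10, o3, so2, temp_apparent.

    Each series is a stationary Gaussian AR(1), rescaled to the target mean
    and SD and truncated (clipped) to the target bounds.  Truncation pulls
    realized moments slightly toward the bounds; for the default marginals
    the bias is small relative to Monte-Carlo noise at a year's length.
    """
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 0]))
    dates = [spec.start + timedelta(days=i) for i in range(spec.n_days)]
    data: dict = {"date": dates}
    for var, m in spec.marginals.items():
        z = _ar1(rng, spec.n_days, spec.rho)
        data[var] = np.clip(m.mean + m.sd * z, m.min, m.max)
    return pd.DataFrame(data)


def _standardized(exposures: pd.DataFrame, spec: GeneratorSpec,
                  var: str) -> np.ndarray:
    m = spec.marginals[var]
    return (exposures[var].to_numpy(dtype=float) - m.mean) / m.sd


def generate_admissions(exposures: pd.DataFrame,
                        spec: GeneratorSpec) -> pd.DataFrame:
    """Add a Poisson ``admissions`` column driven by the planted betas.

    The log rate on day t is ``beta0 + sum_v sum_lag beta[v][lag] *
    z_{v, t-lag}`` where z is the exposure standardized by the spec's own
    mean/SD (so each beta reads as log-rate change per SD).  Days earlier
    than the first available lagged exposure take a neutral (zero)
    contribution.  Counts are capped at ``admissions_cap``.
    """
    for var in spec.marginals:
        if var not in exposures.columns:
            raise ConfigurationError(f"exposure table missing column {var!r}")
        if exposures[var].isna().any():
            raise ConfigurationError(f"exposure column {var!r} has missing days")
    n = len(exposures)
    log_rate = np.full(n, spec.beta0, dtype=float)
    for var, lags in spec.betas.items():
        z = _standardized(exposures, spec, var)
        for lag, beta in lags.items():
            lag = int(lag)
            shifted = np.zeros(n)
            if lag < n:
                shifted[lag:] = z[: n - lag]
            log_rate += float(beta) * shifted
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 1]))
    counts = rng.poisson(np.exp(log_rate))
    out = exposures.copy()
    out["admissions"] = np.minimum(counts, spec.admissions_cap).astype(int)
    return out


def make_fixture(spec: GeneratorSpec, out_prefix) -> tuple[Path, Path]:
    """Write ``<prefix>.csv`` (exposures + admissions) and ``<prefix>.spec.json``.

    The spec file records the full generating configuration next to the
    data for provenance.  Returns the two paths written.
    """
    prefix = Path(out_prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    series = generate_admissions(generate_exposures(spec), spec)
    csv_path = prefix.with_suffix(".csv")
    spec_path = prefix.with_suffix(".spec.json")
    write_series(series, csv_path)
    spec_path.write_text(json.dumps(spec.to_dict(), indent=2) + "\n",
                         encoding="utf-8")
    return csv_path, spec_path
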