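"""Proxy time-series containers and preprocessing.

The analysis works with three kinds of calendar-year-indexed proxies:

* a paleodemographic proxy ``N`` (summed probability of calibrated
  radiocarbon dates, SPD — a relative measure of population level),
* an ordinal warfare-intensity index ``W`` (defensive-settlement coding,
  raw range 0–6, recorded per chrono-cultural period),
* a hydroclimate proxy ``C`` (annual lithic concentration, in %, from a
  marine sediment core off the Peruvian coast; high values indicate
  El Niño-like wet conditions on the coast).

Raw series are smoothed with a penalized cubic spline, resampled onto a
common 25-year grid, and converted to per-step log growth rates — the
response variables of the dynamic-model fits.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml
from scipy.interpolate import make_smoothing_spline

logger = logging.getLogger(__name__)

__all__ = [
    "ProxyTimeSeries",
    "RateSeries",
    "Period",
    "WarfarePeriodCoding",
    "smooth_spline",
    "resample",
    "growth_rates",
    "encode_warfare",
    "apply_floor",
    "clip_range",
    "read_proxy_csv",
    "write_proxy_csv",
    "read_period_table",
    "aligned_table",
]

#: Radiocarbon convention: calibrated years before present are counted
#: back from AD 1950.
PRESENT_AD = 1950

#: Additive floor applied to the warfare index before any log transform
#: (the raw ordinal index can be 0, where a log rate is undefined).
DEFAULT_WARFARE_FLOOR = 0.1


@dataclass(frozen=True)
class ProxyTimeSeries:
    """A calendar-year-indexed sequence of real proxy values.

    Parameters
    ----------
    times
        Calendar years AD, strictly increasing integers.
    values
        Proxy values (SPD probability mass, warfare index, lithic %).
    label
        Free-text description carried through transformations.
    """

    times: np.ndarray
    values: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=int)
        v = np.asarray(self.values, dtype=float)
        if t.ndim != 1 or v.ndim != 1:
            raise ValueError("times and values must be one-dimensional")
        if len(t) != len(v):
            raise ValueError(
                f"length mismatch: {len(t)} times vs {len(v)} values"
            )
        if len(t) >= 2 and not np.all(np.diff(t) > 0):
            raise ValueError("times must be strictly increasing")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "values", v)

    def __len__(self) -> int:
        return len(self.times)

    @property
    def step(self) -> int | None:
        """Uniform spacing in years, or ``None`` if irregular."""
        if len(self.times) < 2:
            return None
        d = np.diff(self.times)
        return int(d[0]) if np.all(d == d[0]) else None

    def with_values(self, values: np.ndarray, label: str | None = None) -> "ProxyTimeSeries":
        return ProxyTimeSeries(
            self.times.copy(), np.asarray(values, float),
            self.label if label is None else label,
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"year": self.times, "value": self.values})


@dataclass(frozen=True)
class RateSeries:
    """Per-step log rates of change of a positive proxy series.

    The rate for the step t-1 → t is stamped at t, so that rate[t]
    aligns with predictor values at t-1 in the model fits.
    """

    times: np.ndarray
    values: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=int)
        v = np.asarray(self.values, dtype=float)
        if len(t) != len(v):
            raise ValueError("length mismatch in RateSeries")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "values", v)

    def __len__(self) -> int:
        return len(self.times)


@dataclass(frozen=True)
class Period:
    """One chrono-cultural period with its ordinal warfare code."""

    name: str
    start: int  # year AD, inclusive
    end: int    # year AD, exclusive
    code: int

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(f"period {self.name!r}: end must exceed start")
        if not 0 <= self.code <= 6:
            raise ValueError(
                f"period {self.name!r}: code {self.code} outside [0, 6]"
            )


@dataclass(frozen=True)
class WarfarePeriodCoding:
    """Ordered, contiguous periods with warfare codes in [0, 6].

    Codes aggregate per-evidence-category scores of absent (0),
    present (1) or common (2); the module accepts any pre-aggregated
    total in [0, 6].  Each period owns its start year and excludes its
    end year (half-open intervals), so boundaries are never counted
    twice.
    """

    periods: tuple[Period, ...]

    def __post_init__(self) -> None:
        ps = tuple(sorted(self.periods, key=lambda p: p.start))
        for a, b in zip(ps, ps[1:]):
            if a.end != b.start:
                raise ValueError(
                    f"periods {a.name!r} and {b.name!r} are not contiguous "
                    f"({a.end} != {b.start})"
                )
        object.__setattr__(self, "periods", ps)

    @property
    def span(self) -> tuple[int, int]:
        return self.periods[0].start, self.periods[-1].end

    @staticmethod
    def component_codes_valid(components: Iterable[int]) -> bool:
        """Check per-category codes are each in {0, 1, 2} before summation."""
        return all(c in (0, 1, 2) for c in components)


# ---------------------------------------------------------------------------
# smoothing


def _spar_to_lam(spar: float) -> float:
    """Map the smoothing parameter spar ∈ [0, 1] to a penalty weight.

    With abscissae rescaled to [0, 1], the penalized least-squares
    objective is  Σ (y_i − g(x_i))² + λ ∫ g''(x)² dx  and we take

        λ(spar) = 256^(3·spar − 1)

    which is strictly increasing in spar, spans ~7 orders of magnitude,
    and puts spar = 0 near interpolation (λ ≈ 0.004) and spar = 1 near
    a linear fit (λ ≈ 6.6e4).  Constant and exactly linear inputs are
    reproduced exactly at every spar because their roughness penalty is
    zero.
    """
    return float(256.0 ** (3.0 * spar - 1.0))


def _penalized_natural_spline(x: np.ndarray, y: np.ndarray, lam: float) -> np.ndarray:
    """Direct Green–Silverman solve of the smoothing-spline problem.

    Returns fitted values g minimizing ||y − g||² + λ gᵀKg with
    K = Q R⁻¹ Qᵀ the natural-cubic-spline roughness matrix.  Used for
    very short series (n == 4) where the B-spline route needs more
    points; any n ≥ 3 works.
    """
    n = len(x)
    h = np.diff(x).astype(float)
    # Q: n x (n-2), R: (n-2) x (n-2) tridiagonal (Green & Silverman 1994)
    Q = np.zeros((n, n - 2))
    R = np.zeros((n - 2, n - 2))
    for j in range(n - 2):
        Q[j, j] = 1.0 / h[j]
        Q[j + 1, j] = -1.0 / h[j] - 1.0 / h[j + 1]
        Q[j + 2, j] = 1.0 / h[j + 1]
        R[j, j] = (h[j] + h[j + 1]) / 3.0
        if j + 1 < n - 2:
            R[j, j + 1] = R[j + 1, j] = h[j + 1] / 6.0
    K = Q @ np.linalg.solve(R, Q.T)
    return np.linalg.solve(np.eye(n) + lam * K, y)


def smooth_spline(series: ProxyTimeSeries, spar: float) -> ProxyTimeSeries:
    """Smooth a series with a penalized cubic spline.

    Parameters
    ----------
    series
        Input series with at least 4 points.
    spar
        Smoothing parameter in [0, 1]; larger is smoother.  The
        residual sum of squares against the raw data is non-decreasing
        in spar.  The warfare index uses 0.90 and the climate proxy
        0.65 by convention in this analysis.
    """
    if not 0.0 <= spar <= 1.0:
        raise ValueError(f"spar must be in [0, 1], got {spar}")
    n = len(series)
    if n < 4:
        raise ValueError(f"smoothing needs at least 4 points, got {n}")
    x = series.times.astype(float)
    x01 = (x - x[0]) / (x[-1] - x[0])
    lam = _spar_to_lam(spar)
    # linear functions are in the penalty's null space, so the smoother
    # commutes with linear detrending; detrending keeps the solve well
    # conditioned at large lambda and makes constant/linear inputs exact
    slope, intercept = np.polyfit(x01, series.values, 1)
    trend = intercept + slope * x01
    resid = series.values - trend
    if n == 4:
        fitted = trend + _penalized_natural_spline(x01, resid, lam)
    else:
        spl = make_smoothing_spline(x01, resid, lam=lam)
        fitted = trend + spl(x01)
    return series.with_values(fitted, label=f"{series.label} smoothed(spar={spar:g})")


# ---------------------------------------------------------------------------
# resampling and rates


def resample(series: ProxyTimeSeries, step: int, start: int, end: int) -> ProxyTimeSeries:
    """Resample onto the grid start, start+step, …, end.

    Values at grid years absent from the source are obtained by linear
    interpolation between neighbouring source points.  The requested
    window must lie inside the source span and step must divide
    end − start.
    """
    if start < series.times[0] or end > series.times[-1]:
        raise ValueError(
            f"window [{start}, {end}] outside source span "
            f"[{series.times[0]}, {series.times[-1]}]"
        )
    if (end - start) % step != 0:
        raise ValueError(f"step {step} does not divide window {end - start}")
    grid = np.arange(start, end + 1, step)
    vals = np.interp(grid, series.times, series.values)
    return ProxyTimeSeries(grid, vals, label=series.label)


def growth_rates(series: ProxyTimeSeries) -> RateSeries:
    """Per-step log rates of change, log X_t − log X_{t−1}.

    All source values must be strictly positive; the rate for the step
    into year t is stamped at t (output has one fewer point than the
    input).
    """
    bad = np.where(series.values <= 0)[0]
    if bad.size:
        raise ValueError(
            f"non-positive value {series.values[bad[0]]:g} at year "
            f"{series.times[bad[0]]}: log rate undefined"
        )
    logv = np.log(series.values)
    return RateSeries(series.times[1:], np.diff(logv), label=f"rate({series.label})")


def encode_warfare(coding: WarfarePeriodCoding, year_range: tuple[int, int]) -> ProxyTimeSeries:
    """Translate period-coded warfare into an annual step function.

    The value at year y is the code of the half-open period
    [start, end) containing y.  Every year of ``year_range``
    (inclusive) must be covered.
    """
    start, end = year_range
    lo, hi = coding.span
    if start < lo or end >= hi:
        raise ValueError(
            f"years [{start}, {end}] not covered by periods [{lo}, {hi})"
        )
    years = np.arange(start, end + 1)
    starts = np.array([p.start for p in coding.periods])
    codes = np.array([float(p.code) for p in coding.periods])
    idx = np.searchsorted(starts, years, side="right") - 1
    return ProxyTimeSeries(years, codes[idx], label="warfare index")


def apply_floor(series: ProxyTimeSeries, eps: float = DEFAULT_WARFARE_FLOOR) -> ProxyTimeSeries:
    """Add a small floor ε before log-transforming a series that can be 0.

    The raw warfare index is legitimately 0 in peaceful periods; the
    multiplicative warfare models need W > 0.  The applied floor is
    logged so runs are auditable.
    """
    if eps <= 0:
        raise ValueError("floor must be positive")
    logger.info("applying floor eps=%g to series %r", eps, series.label)
    return series.with_values(series.values + eps, label=f"{series.label}+{eps:g}")


def clip_range(series: ProxyTimeSeries, lo: float = 0.0, hi: float = 6.0) -> ProxyTimeSeries:
    """Clip values into [lo, hi] (smoothing can overshoot the ordinal range)."""
    return series.with_values(np.clip(series.values, lo, hi), label=series.label)


# ---------------------------------------------------------------------------
# I/O


def read_proxy_csv(path: str | Path, label: str = "") -> ProxyTimeSeries:
    """Read a two-column (year, value) CSV with header."""
    df = pd.read_csv(path)
    if df.shape[1] < 2:
        raise ValueError(f"{path}: expected columns (year, value)")
    return ProxyTimeSeries(
        df.iloc[:, 0].to_numpy(int), df.iloc[:, 1].to_numpy(float),
        label=label or str(path),
    )


def write_proxy_csv(series: ProxyTimeSeries, path: str | Path) -> None:
    series.to_frame().to_csv(path, index=False)


def read_period_table(path: str | Path) -> WarfarePeriodCoding:
    """Read a warfare period table from CSV or YAML.

    CSV columns: name, start, end, code.  YAML: a list of mappings with
    the same keys.  Period year boundaries are a user-supplied
    configuration — they are a property of the regional chronology, not
    of this package.
    """
    path = Path(path)
    if path.suffix.lower() in (".yml", ".yaml"):
        rows = yaml.safe_load(path.read_text())
    else:
        rows = pd.read_csv(path).to_dict("records")
    return WarfarePeriodCoding(tuple(
        Period(str(r["name"]), int(r["start"]), int(r["end"]), int(r["code"]))
        for r in rows
    ))


def aligned_table(
    spd_n: ProxyTimeSeries,
    spd_nn: ProxyTimeSeries,
    lith: ProxyTimeSeries,
    war: ProxyTimeSeries,
) -> pd.DataFrame:
    """Assemble the aligned 25-year analysis table.

    All four inputs must already share one uniform grid.  Columns
    mirror the exchange layout used throughout the analysis: calBP,
    yearAD, SPDn, SPDnn, Rn, Rnn, LithPct, War, Rwar.  Rate columns
    are NaN on the first row (no preceding step).
    """
    grids = {tuple(s.times) for s in (spd_n, spd_nn, lith, war)}
    if len(grids) != 1:
        raise ValueError("series are not on a common grid")
    years = spd_n.times
    rn = np.full(len(years), np.nan)
    rnn = np.full(len(years), np.nan)
    rwar = np.full(len(years), np.nan)
    rn[1:] = growth_rates(spd_n).values
    rnn[1:] = growth_rates(spd_nn).values
    rwar[1:] = growth_rates(apply_floor(war)).values if np.any(war.values <= 0) \
        else growth_rates(war).values
    return pd.DataFrame({
        "calBP": PRESENT_AD - years,
        "yearAD": years,
        "SPDn": spd_n.values,
        "SPDnn": spd_nn.values,
        "Rn": rn,
        "Rnn": rnn,
        "LithPct": lith.values,
        "War": war.values,
        "Rwar": rwar,
    })
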