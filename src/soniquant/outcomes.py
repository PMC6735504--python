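"""Tumor-growth kinetics, survival analysis, and exposure utilities.

Treatment outcome in the orthotopic glioma model is summarized by:

* exponential tumor-volume growth V(t) = V0 * 2^(t/Td), fit per animal to
  estimate the doubling time Td (days);
* Kaplan-Meier product-limit survival with log-rank group comparisons and
  the percent increase in median survival time (IST);
* lognormal-appropriate summaries of drug concentrations — geometric mean
  and geometric %CV — with paired two-tailed t-tests on log-transformed
  sonicated/control pairs;
* body-surface-area dose conversion (human equivalent dose) and the
  per-target pulse repetition frequency of an interleaved sonication.

Kaplan-Meier and log-rank computations are delegated to ``lifelines``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test
from scipy import optimize, stats

__all__ = [
    "GrowthFit",
    "KMResult",
    "LogrankResult",
    "PairedLogTTest",
    "fit_doubling_time",
    "km_curve",
    "logrank",
    "increase_in_survival_time",
    "geometric_summary",
    "paired_log_ttest",
    "human_equivalent_dose",
    "per_target_prf",
]


@dataclass(frozen=True)
class GrowthFit:
    """Exponential growth fit V(t) = V0 * 2^(t/Td)."""

    doubling_days: float
    v0: float
    rmse: float
    finite: bool  # False when growth is flat (Td -> inf) or negative


def _growth_model(t: np.ndarray, v0: float, rate: float) -> np.ndarray:
    # parametrized by rate = 1/Td so a flat series (rate=0) stays finite
    return v0 * np.exp2(np.asarray(t) * rate)


def fit_doubling_time(times_days: Sequence[float], volumes_mm3: Sequence[float]) -> GrowthFit:
    """Estimate the tumor-volume doubling time in days.

    Nonlinear least squares of V(t) = V0 * 2^(t/Td), warm-started from the
    log-linear regression of ln V on t. Requires >= 3 positive volumes at
    strictly increasing times. A flat series yields ``doubling_days=inf``
    with ``finite=False``; a shrinking tumor yields a negative doubling
    time (i.e. a halving time), also flagged non-finite growth.
    """
    t = np.asarray(times_days, dtype=float)
    v = np.asarray(volumes_mm3, dtype=float)
    if t.size < 3:
        raise ValueError("need at least 3 time points")
    if np.any(np.diff(t) <= 0):
        raise ValueError("times must be strictly increasing")
    if np.any(v <= 0):
        raise ValueError("volumes must be positive")

    # log-linear warm start: ln V = ln V0 + t * rate * ln 2
    slope, intercept = np.polyfit(t, np.log2(v), 1)
    p0 = (float(2.0**intercept), float(slope))
    try:
        import warnings as _warnings

        with _warnings.catch_warnings():
            # flat series: covariance is singular, which is expected here
            _warnings.simplefilter("ignore", optimize.OptimizeWarning)
            popt, _ = optimize.curve_fit(_growth_model, t, v, p0=p0, maxfev=5000)
    except RuntimeError as exc:
        raise ValueError(f"growth fit failed to converge: {exc}") from None
    v0, rate = float(popt[0]), float(popt[1])
    rmse = float(np.sqrt(np.mean((_growth_model(t, *popt) - v) ** 2)))
    if abs(rate) < 1e-12:
        return GrowthFit(doubling_days=math.inf, v0=v0, rmse=rmse, finite=False)
    td = 1.0 / rate
    return GrowthFit(doubling_days=td, v0=v0, rmse=rmse, finite=td > 0)


@dataclass(frozen=True)
class KMResult:
    """Kaplan-Meier product-limit estimate with median survival.

    ``median`` uses the convention "earliest time with S(t) <= 0.5";
    ``median_midpoint`` averages that time with the next event time when S
    lands exactly on 0.5 (with an even uncensored sample this reproduces
    the familiar sample median).
    """

    times: np.ndarray
    survival: np.ndarray
    median: float
    median_midpoint: float
    n_events: int
    n_censored: int


def km_curve(table: pd.DataFrame) -> KMResult:
    """Product-limit survival estimate from a (time, event) table.

    ``table`` needs columns ``time_days`` and ``event_flag`` (1 = death,
    0 = censored); deaths precede censorings at tied times, as in the
    standard estimator. Raises if no events occurred (median undefined).
    """
    times = np.asarray(table["time_days"], dtype=float)
    events = np.asarray(table["event_flag"], dtype=int)
    if np.any(times <= 0):
        raise ValueError("survival times must be positive")
    if events.sum() < 1:
        raise ValueError("all subjects censored: survival median undefined")

    kmf = KaplanMeierFitter()
    kmf.fit(times, event_observed=events)
    sf = kmf.survival_function_
    t_grid = sf.index.to_numpy(dtype=float)
    s = sf.iloc[:, 0].to_numpy(dtype=float)

    # median: earliest time with S(t) <= 0.5 (tolerance absorbs the
    # product-limit rounding when S lands exactly on one half)
    below = np.flatnonzero(s <= 0.5 + 1e-9)
    if below.size:
        median = float(t_grid[below[0]])
        median_midpoint = median
        if math.isclose(s[below[0]], 0.5, abs_tol=1e-9):
            # S sits exactly on 1/2: the alternative convention averages
            # with the next event time (sample median for even n, uncensored)
            later = np.unique(times[(events == 1) & (times > median)])
            if later.size:
                median_midpoint = 0.5 * (median + float(later[0]))
    else:
        median = math.inf
        median_midpoint = math.inf
    return KMResult(
        times=t_grid,
        survival=s,
        median=median,
        median_midpoint=median_midpoint,
        n_events=int(events.sum()),
        n_censored=int((events == 0).sum()),
    )


@dataclass(frozen=True)
class LogrankResult:
    chi2: float
    p_value: float
    df: int


def logrank(tables: Sequence[pd.DataFrame]) -> LogrankResult:
    """K-sample log-rank test across survival tables.

    Standard observed-minus-expected statistic referred to a chi-square
    with k-1 degrees of freedom. Requires at least two groups and at least
    one event overall.
    """
    if len(tables) < 2:
        raise ValueError("log-rank comparison needs at least two groups")
    frames = []
    for i, tbl in enumerate(tables):
        frames.append(
            pd.DataFrame(
                {
                    "time_days": np.asarray(tbl["time_days"], dtype=float),
                    "event_flag": np.asarray(tbl["event_flag"], dtype=int),
                    "group": i,
                }
            )
        )
    df = pd.concat(frames, ignore_index=True)
    if df["event_flag"].sum() < 1:
        raise ValueError("no events in any group")
    res = multivariate_logrank_test(df["time_days"], df["group"], df["event_flag"])
    return LogrankResult(
        chi2=float(res.test_statistic), p_value=float(res.p_value), df=len(tables) - 1
    )


def increase_in_survival_time(median_treated: float, median_reference: float) -> float:
    """Percent increase in median survival time (IST) over a reference."""
    if median_reference <= 0:
        raise ValueError("reference median must be positive")
    return 100.0 * (median_treated / median_reference - 1.0)


def geometric_summary(values: Sequence[float]) -> tuple[float, float]:
    """Geometric mean and geometric %CV of positive concentration data.

    gm = exp(mean ln x); gcv% = 100 * sqrt(exp(s^2) - 1) with s^2 the
    sample variance of ln x — the natural summaries for lognormal data.
    """
    x = np.asarray(values, dtype=float)
    if x.size == 0 or np.any(x <= 0):
        raise ValueError("values must be positive and non-empty")
    logs = np.log(x)
    gm = float(np.exp(np.mean(logs)))
    if x.size < 2:
        return gm, 0.0
    gcv = 100.0 * math.sqrt(math.exp(float(np.var(logs, ddof=1))) - 1.0)
    return gm, gcv


@dataclass(frozen=True)
class PairedLogTTest:
    t_statistic: float
    p_value: float
    n: int
    degenerate: bool  # zero variance of the paired log-differences


def paired_log_ttest(sonicated: Sequence[float], control: Sequence[float]) -> PairedLogTTest:
    """Paired two-tailed t-test on log-transformed concentration pairs."""
    a = np.asarray(sonicated, dtype=float)
    b = np.asarray(control, dtype=float)
    if a.size != b.size:
        raise ValueError("paired samples must have equal length")
    if a.size < 2:
        raise ValueError("need at least 2 pairs")
    if np.any(a <= 0) or np.any(b <= 0):
        raise ValueError("values must be positive for the log transform")
    diffs = np.log(a) - np.log(b)
    if np.allclose(np.var(diffs), 0.0):
        if np.allclose(diffs.mean(), 0.0):
            return PairedLogTTest(t_statistic=0.0, p_value=1.0, n=a.size, degenerate=True)
        return PairedLogTTest(t_statistic=math.inf, p_value=0.0, n=a.size, degenerate=True)
    res = stats.ttest_rel(np.log(a), np.log(b))
    return PairedLogTTest(
        t_statistic=float(res.statistic), p_value=float(res.pvalue), n=a.size, degenerate=False
    )


def human_equivalent_dose(animal_dose_mg_per_kg: float, km_factor: float) -> float:
    """Body-surface-area dose scaling: mg/m^2 = mg/kg x Km.

    Km is the species conversion factor (6 for the rat).
    """
    if animal_dose_mg_per_kg < 0 or km_factor <= 0:
        raise ValueError("dose must be >= 0 and Km factor positive")
    return animal_dose_mg_per_kg * km_factor


def per_target_prf(n_targets: int, burst_interval_s: float) -> float:
    """Per-target pulse repetition frequency of an interleaved sonication.

    With bursts cycling across ``n_targets`` every ``burst_interval_s``,
    each target is revisited every n x interval seconds.
    """
    if n_targets < 1 or burst_interval_s <= 0:
        raise ValueError("need n_targets >= 1 and positive burst interval")
    return 1.0 / (n_targets * burst_interval_s)
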