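"""Biodegradable-DOC incubation kinetics.

28-day dark incubations track dissolved organic carbon (DOC) drawdown by
the ambient microbial community. This module computes, per incubation:

* BDOC, the concentration consumed (day-0 minus final-day DOC);
* the first-order decay constant ``k = ln(C0/CT)/T`` from the endpoint
  concentrations (positive for decay) and, as a robustness check, from an
  ordinary log-linear regression over all time points;
* the half-life ``t_1/2 = ln(2)/k`` of the DOC pool;
* the linear relation between initial DOM composition (A:T peak ratio)
  and half-life across incubations.

The endpoint ``k`` is written with the decaying concentration in the
denominator so that consumption gives a positive rate, matching the
reported convention for these incubations; net DOC production (CT > C0)
yields a negative rate and is flagged rather than rejected.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "IncubationSeries",
    "DecayResult",
    "compute_bdoc",
    "decay_rate",
    "half_life",
    "fit_decay_regression",
    "analyze_incubation",
    "correlate_lability",
]

DEFAULT_DURATION_DAYS = 28.0

REQUIRED_COLUMNS = ("site", "season", "replicate", "day", "doc")


@dataclass(frozen=True)
class IncubationSeries:
    """A validated tidy incubation table (site, season, replicate, day, doc)."""

    data: pd.DataFrame

    def __post_init__(self):
        df = self.data
        missing = set(REQUIRED_COLUMNS) - set(df.columns)
        if missing:
            raise ValueError(f"incubation table missing columns: {sorted(missing)}")
        if (df["day"] < 0).any():
            raise ValueError("days must be nonnegative")
        if (df["doc"] <= 0).any():
            raise ValueError("DOC concentrations must be positive")
        if 0 not in set(df["day"]):
            raise ValueError("incubation series must include day 0")

    def replicate_means(self) -> pd.DataFrame:
        """Mean DOC per day across replicates, sorted by day."""
        return (self.data.groupby("day", as_index=False)["doc"].mean()
                .sort_values("day").reset_index(drop=True))


@dataclass(frozen=True)
class DecayResult:
    """Summary of one incubation: consumption, rate, half-life."""

    bdoc: float             # mg/L consumed over the incubation
    k: float                # 1/day, positive for net decay
    t_half: float           # days; NaN when k <= 0
    method: str             # 'endpoint' or 'regression'
    c0: float
    cT: float
    T: float
    net_production: bool = False


def compute_bdoc(c0: float, cT: float) -> float:
    """Biodegradable DOC: initial minus final concentration (mg/L).

    Negative values indicate net DOC production during the incubation and
    are returned as-is with a warning.
    """
    if not (c0 > 0 and cT > 0):
        raise ValueError("concentrations must be positive")
    bdoc = c0 - cT
    if bdoc < 0:
        warnings.warn("final DOC exceeds initial DOC: net production, BDOC < 0")
    return bdoc


def decay_rate(c0: float, cT: float, T: float = DEFAULT_DURATION_DAYS) -> float:
    """First-order decay constant k = ln(C0/CT)/T (1/day).

    Positive for net consumption; negative (flagged) when the pool grew.
    """
    if not (c0 > 0 and cT > 0):
        raise ValueError("concentrations must be positive")
    if not T > 0:
        raise ValueError("incubation duration must be positive")
    k = float(np.log(c0 / cT) / T)
    if k < 0:
        warnings.warn("negative decay rate: net DOC production over the incubation")
    return k


def half_life(k: float) -> float:
    """Half-life of the DOC pool, t_1/2 = ln(2)/k, in days.

    Undefined (NaN, with a warning) for non-positive rates.
    """
    if k <= 0:
        warnings.warn("half-life undefined for non-positive decay rate")
        return float("nan")
    return float(np.log(2.0) / k)


def fit_decay_regression(series: IncubationSeries) -> DecayResult:
    """Log-linear estimate of k over all time points (replicates averaged).

    Ordinary least squares of ln(DOC) on day; the negated slope is k. On
    noiseless exponential data this equals the endpoint estimator exactly.
    """
    means = series.replicate_means()
    if len(means) < 3:
        raise ValueError("regression estimator needs at least 3 time points")
    day = means["day"].to_numpy(float)
    doc = means["doc"].to_numpy(float)
    slope, intercept = np.polyfit(day, np.log(doc), 1)
    k = float(-slope)
    c0_fit = float(np.exp(intercept))
    cT_fit = float(np.exp(intercept + slope * day[-1]))
    if k < -1e-15:  # ignore sign noise from a numerically zero slope
        warnings.warn("negative regression decay rate: net DOC production")
    return DecayResult(
        bdoc=compute_bdoc(doc[0], doc[-1]), k=k,
        t_half=half_life(k) if k > 0 else float("nan"),
        method="regression", c0=c0_fit, cT=cT_fit, T=float(day[-1]),
        net_production=k < 0,
    )


def analyze_incubation(series: IncubationSeries,
                       method: str = "endpoint",
                       T: float | None = None) -> DecayResult:
    """Full per-incubation summary from a tidy replicate table.

    Replicates are averaged per time point; ``method='endpoint'`` (the
    default) applies the two-point formula between day 0 and the final
    day (or ``T`` if given), ``'regression'`` the log-linear fit.
    """
    if method == "regression":
        return fit_decay_regression(series)
    if method != "endpoint":
        raise ValueError(f"unknown method {method!r}")
    means = series.replicate_means()
    day = means["day"].to_numpy(float)
    doc = means["doc"].to_numpy(float)
    T_use = float(day[-1]) if T is None else float(T)
    sel = np.isclose(day, T_use)
    if not sel.any():
        raise ValueError(f"no observation at requested endpoint day {T_use}")
    c0 = float(doc[np.isclose(day, 0.0)][0])
    cT = float(doc[sel][0])
    k = decay_rate(c0, cT, T_use)
    return DecayResult(
        bdoc=compute_bdoc(c0, cT), k=k,
        t_half=half_life(k) if k > 0 else float("nan"),
        method="endpoint", c0=c0, cT=cT, T=T_use, net_production=k < 0,
    )


def correlate_lability(at_ratios: np.ndarray, half_lives: np.ndarray):
    """Linear regression of half-life on the initial A:T peak ratio.

    Tests whether more humic-like (recalcitrant) starting DOM decays more
    slowly. Returns (slope, intercept, r_squared, p_value) from a simple
    OLS with a two-sided slope t-test.
    """
    x = np.asarray(at_ratios, float)
    y = np.asarray(half_lives, float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("inputs must be equal-length 1-D arrays")
    if x.size < 3:
        raise ValueError("need at least 3 paired observations")
    if np.allclose(x, x[0]):
        raise ValueError("zero variance in A:T ratios; regression undefined")
    res = stats.linregress(x, y)
    return float(res.slope), float(res.intercept), float(res.rvalue ** 2), float(res.pvalue)
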