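"""Descriptive statistics and Beta/Gamma/Normal fitting for behavioral readouts.

Sucrose preference is a proportion and typically left-skewed in naive
rats; immobility time is positive and right-skewed.  Neither is Gaussian,
which motivates fitting a Beta law to the former and a Gamma law to the
latter and adjudicating fit with AIC (likelihood-based) alongside the
Kolmogorov–Smirnov distance (assumption-light); the package reports both
without privileging either.

Conventions: skewness and kurtosis are the bias-corrected adjusted
Fisher–Pearson forms with the *excess* kurtosis convention (Gaussian = 0),
matching mainstream statistics-package output.  The Gamma family is
parameterized by (shape, rate).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .classifier import percentile

__all__ = [
    "DescriptiveSummary",
    "DistFit",
    "describe",
    "fit_beta",
    "fit_gamma",
    "fit_normal",
    "compare_fits",
    "qq_points",
    "gamma_shape_from_moments",
]

DEFAULT_LEVELS = (0.05, 0.10, 0.15, 0.25, 0.50, 0.75, 0.85, 0.90, 0.95)

#: Nudge applied to sucrose preference values lying exactly at 0 or 1
#: before Beta fitting (the likelihood is undefined on the boundary).
BOUNDARY_NUDGE = 1e-6


@dataclass
class DescriptiveSummary:
    n: int
    mean: float
    sd: float
    skewness: float
    kurtosis: float  # excess
    percentiles: dict[float, float]


def describe(
    values: Sequence[float],
    levels: Sequence[float] = DEFAULT_LEVELS,
    percentile_method: str = "weibull",
) -> DescriptiveSummary:
    """Descriptive summary with bias-corrected shape statistics.

    Requires n >= 2 for the sd, n >= 3 for skewness and n >= 4 for excess
    kurtosis; a constant sequence (sd = 0) has undefined shape statistics
    and raises.
    """
    x = np.asarray(values, dtype=float)
    if x.size < 4:
        raise ValueError(f"need n >= 4 for a full summary, got n={x.size}")
    sd = float(np.std(x, ddof=1))
    if sd == 0.0:
        raise ValueError("constant sequence: skewness/kurtosis undefined")
    return DescriptiveSummary(
        n=int(x.size),
        mean=float(np.mean(x)),
        sd=sd,
        skewness=float(stats.skew(x, bias=False)),
        kurtosis=float(stats.kurtosis(x, fisher=True, bias=False)),
        percentiles={
            float(p): percentile(x, p, method=percentile_method)
            for p in sorted(levels)
        },
    )


@dataclass
class DistFit:
    """A fitted univariate law.

    ``params`` is (shape1, shape2) for beta, (shape, rate) for gamma and
    (mean, sd) for normal.
    """

    family: str
    params: tuple[float, ...]
    method: str
    logL: float
    n: int

    def frozen(self):
        """The fitted law as a frozen scipy distribution."""
        if self.family == "beta":
            return stats.beta(*self.params)
        if self.family == "gamma":
            shape, rate = self.params
            return stats.gamma(shape, scale=1.0 / rate)
        if self.family == "normal":
            return stats.norm(*self.params)
        raise ValueError(f"unknown family {self.family!r}")

    def mean(self) -> float:
        """Analytic mean of the fitted law."""
        return float(self.frozen().mean())

    @property
    def n_params(self) -> int:
        return len(self.params)

    @property
    def aic(self) -> float:
        return -2.0 * self.logL + 2.0 * self.n_params


def _prepare_beta_values(values: Sequence[float]) -> np.ndarray:
    x = np.asarray(values, dtype=float)
    if ((x < 0) | (x > 1)).any():
        raise ValueError("beta fitting requires values in [0, 1]")
    n_boundary = int(((x == 0) | (x == 1)).sum())
    if n_boundary:
        warnings.warn(
            f"{n_boundary} value(s) at the [0,1] boundary nudged by "
            f"{BOUNDARY_NUDGE} for beta fitting",
            stacklevel=3,
        )
        x = np.clip(x, BOUNDARY_NUDGE, 1.0 - BOUNDARY_NUDGE)
    return x


def _beta_moments_params(mean: float, var: float) -> tuple[float, float]:
    c = mean * (1.0 - mean) / var - 1.0
    if c <= 0:
        raise ValueError(
            f"variance {var} >= mean(1-mean) = {mean * (1 - mean)}: "
            "method of moments infeasible for the beta family"
        )
    return mean * c, (1.0 - mean) * c


def fit_beta(values: Sequence[float], method: str = "mle") -> DistFit:
    """Fit a Beta law to proportions.

    Method of moments solves shape1 = m*c, shape2 = (1-m)*c with
    c = m(1-m)/v - 1; MLE maximizes the likelihood numerically from the
    moments start (location 0 and scale 1 held fixed).
    """
    x = _prepare_beta_values(values)
    if x.size < 3:
        raise ValueError("need n >= 3 to fit a beta law")
    m, v = float(np.mean(x)), float(np.var(x, ddof=1))
    a0, b0 = _beta_moments_params(m, v)
    if method == "moments":
        a, b = a0, b0
    elif method == "mle":
        a, b, _, _ = stats.beta.fit(x, a0, b0, floc=0.0, fscale=1.0)
    else:
        raise ValueError(f"unknown method {method!r}")
    logL = float(np.sum(stats.beta.logpdf(x, a, b)))
    return DistFit("beta", (float(a), float(b)), method, logL, int(x.size))


def gamma_shape_from_moments(mean: float, sd: float) -> float:
    """Method-of-moments Gamma shape (mean/sd)^2 — exact by construction."""
    if mean <= 0 or sd <= 0:
        raise ValueError("mean and sd must be positive")
    return (mean / sd) ** 2


def fit_gamma(values: Sequence[float], method: str = "mle") -> DistFit:
    """Fit a Gamma(shape, rate) law to positive values.

    Method of moments: shape = (mean/sd)^2, rate = mean/variance; MLE via
    the standard likelihood maximization from the moments start (location
    fixed at 0).
    """
    x = np.asarray(values, dtype=float)
    if (x <= 0).any():
        raise ValueError("gamma fitting requires strictly positive values")
    if x.size < 3:
        raise ValueError("need n >= 3 to fit a gamma law")
    m, sd = float(np.mean(x)), float(np.std(x, ddof=1))
    shape0 = gamma_shape_from_moments(m, sd)
    if method == "moments":
        shape, rate = shape0, m / sd**2
    elif method == "mle":
        shape, _, scale = stats.gamma.fit(x, shape0, floc=0.0)
        rate = 1.0 / scale
    else:
        raise ValueError(f"unknown method {method!r}")
    logL = float(np.sum(stats.gamma.logpdf(x, shape, scale=1.0 / rate)))
    return DistFit("gamma", (float(shape), float(rate)), method, logL, int(x.size))


def fit_normal(values: Sequence[float], method: str = "mle") -> DistFit:
    """Gaussian fit; the MLE and the moments fit coincide up to the
    variance denominator (MLE uses 1/n)."""
    x = np.asarray(values, dtype=float)
    if x.size < 3:
        raise ValueError("need n >= 3 to fit a normal law")
    m = float(np.mean(x))
    sd = float(np.std(x, ddof=0 if method == "mle" else 1))
    logL = float(np.sum(stats.norm.logpdf(x, m, sd)))
    return DistFit("normal", (m, sd), method, logL, int(x.size))


_FITTERS = {"beta": fit_beta, "gamma": fit_gamma, "normal": fit_normal}


def compare_fits(
    values: Sequence[float],
    candidates: Sequence[tuple[str, str] | str] = ("beta", "gamma", "normal"),
) -> pd.DataFrame:
    """Fit each candidate family and rank by AIC.

    Returns one row per candidate with logL, AIC, the Kolmogorov–Smirnov
    distance against the fitted law, and the AIC rank.  A family whose
    support excludes the data is recorded as infeasible (NaN statistics),
    not fatal.
    """
    if len(candidates) == 0:
        raise ValueError("no candidate families given")
    rows = []
    for cand in candidates:
        family, method = cand if isinstance(cand, tuple) else (cand, "mle")
        try:
            fit = _FITTERS[family](values, method=method)
        except (ValueError, RuntimeError) as exc:
            rows.append(
                {"family": family, "method": method, "feasible": False,
                 "logL": np.nan, "AIC": np.nan, "ks_distance": np.nan,
                 "note": str(exc)}
            )
            continue
        ks = stats.kstest(np.asarray(values, dtype=float), fit.frozen().cdf)
        rows.append(
            {"family": family, "method": method, "feasible": True,
             "logL": fit.logL, "AIC": fit.aic,
             "ks_distance": float(ks.statistic), "note": ""}
        )
    df = pd.DataFrame(rows)
    df["rank"] = df["AIC"].rank(method="min")
    return df.sort_values("AIC", na_position="last").reset_index(drop=True)


def qq_points(values: Sequence[float], fit: DistFit) -> np.ndarray:
    """Quantile–quantile point data against a fitted law (no rendering).

    The i-th point pairs the fitted law's quantile at plotting position
    (i - 0.5)/n with the i-th order statistic; returned sorted, shape (n, 2).
    """
    x = np.sort(np.asarray(values, dtype=float))
    n = x.size
    if n == 0:
        raise ValueError("empty sample")
    positions = (np.arange(1, n + 1) - 0.5) / n
    theoretical = fit.frozen().ppf(positions)
    return np.column_stack([theoretical, x])
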