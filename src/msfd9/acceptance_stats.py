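"""Statistical range of acceptance for regulated contaminant concentrations.

The compliance rule models concentrations of a contaminant category as
lognormal, Y ~ LN(mu, sigma), anchors the distribution at the geometric mean
of the observed data, places the regulatory threshold level TL at the 90th
percentile of the fitted distribution, and judges a data set compliant when
the empirical 90th percentile does not exceed TL. A Shapiro-Wilk test on
log-concentrations checks the lognormality assumption; its outcome is
reported but never silently changes the decision.

Two conventions for the dispersion parameter are provided:

``cv20`` (default)
    The fitted lognormal has median equal to the geometric mean and a
    natural-scale standard deviation of 20% of that median (a 20%
    coefficient of variation), i.e. ``sigma = sqrt(ln(1 + 0.2**2))``. This
    is unit-free: rescaling the data rescales the range identically.
``literal_log``
    ``sigma = 0.2 * |ln(gm)|`` — dispersion read as 20% of the log-scale
    location itself. Unit-dependent and degenerate at gm = 1; retained for
    auditability only.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import stats

__all__ = [
    "Z90",
    "SIGMA_CV20",
    "geometric_mean",
    "sigma_from_cv",
    "shapiro_log",
    "empirical_quantile",
    "AcceptanceRange",
    "fit_acceptance_range",
    "AcceptanceDecision",
    "assess",
    "write_acceptance_report",
]

#: Standard-normal 90th percentile z_0.9.
Z90: float = float(stats.norm.ppf(0.9))

#: Log-scale sigma giving a 20% natural-scale coefficient of variation.
SIGMA_CV20: float = math.sqrt(math.log(1.0 + 0.2**2))

#: Shapiro-Wilk validity cap; larger samples are subsampled.
_SHAPIRO_MAX_N = 5000


def sigma_from_cv(cv: float) -> float:
    """Log-scale sigma of a lognormal with natural-scale CV ``cv``."""
    if cv <= 0:
        raise ValueError(f"cv must be positive, got {cv}")
    return math.sqrt(math.log1p(cv * cv))


def geometric_mean(values: Sequence[float]) -> float:
    """exp(mean(ln values)); every value must be strictly positive
    (zeros are expected to have been handled by LOQ substitution)."""
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        raise ValueError("geometric mean of empty data")
    nonpos = np.flatnonzero(arr <= 0)
    if nonpos.size:
        raise ValueError(
            f"non-positive value {arr[nonpos[0]]} at index {int(nonpos[0])}"
        )
    return float(np.exp(np.mean(np.log(arr))))


def shapiro_log(
    values: Sequence[float], subsample_seed: int = 0
) -> float:
    """Shapiro-Wilk p-value of ln(values).

    Valid for 3 <= n <= 5000; larger samples are subsampled to 5000 points
    with a fixed seed so the reported p-value is reproducible. Constant
    input is an error (the statistic is undefined).
    """
    arr = np.asarray(values, dtype=float)
    if arr.size < 3:
        raise ValueError(f"Shapiro test needs n >= 3, got n = {arr.size}")
    if np.any(arr <= 0):
        raise ValueError("Shapiro test on logs requires positive values")
    logs = np.log(arr)
    if np.ptp(logs) == 0:
        raise ValueError("Shapiro test undefined for constant data")
    if logs.size > _SHAPIRO_MAX_N:
        rng = np.random.default_rng(subsample_seed)
        logs = rng.choice(logs, size=_SHAPIRO_MAX_N, replace=False)
    return float(stats.shapiro(logs).pvalue)


def empirical_quantile(
    values: Sequence[float], q: float, method: str = "linear"
) -> float:
    """Order-statistic quantile of the data.

    ``method`` is any numpy quantile estimator name; the default linear
    interpolation of the empirical distribution function is used throughout
    the assessment unless configured otherwise.
    """
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        raise ValueError("quantile of empty data")
    if not 0.0 < q < 1.0:
        raise ValueError(f"q must be in (0, 1), got {q}")
    return float(np.quantile(arr, q, method=method))


@dataclass(frozen=True)
class AcceptanceRange:
    """Fitted acceptance range for one category.

    ``gm`` is the geometric mean of the data (category unit), ``mu`` and
    ``sigma`` the log-scale lognormal parameters, ``tl`` the regulatory
    threshold level, ``theoretical_p90`` the 90th percentile of the fitted
    lognormal and ``empirical_p90`` the 90th percentile of the data (both
    in the category unit). ``shapiro_p`` reports the lognormality check.
    """

    category_code: str
    n: int
    gm: float
    mu: float
    sigma: float
    tl: float
    theoretical_p90: float
    empirical_p90: float
    shapiro_p: float
    convention: str = "cv20"


def fit_acceptance_range(
    values: Sequence[float],
    tl: float,
    convention: str = "cv20",
    category_code: str = "",
    quantile_method: str = "linear",
    shapiro_subsample_seed: int = 0,
) -> AcceptanceRange:
    """Fit the acceptance range to one category's concentration data.

    Requires n >= 3 strictly positive values and tl > 0. The theoretical
    90th percentile is the closed-form lognormal quantile
    ``exp(mu + z_0.9 * sigma)``.
    """
    arr = np.asarray(values, dtype=float)
    if arr.size < 3:
        raise ValueError(f"need n >= 3 values to fit, got {arr.size}")
    if tl <= 0:
        raise ValueError(f"threshold level must be positive, got {tl}")
    gm = geometric_mean(arr)
    mu = math.log(gm)
    if convention == "cv20":
        sigma = SIGMA_CV20
    elif convention == "literal_log":
        if mu == 0.0:
            raise ValueError(
                "literal_log convention degenerate at gm = 1 (mu = 0)"
            )
        sigma = 0.2 * abs(mu)
    else:
        raise ValueError(f"unknown convention {convention!r}")
    theoretical_p90 = math.exp(mu + Z90 * sigma)
    empirical_p90 = empirical_quantile(arr, 0.9, method=quantile_method)
    try:
        shapiro_p = shapiro_log(arr, subsample_seed=shapiro_subsample_seed)
    except ValueError:
        # constant data: the normality check is undefined, not a failure
        shapiro_p = float("nan")
    return AcceptanceRange(
        category_code=category_code,
        n=int(arr.size),
        gm=gm,
        mu=mu,
        sigma=sigma,
        tl=float(tl),
        theoretical_p90=theoretical_p90,
        empirical_p90=empirical_p90,
        shapiro_p=shapiro_p,
        convention=convention,
    )


@dataclass(frozen=True)
class AcceptanceDecision:
    """Pass/fail of a data set against its threshold level.

    ``passed`` is True iff the empirical 90th percentile does not exceed
    TL (ties pass). ``margin = tl - empirical_p90`` in the category unit.
    ``normality_ok`` flags the Shapiro gate at the configured alpha; a
    failed gate is reported, never a silent decision change.
    """

    category_code: str
    passed: bool
    margin: float
    normality_ok: bool
    range: AcceptanceRange


def assess(
    values: Sequence[float],
    tl: float,
    convention: str = "cv20",
    alpha: float = 0.05,
    category_code: str = "",
    quantile_method: str = "linear",
) -> AcceptanceDecision:
    """Fit the acceptance range and decide compliance."""
    rng_ = fit_acceptance_range(
        values,
        tl,
        convention=convention,
        category_code=category_code,
        quantile_method=quantile_method,
    )
    passed = rng_.empirical_p90 <= rng_.tl
    normality_ok = bool(
        not math.isnan(rng_.shapiro_p) and rng_.shapiro_p >= alpha
    )
    return AcceptanceDecision(
        category_code=category_code,
        passed=passed,
        margin=rng_.tl - rng_.empirical_p90,
        normality_ok=normality_ok,
        range=rng_,
    )


_REPORT_COLUMNS = [
    "category_code",
    "n",
    "gm",
    "mu",
    "sigma",
    "tl",
    "theoretical_p90",
    "empirical_p90",
    "shapiro_p",
    "pass",
]


def write_acceptance_report(
    decisions: Sequence[AcceptanceDecision], path
) -> None:
    """Emit one delimited-text row per category's acceptance decision."""
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write(",".join(_REPORT_COLUMNS) + "\n")
        for d in decisions:
            r = d.range
            row = [
                r.category_code,
                str(r.n),
                repr(r.gm),
                repr(r.mu),
                repr(r.sigma),
                repr(r.tl),
                repr(r.theoretical_p90),
                repr(r.empirical_p90),
                repr(r.shapiro_p),
                "true" if d.passed else "false",
            ]
            fh.write(",".join(row) + "\n")
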