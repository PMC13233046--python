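"""Comparative statistics: burden-vs-lifespan regression, leave-one-out
sensitivity, rank correlation, and paired tests.

The central comparison is a simple linear regression of excess mutation
burden against species covariates — maximum lifespan (MLS, years), adult body
mass, or longevity quotient (LQ) — with leave-one-out refits to check that no
single influential species (human, whale, rat) drives the correlation.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from math import factorial
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats


@dataclass(frozen=True)
class SpeciesMeta:
    species: str
    mls_years: float
    body_mass_g: float
    lq: float

    def __post_init__(self):
        for attr in ("mls_years", "body_mass_g", "lq"):
            v = getattr(self, attr)
            if not np.isfinite(v) or v <= 0:
                raise ValueError(f"{attr} must be finite and positive, got {v}")


@dataclass
class RegressionResult:
    covariate: str
    slope: float
    intercept: float
    r_squared: float
    p_value: float
    n: int
    excluded: list[str] = field(default_factory=list)


def fit_regression(
    x: Sequence[float],
    y: Sequence[float],
    covariate: str = "x",
    excluded: Sequence[str] = (),
) -> RegressionResult:
    """Ordinary least squares of y on x; two-sided slope p from the t
    distribution with n-2 df; R² is the squared Pearson correlation."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("x and y lengths differ")
    if x.size < 3:
        raise ValueError(f"regression needs n >= 3 points, got {x.size}")
    if np.ptp(x) == 0:
        raise ValueError("constant x: regression undefined")
    res = stats.linregress(x, y)
    r2 = float(res.rvalue**2)
    if np.isnan(r2):  # constant y: flat line fits exactly, no correlation
        r2 = 0.0
    p = float(res.pvalue)
    return RegressionResult(
        covariate=covariate,
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=r2,
        p_value=1.0 if np.isnan(p) else p,
        n=int(x.size),
        excluded=list(excluded),
    )


def leave_one_out(
    points: pd.DataFrame,
    exclusions: Sequence[Sequence[str]],
    x: str = "x",
    y: str = "y",
    covariate: str = "x",
) -> list[RegressionResult]:
    """Refit the regression after excluding each listed species set.

    ``points`` needs columns ``species``, ``x``, ``y``; each result is exactly
    :func:`fit_regression` on the retained subset. The empty exclusion set
    reproduces the full fit.
    """
    known = set(points["species"])
    results = []
    for excl in exclusions:
        excl = list(excl)
        unknown = set(excl) - known
        if unknown:
            raise ValueError(f"unknown species in exclusion: {sorted(unknown)}")
        sub = points[~points["species"].isin(excl)]
        results.append(
            fit_regression(sub[x], sub[y], covariate=covariate, excluded=excl)
        )
    return results


def _midranks(v: np.ndarray) -> np.ndarray:
    return stats.rankdata(v, method="average")


def spearman_correlation(
    x: Sequence[float], y: Sequence[float], exact_max_n: int = 9
) -> tuple[float, float]:
    """Spearman's rank correlation with midranks for ties.

    rho is the Pearson correlation of the rank vectors. The two-sided p-value
    is exact — enumerating all n! rank permutations — for n <= ``exact_max_n``,
    and the usual t(n-2) approximation above that.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("x and y lengths differ")
    n = x.size
    if n < 4:
        raise ValueError(f"need n >= 4, got {n}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("constant vector: rank correlation undefined")
    rx, ry = _midranks(x), _midranks(y)
    rho = float(np.corrcoef(rx, ry)[0, 1])
    if n <= exact_max_n:
        perms = np.array(list(itertools.permutations(range(n))))
        rho_null = _rank_corr_all(rx, ry[perms])
        p = float(np.mean(np.abs(rho_null) >= abs(rho) - 1e-12))
    else:
        if abs(rho) >= 1.0:
            p = 0.0
        else:
            t = rho * np.sqrt((n - 2) / (1 - rho**2))
            p = float(2 * stats.t.sf(abs(t), df=n - 2))
    return rho, p


def _rank_corr_all(rx: np.ndarray, ry_rows: np.ndarray) -> np.ndarray:
    """Pearson correlation of rx against each row of ry_rows."""
    rx_c = rx - rx.mean()
    ry_c = ry_rows - ry_rows.mean(axis=1, keepdims=True)
    num = ry_c @ rx_c
    den = np.sqrt((rx_c**2).sum() * (ry_c**2).sum(axis=1))
    return num / den


def paired_t_test(a: Sequence[float], b: Sequence[float]) -> tuple[float, float]:
    """Two-sided paired Student's t-test on matched samples."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size != b.size:
        raise ValueError("paired test needs equal lengths")
    if a.size < 2:
        raise ValueError("need n >= 2 pairs")
    d = b - a
    if np.all(d == 0):
        raise ValueError("all paired differences are zero: t statistic undefined")
    if d.std(ddof=1) == 0:  # constant non-zero shift: t diverges, p -> 0
        return float(np.sign(d[0]) * np.inf), 0.0
    res = stats.ttest_rel(b, a)
    return float(res.statistic), float(res.pvalue)


def wilcoxon_signed_rank(a: Sequence[float], b: Sequence[float]) -> tuple[float, float]:
    """Two-sided Wilcoxon matched-pairs signed-rank test; exact null
    distribution for n <= 25 non-zero differences, normal approximation above."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size != b.size:
        raise ValueError("paired test needs equal lengths")
    d = b - a
    nonzero = np.count_nonzero(d)
    if nonzero == 0:
        raise ValueError("all paired differences are zero: W statistic undefined")
    if a.size < 5:
        raise ValueError("need n >= 5 pairs")
    method = "exact" if nonzero <= 25 else "approx"
    res = stats.wilcoxon(b, a, zero_method="wilcox", method=method)
    return float(res.statistic), float(res.pvalue)
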