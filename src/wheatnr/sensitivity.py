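"""Trait sensitivity to N supply and path-coefficient decomposition.

Sensitivity of a trait to fertilizer N is the ordinary least-squares slope
``k`` of the trait against the N rate (trait units per kg N/ha), fitted per
cultivar x year on treatment means by default.  Slopes of different traits
are then correlated across cultivars to ask, e.g., whether cultivars whose
fast-filling phase lengthens most under N are also the most N-responsive
in yield.

Path analysis decomposes the correlation of each yield component (grain
weight GW, grains per spike GPS, spikes per unit area SPUA) with grain
yield GY into a direct standardized path coefficient plus indirect
contributions routed through the other components:

    r(i, GY) = direct_i + sum_{j != i} r_ij * direct_j

The direct coefficients solve the standardized normal equations
R_pred p = r_resp, so the identity above holds exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "SensitivitySlope",
    "PathDecomposition",
    "sensitivity_slope",
    "variance_explained",
    "path_analysis",
    "PathAnalysisModel",
]


@dataclass(frozen=True)
class SensitivitySlope:
    trait: str
    cultivar: str
    year: str
    k: float
    b: float
    r_squared: float


@dataclass(frozen=True)
class PathDecomposition:
    """Direct/indirect path decomposition of predictor-response correlations.

    ``indirect[i, j]`` (j != i) is the contribution of predictor i routed
    through predictor j, r_ij * direct_j; the diagonal is zero.
    ``r_squared_single[i]`` is the variance in the response explained by
    predictor i alone (squared correlation); ``r_squared_full`` is the
    multiple-R^2 of the joint standardized regression,
    sum_i direct_i * r(i, response).
    """

    response: str
    predictors: tuple[str, ...]
    direct: np.ndarray
    indirect: np.ndarray
    correlations: np.ndarray
    r_squared_single: np.ndarray
    r_squared_full: float
    n: int

    def summary(self) -> str:
        lines = [f"Path analysis of {self.response} on {', '.join(self.predictors)} "
                 f"(n = {self.n})",
                 f"  full R^2 = {self.r_squared_full:.4f}",
                 "  predictor   r(y)      direct    sum(indirect)   r^2 single"]
        for i, p in enumerate(self.predictors):
            ind = self.indirect[i].sum()
            lines.append(
                f"  {p:<10} {self.correlations[i]:8.4f} {self.direct[i]:10.4f} "
                f"{ind:12.4f} {self.r_squared_single[i]:12.4f}"
            )
        return "\n".join(lines)


def sensitivity_slope(
    rates, values, trait: str = "trait", cultivar: str = "cultivar", year: str = "year"
) -> SensitivitySlope:
    """OLS slope of a trait against fertilizer N rate (>= 3 distinct rates)."""
    x = np.asarray(rates, dtype=float)
    y = np.asarray(values, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("rates and values must be 1-D arrays of equal length")
    if len(np.unique(x)) < 3:
        raise ValueError("need at least 3 distinct N rates")
    if np.ptp(x) == 0:
        raise ValueError("zero variance in N rates")
    res = stats.linregress(x, y)
    r2 = float(res.rvalue ** 2) if np.std(y) > 0 else 0.0
    return SensitivitySlope(trait=trait, cultivar=cultivar, year=year,
                            k=float(res.slope), b=float(res.intercept), r_squared=r2)


def variance_explained(x, y) -> float:
    """Fraction of variance in y explained by x: squared Pearson correlation."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or len(x) < 3:
        raise ValueError("need >= 3 paired observations")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance: correlation undefined")
    r = float(np.corrcoef(x, y)[0, 1])
    return r * r


def path_analysis(
    data: pd.DataFrame, response: str, predictors: list[str] | tuple[str, ...]
) -> PathDecomposition:
    """Standardized path decomposition of a response on its components.

    Solves R_pred p = r_resp for the direct coefficients; the predictor
    correlation matrix must be non-singular.
    """
    predictors = tuple(predictors)
    cols = [response, *predictors]
    d = data[cols].dropna()
    n = len(d)
    if n < len(predictors) + 2:
        raise ValueError(f"need at least {len(predictors) + 2} complete rows, got {n}")
    mat = d.to_numpy(dtype=float)
    if np.any(np.std(mat, axis=0) == 0):
        raise ValueError("a column has zero variance")
    corr = np.corrcoef(mat, rowvar=False)
    r_resp = corr[0, 1:]
    r_pred = corr[1:, 1:]
    cond = np.linalg.cond(r_pred)
    if cond > 1e10:
        raise ValueError(f"singular predictor correlation matrix (cond = {cond:.3g})")
    direct = np.linalg.solve(r_pred, r_resp)
    p = len(predictors)
    indirect = np.zeros((p, p))
    for i in range(p):
        for j in range(p):
            if i != j:
                indirect[i, j] = r_pred[i, j] * direct[j]
    return PathDecomposition(
        response=response,
        predictors=predictors,
        direct=direct,
        indirect=indirect,
        correlations=r_resp,
        r_squared_single=r_resp ** 2,
        r_squared_full=float(direct @ r_resp),
        n=n,
    )


class PathAnalysisModel:
    """Model facade: path decomposition of yield on its components."""

    def __init__(self, data: pd.DataFrame, response: str = "grain_yield_t_ha",
                 predictors: tuple[str, ...] = ("gw_mg", "gps", "spua")):
        self.data = data
        self.response = response
        self.predictors = tuple(predictors)

    def fit(self) -> PathDecomposition:
        return path_analysis(self.data, self.response, self.predictors)


def correlate_slopes(
    slopes_a: pd.Series, slopes_b: pd.Series
) -> tuple[float, float, bool]:
    """Pearson r (with two-sided p) between two across-cultivar slope sets.

    Returns (r, p, low_power) where low_power flags n < 8 samples — with a
    handful of cultivars the test has little power and should be read as
    descriptive.
    """
    a, b = slopes_a.align(slopes_b, join="inner")
    if len(a) < 3:
        raise ValueError("need at least 3 paired slopes")
    r, p = stats.pearsonr(a.to_numpy(float), b.to_numpy(float))
    return float(r), float(p), len(a) < 8
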