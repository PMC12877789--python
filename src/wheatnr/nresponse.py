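"""Linear-plateau yield-nitrogen response fitting.

Grain yield of a cultivar rises approximately linearly with fertilizer N up
to a breakpoint and is flat beyond it:

    GY(N) = intercept + n_r * min(N, n_cs)

The slope of the linear phase, N_r, measures the cultivar's N
responsiveness; the breakpoint N_cs is the critical N supply — the minimum
fertilizer rate achieving the maximum yield GY_max = intercept + n_r * n_cs.

For a fixed breakpoint the model is linear in (intercept, slope), so the
fit profiles the residual sum of squares over a deterministic candidate
grid of breakpoints (closed-form conditional least squares at each), then
refines the best candidate with bounded scalar minimisation.  Ties are
broken toward the smallest breakpoint, matching the "minimum N rate"
definition of the critical supply.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize_scalar

__all__ = [
    "YieldResponseSeries",
    "LinearPlateauFit",
    "LinearPlateauModel",
    "LinearPlateauResults",
    "fit_linear_plateau",
    "predict_yield",
]


@dataclass(frozen=True)
class YieldResponseSeries:
    """Replicate- or mean-level yields of one cultivar x year across N rates."""

    cultivar: str
    year: str
    n_rates: np.ndarray
    yields: np.ndarray

    def __post_init__(self) -> None:
        r = np.asarray(self.n_rates, dtype=float)
        y = np.asarray(self.yields, dtype=float)
        object.__setattr__(self, "n_rates", r)
        object.__setattr__(self, "yields", y)
        if r.shape != y.shape or r.ndim != 1:
            raise ValueError("n_rates and yields must be 1-D arrays of equal length")
        if np.any(r < 0):
            raise ValueError("N rates must be non-negative")
        if len(np.unique(r)) < 3:
            raise ValueError("need at least 3 distinct N rates for a breakpoint fit")
        if np.any(y <= 0):
            raise ValueError("yields must be positive")


@dataclass(frozen=True)
class LinearPlateauFit:
    """Fitted linear-plateau response.

    ``gy_max = intercept + n_r * n_cs`` by construction (continuity).
    ``plateau_observed`` is False when the optimal breakpoint sits at the
    maximum tested rate, i.e. the response is still linear over the design.
    ``degenerate`` flags an all-equal-yields input; ``negative_slope`` flags
    an N-depressed (downward) response.
    """

    intercept: float
    n_r: float
    n_cs: float
    gy_max: float
    rss: float
    plateau_observed: bool
    degenerate: bool = False
    negative_slope: bool = False


def _conditional_ls(rates: np.ndarray, yields: np.ndarray, ncs: float) -> tuple[float, float, float]:
    """Closed-form least squares of y on min(rate, ncs); returns (b0, b1, rss)."""
    x = np.minimum(rates, ncs)
    xm, ym = x.mean(), yields.mean()
    sxx = float(np.sum((x - xm) ** 2))
    if sxx <= 1e-12:
        # breakpoint at/below the smallest rate: flat model (mean)
        b0, b1 = ym, 0.0
    else:
        b1 = float(np.sum((x - xm) * (yields - ym)) / sxx)
        b0 = ym - b1 * xm
    rss = float(np.sum((yields - (b0 + b1 * x)) ** 2))
    return b0, b1, rss


def fit_linear_plateau(
    series: YieldResponseSeries, grid_step: float = 1.0
) -> LinearPlateauFit:
    """Continuity-constrained least-squares linear-plateau fit.

    Breakpoint candidates are the observed rates plus a uniform grid
    (``grid_step`` kg N/ha) over [min rate, max rate]; the winner is refined
    with bounded minimisation over +/- one grid step.  Deterministic.
    """
    r, y = series.n_rates, series.yields
    rmin, rmax = float(r.min()), float(r.max())

    if np.allclose(y, y[0]):
        return LinearPlateauFit(
            intercept=float(y[0]), n_r=0.0, n_cs=rmin, gy_max=float(y[0]),
            rss=float(np.sum((y - y.mean()) ** 2)), plateau_observed=True,
            degenerate=True,
        )

    candidates = np.unique(np.concatenate([
        np.arange(rmin, rmax, grid_step), np.unique(r), [rmax],
    ]))
    # candidates below the second distinct rate make min(r, c) constant;
    # the flat model there is handled by _conditional_ls
    best_c, best_rss, best_b = None, math.inf, (0.0, 0.0)
    for c in candidates:
        b0, b1, rss = _conditional_ls(r, y, float(c))
        if rss < best_rss - 1e-12 or (
            abs(rss - best_rss) <= 1e-12 and (best_c is None or c < best_c)
        ):
            best_c, best_rss, best_b = float(c), rss, (b0, b1)

    lo = max(rmin, best_c - grid_step)
    hi = min(rmax, best_c + grid_step)
    if hi > lo:
        ref = minimize_scalar(
            lambda c: _conditional_ls(r, y, c)[2],
            bounds=(lo, hi), method="bounded",
            options={"xatol": 1e-8},
        )
        if np.isfinite(ref.fun) and ref.fun < best_rss - 1e-12:
            best_c = float(ref.x)
            b0, b1, best_rss = _conditional_ls(r, y, best_c)
            best_b = (b0, b1)

    b0, b1 = best_b
    plateau_observed = best_c < rmax - 1e-9
    return LinearPlateauFit(
        intercept=b0,
        n_r=b1,
        n_cs=best_c,
        gy_max=b0 + b1 * best_c,
        rss=best_rss,
        plateau_observed=plateau_observed,
        negative_slope=b1 < 0,
    )


def predict_yield(fit: LinearPlateauFit, n_rate) -> np.ndarray | float:
    """GY(N) = intercept + n_r * min(N, n_cs); equals gy_max beyond n_cs."""
    n = np.asarray(n_rate, dtype=float)
    if np.any(n < 0):
        raise ValueError("n_rate must be non-negative")
    out = fit.intercept + fit.n_r * np.minimum(n, fit.n_cs)
    return float(out) if np.isscalar(n_rate) else out


class LinearPlateauModel:
    """Linear-plateau model of grain yield against fertilizer N rate."""

    def __init__(self, n_rates, yields, cultivar: str = "cultivar", year: str = "year"):
        self.series = YieldResponseSeries(cultivar, year, np.asarray(n_rates, float),
                                          np.asarray(yields, float))

    @classmethod
    def from_dataframe(cls, df, rate_col="n_rate_kg_ha", yield_col="grain_yield_t_ha",
                       cultivar: str = "cultivar", year: str = "year"):
        return cls(df[rate_col].to_numpy(), df[yield_col].to_numpy(),
                   cultivar=cultivar, year=year)

    def fit(self, grid_step: float = 1.0) -> "LinearPlateauResults":
        return LinearPlateauResults(self, fit_linear_plateau(self.series, grid_step))


@dataclass
class LinearPlateauResults:
    model: LinearPlateauModel
    fit: LinearPlateauFit

    def predict(self, n_rate):
        return predict_yield(self.fit, n_rate)

    @property
    def n_r(self) -> float:
        return self.fit.n_r

    @property
    def n_cs(self) -> float:
        return self.fit.n_cs

    @property
    def gy_max(self) -> float:
        return self.fit.gy_max

    def summary(self) -> str:
        f = self.model.series
        ft = self.fit
        flags = []
        if ft.degenerate:
            flags.append("degenerate (all yields equal)")
        if ft.negative_slope:
            flags.append("negative slope (N-depressed)")
        if not ft.plateau_observed:
            flags.append("no plateau within tested rates")
        return "\n".join([
            f"Linear-plateau yield response: {f.cultivar} / {f.year}",
            f"  intercept = {ft.intercept:.4f} t/ha",
            f"  N_r   = {ft.n_r:.5f} t/ha per kg N/ha",
            f"  N_cs  = {ft.n_cs:.2f} kg N/ha",
            f"  GY_max = {ft.gy_max:.4f} t/ha",
            f"  rss = {ft.rss:.6g}",
        ] + ([f"  flags: {'; '.join(flags)}"] if flags else []))
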