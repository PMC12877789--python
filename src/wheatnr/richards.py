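"""Richards growth-curve fitting and grain-filling phase decomposition.

The grain-filling trajectory of a wheat grain is modelled with the
four-parameter Richards function

    W(t) = A * (1 + B * exp(-k t))**(-1/N)

where ``W`` is grain weight, ``t`` days post-anthesis, ``A`` the asymptotic
final grain weight, ``k`` a rate constant (d^-1) and ``B``, ``N`` shape
coefficients.  The filling process is decomposed into three phases —
slow-, fast- and slight-increase — delimited by the two zeros of the third
time-derivative of ``W`` (``T1``, ``T2``) and by the time at which the grain
reaches 99 % of its final weight (``T3``).  All phase boundaries and the
maximum / mean filling rates have closed forms in (A, B, k, N), which this
module implements alongside a robust multi-start least-squares fitter.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

__all__ = [
    "RichardsParams",
    "FillingTraits",
    "FitDiagnostics",
    "FitConfig",
    "GrainFillSeries",
    "RichardsModel",
    "RichardsResults",
    "richards_weight",
    "richards_rate",
    "filling_traits",
    "fit_richards",
]


class TraitOrderingError(ValueError):
    """Raised when the phase boundaries of a fitted curve are not ordered."""


@dataclass(frozen=True)
class RichardsParams:
    """Coefficients of one grain-filling curve.

    Attributes
    ----------
    A : float
        Asymptotic final grain weight (weight units of the series).
    B : float
        Shape/offset coefficient (> 0); shifts the curve along the time axis.
    k : float
        Rate constant (d^-1, > 0).
    N : float
        Shape exponent (> 0); N = 1 recovers the logistic curve.
    """

    A: float
    B: float
    k: float
    N: float

    def __post_init__(self) -> None:
        for name in ("A", "B", "k", "N"):
            v = getattr(self, name)
            if not (np.isfinite(v) and v > 0):
                raise ValueError(f"Richards parameter {name} must be finite and > 0, got {v!r}")

    def as_array(self) -> np.ndarray:
        return np.array([self.A, self.B, self.k, self.N])


@dataclass(frozen=True)
class FillingTraits:
    """Derived grain-filling descriptors (all closed form in the parameters).

    ``T1 < T2 < T3`` are the phase end-times (d); the durations are
    ``T_slow = T1``, ``T_fast = T2 - T1``, ``T_slight = T3 - T2``.
    ``gfr_max``/``gfr_mean`` are the maximum and mean filling rates
    (weight d^-1).  ``t1_nonpositive`` flags curves whose slow phase ends
    at or before anthesis; such fits are kept but excluded from downstream
    aggregation.
    """

    gfr_max: float
    gfr_mean: float
    t1: float
    t2: float
    t3: float
    t_slow: float
    t_fast: float
    t_slight: float
    t1_nonpositive: bool = False


@dataclass(frozen=True)
class FitDiagnostics:
    rss: float
    r_squared: float
    n_points: int
    converged: bool
    n_restarts_used: int


@dataclass(frozen=True)
class FitConfig:
    """Options for the least-squares fit.

    ``r2_accept`` is the coefficient of determination below which the
    multi-start grid is tried; ``max_nfev`` caps function evaluations per
    start.
    """

    r2_accept: float = 0.98
    max_nfev: int = 2000
    xtol: float = 1e-12
    ftol: float = 1e-12


@dataclass(frozen=True)
class GrainFillSeries:
    """One plot's grain-weight time series (days post-anthesis vs weight)."""

    plot_id: str
    times: np.ndarray
    weights: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        w = np.asarray(self.weights, dtype=float)
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "weights", w)
        if t.ndim != 1 or w.shape != t.shape:
            raise ValueError("times and weights must be 1-D arrays of equal length")
        if len(t) < 5:
            raise ValueError("a Richards fit needs at least 5 time points (4 free parameters)")
        if t[0] < 0 or np.any(np.diff(t) <= 0):
            raise ValueError("times must be non-negative and strictly increasing")
        if np.any(w <= 0):
            raise ValueError("grain weights must be strictly positive")


# ---------------------------------------------------------------------------
# closed-form curve, rate, and phase boundaries
# ---------------------------------------------------------------------------

def richards_weight(params: RichardsParams, t):
    """Grain weight W(t) = A (1 + B e^{-kt})^{-1/N}.

    Evaluated in log space so that large |k t| cannot overflow: with
    z = ln B - k t,  W = A exp(-log(1+e^z)/N).
    """
    t = np.asarray(t, dtype=float)
    z = math.log(params.B) - params.k * t
    return params.A * np.exp(-np.logaddexp(0.0, z) / params.N)


def richards_rate(params: RichardsParams, t):
    """Filling rate dW/dt = (A k B / N) e^{-kt} (1 + B e^{-kt})^{-1/N - 1}."""
    t = np.asarray(t, dtype=float)
    z = math.log(params.B) - params.k * t
    log_rate = (
        math.log(params.A * params.k / params.N)
        + z
        - (1.0 + 1.0 / params.N) * np.logaddexp(0.0, z)
    )
    return np.exp(log_rate)


def _inflection_u(N: float) -> tuple[float, float]:
    """Values of u = B e^{-kt} at the zeros of the third derivative.

    The third derivative of the Richards function vanishes at
    u = [N^2 + 3N ± N sqrt(N^2 + 6N + 5)] / 2; the larger root corresponds
    to the earlier time T1 (u decreases with t).
    """
    disc = math.sqrt(N * N + 6.0 * N + 5.0)
    u1 = (N * N + 3.0 * N + N * disc) / 2.0
    u2 = (N * N + 3.0 * N - N * disc) / 2.0
    return u1, u2


def filling_traits(params: RichardsParams, *, strict: bool = True) -> FillingTraits:
    """Compute phase end-times, durations and filling rates in closed form.

    GFR_max = k A (N+1)^{-(N+1)/N}          (rate at the inflection point)
    GFR_mean = A k / (2 (N+2))
    T1, T2  = -(1/k) ln(u/B) at the third-derivative zeros u
    T3      = -(1/k) ln[((100/99)^N - 1)/B]   (W(T3) = 0.99 A)

    Raises :class:`TraitOrderingError` when T3 <= T2, i.e. when the parameter
    set violates (100/99)^N - 1 < (N^2 + 3N - N sqrt(N^2+6N+5))/2.  A curve
    whose slow phase ends before anthesis (T1 <= 0) is returned with the
    ``t1_nonpositive`` flag set rather than clamped.
    """
    A, B, k, N = params.A, params.B, params.k, params.N
    u1, u2 = _inflection_u(N)
    u3 = (100.0 / 99.0) ** N - 1.0
    if strict and not u3 < u2:
        raise TraitOrderingError(
            "phase ordering violated: (100/99)^N - 1 = "
            f"{u3:.6g} must be < (N^2+3N-N*sqrt(N^2+6N+5))/2 = {u2:.6g} for T3 > T2"
        )
    t1 = -math.log(u1 / B) / k
    t2 = -math.log(u2 / B) / k
    t3 = -math.log(u3 / B) / k
    gfr_max = k * A * (N + 1.0) ** (-(N + 1.0) / N)
    gfr_mean = A * k / (2.0 * (N + 2.0))
    return FillingTraits(
        gfr_max=gfr_max,
        gfr_mean=gfr_mean,
        t1=t1,
        t2=t2,
        t3=t3,
        t_slow=t1,
        t_fast=t2 - t1,
        t_slight=t3 - t2,
        t1_nonpositive=t1 <= 0.0,
    )


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------

def _initial_guess(t: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Data-driven start: A from the series maximum, k from a logistic
    linearisation of logit(W/A0) vs t, N0 = 1, B0 through the first point."""
    a0 = 1.05 * float(np.max(w))
    p = np.clip(w / a0, 1e-6, 1.0 - 1e-6)
    logit = np.log(p / (1.0 - p))
    k0 = float(np.polyfit(t, logit, 1)[0])
    k0 = min(max(k0, 0.01), 1.0)
    n0 = 1.0
    # (1 + B e^{-k t1})^{-1/N} = w1/A0  =>  B = ((A0/w1)^N - 1) e^{k t1}
    b0 = ((a0 / w[0]) ** n0 - 1.0) * math.exp(k0 * t[0])
    b0 = min(max(b0, 1e-3), 1e3)
    return np.array([a0, b0, k0, n0])


def _residuals(x: np.ndarray, t: np.ndarray, w: np.ndarray) -> np.ndarray:
    p = RichardsParams(*x)
    return richards_weight(p, t) - w


def fit_richards(
    series: GrainFillSeries, config: FitConfig | None = None
) -> tuple[RichardsParams, FitDiagnostics]:
    """Unweighted least-squares fit of the Richards curve to one series.

    The first attempt starts from a data-driven guess; if it fails or leaves
    r^2 below ``config.r2_accept`` a deterministic 3x3x3 multiplicative grid
    over (k0, N0, B0) x {0.5, 1, 2} is tried and the lowest-RSS solution kept.
    Non-convergence of every start is reported through the diagnostics
    (``converged=False``), never hidden behind a fallback value.
    """
    config = config or FitConfig()
    t, w = series.times, series.weights
    x0 = _initial_guess(t, w)
    lo = np.array([1e-9, 1e-6, 1e-6, 1e-6])
    hi = np.array([3.0 * float(np.max(w)), 1e3, 1e3, 1e3])

    tss = float(np.sum((w - w.mean()) ** 2))

    def attempt(x_start: np.ndarray):
        x_start = np.clip(x_start, lo * (1 + 1e-12), hi * (1 - 1e-12))
        try:
            sol = least_squares(
                _residuals,
                x_start,
                bounds=(lo, hi),
                args=(t, w),
                xtol=config.xtol,
                ftol=config.ftol,
                gtol=1e-12,
                max_nfev=config.max_nfev,
            )
        except Exception:
            return None
        if not np.all(np.isfinite(sol.x)):
            return None
        return sol

    best = attempt(x0)
    n_restarts = 0

    def rss_of(sol) -> float:
        return float(2.0 * sol.cost)

    def r2_of(sol) -> float:
        if tss <= 0:
            return 1.0
        return 1.0 - rss_of(sol) / tss

    need_grid = best is None or not best.success or r2_of(best) < config.r2_accept
    if need_grid:
        a0, b0, k0, n0 = x0
        for mk in (0.5, 1.0, 2.0):
            for mn in (0.5, 1.0, 2.0):
                for mb in (0.5, 1.0, 2.0):
                    n_restarts += 1
                    cand = attempt(np.array([a0, b0 * mb, k0 * mk, n0 * mn]))
                    if cand is None or not cand.success:
                        continue
                    if best is None or rss_of(cand) < rss_of(best) - 1e-14:
                        best = cand

    if best is None:
        diag = FitDiagnostics(math.inf, 0.0, len(t), False, n_restarts)
        raise RuntimeError(f"Richards fit failed for {series.plot_id}: {diag}")

    params = RichardsParams(*best.x)
    diag = FitDiagnostics(
        rss=rss_of(best),
        r_squared=r2_of(best),
        n_points=len(t),
        converged=bool(best.success),
        n_restarts_used=n_restarts,
    )
    return params, diag


# ---------------------------------------------------------------------------
# Model / Results facade
# ---------------------------------------------------------------------------

class RichardsModel:
    """Richards growth model for one grain-weight time series.

    Parameters
    ----------
    times, weights : array-like
        Days post-anthesis (strictly increasing, >= 0) and grain weights
        (> 0, at least 5 points).
    plot_id : str
        Identifier carried through to outputs.

    Examples
    --------
    >>> model = RichardsModel([0, 6, 12, 18, 24, 30, 36], weights)
    >>> res = model.fit()
    >>> res.traits.t_fast
    """

    def __init__(self, times, weights, plot_id: str = "series"):
        self.series = GrainFillSeries(plot_id, np.asarray(times, float), np.asarray(weights, float))

    @classmethod
    def from_dataframe(cls, df, time_col="day_post_anthesis", weight_col="grain_weight",
                       plot_id: str = "series"):
        d = df.sort_values(time_col)
        return cls(d[time_col].to_numpy(), d[weight_col].to_numpy(), plot_id=plot_id)

    def fit(self, config: FitConfig | None = None) -> "RichardsResults":
        params, diag = fit_richards(self.series, config)
        return RichardsResults(self, params, diag)


@dataclass
class RichardsResults:
    """Fitted Richards curve with diagnostics and derived filling traits."""

    model: RichardsModel
    params: RichardsParams
    diagnostics: FitDiagnostics
    _traits: FillingTraits | None = field(default=None, repr=False)

    @property
    def traits(self) -> FillingTraits:
        if self._traits is None:
            self._traits = filling_traits(self.params)
        return self._traits

    def predict(self, t):
        return richards_weight(self.params, t)

    def rate(self, t):
        return richards_rate(self.params, t)

    def bse(self) -> np.ndarray:
        """Approximate standard errors from the Gauss-Newton covariance."""
        t, w = self.model.series.times, self.model.series.weights
        x = self.params.as_array()
        eps = np.maximum(1e-7 * np.abs(x), 1e-9)
        jac = np.empty((len(t), 4))
        for j in range(4):
            xp, xm = x.copy(), x.copy()
            xp[j] += eps[j]
            xm[j] -= eps[j]
            jac[:, j] = (
                richards_weight(RichardsParams(*xp), t) - richards_weight(RichardsParams(*xm), t)
            ) / (2 * eps[j])
        dof = max(len(t) - 4, 1)
        sigma2 = self.diagnostics.rss / dof
        try:
            cov = sigma2 * np.linalg.inv(jac.T @ jac)
            return np.sqrt(np.clip(np.diag(cov), 0, None))
        except np.linalg.LinAlgError:
            return np.full(4, np.nan)

    def summary(self) -> str:
        p, d = self.params, self.diagnostics
        se = self.bse()
        lines = [
            f"Richards grain-filling fit: {self.model.series.plot_id}",
            f"  n = {d.n_points}, rss = {d.rss:.6g}, r^2 = {d.r_squared:.6f}, "
            f"converged = {d.converged}, restarts = {d.n_restarts_used}",
            "  param      estimate     std.err.",
            f"  A      {p.A:12.5g} {se[0]:12.4g}",
            f"  B      {p.B:12.5g} {se[1]:12.4g}",
            f"  k      {p.k:12.5g} {se[2]:12.4g}",
            f"  N      {p.N:12.5g} {se[3]:12.4g}",
        ]
        try:
            tr = self.traits
            lines += [
                f"  GFR_max = {tr.gfr_max:.4g}  GFR_mean = {tr.gfr_mean:.4g} (weight/d)",
                f"  T1 = {tr.t1:.3f}  T2 = {tr.t2:.3f}  T3 = {tr.t3:.3f} (d)",
                f"  T_slow = {tr.t_slow:.3f}  T_fast = {tr.t_fast:.3f}  "
                f"T_slight = {tr.t_slight:.3f} (d)",
            ]
            if tr.t1_nonpositive:
                lines.append("  flag: T1 <= 0 (slow phase ended before anthesis)")
        except TraitOrderingError as exc:
            lines.append(f"  traits unavailable: {exc}")
        return "\n".join(lines)
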