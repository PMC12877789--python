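"""Flag-leaf SPAD decline and chlorophyll degradation rate (CDR).

Post-anthesis SPAD readings (an optical proxy for leaf chlorophyll) are
fitted with a quadratic SPAD(t) = a t^2 + b t + c.  The magnitude of the
curvature term, |2a| — the slope of the first derivative 2at + b — serves
as the chlorophyll degradation rate.  Because the description of CDR in
the field literature conflates |2a| with the slope of a straight-line
regression of SPAD on time, both quantities are computed: ``cdr`` follows
the quadratic-curvature definition, ``linear_decline_rate`` the ordinary
least-squares slope magnitude.  |2a| is invariant to shifting the time
origin and to adding any linear trend; the linear rate is invariant only
to constant shifts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["SpadSeries", "SenescenceFit", "SpadDeclineModel", "SenescenceResults", "fit_spad"]


@dataclass(frozen=True)
class SpadSeries:
    plot_id: str
    times: np.ndarray
    spad: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        s = np.asarray(self.spad, dtype=float)
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "spad", s)
        if t.ndim != 1 or s.shape != t.shape:
            raise ValueError("times and spad must be 1-D arrays of equal length")
        if len(np.unique(t)) != len(t):
            raise ValueError("duplicate measurement times")
        if np.any(s < 0):
            raise ValueError("SPAD values must be non-negative")


@dataclass(frozen=True)
class SenescenceFit:
    """Quadratic senescence fit: coefficients, CDR and the linear rate.

    ``quadratic_available`` is False when fewer than 3 points were given; the
    linear decline rate is still reported in that case (with a, b, c NaN).
    """

    a: float
    b: float
    c: float
    cdr: float
    linear_decline_rate: float
    rss: float
    quadratic_available: bool = True


def fit_spad(series: SpadSeries) -> SenescenceFit:
    """Least-squares quadratic fit of SPAD on days post-anthesis.

    cdr = |2a|; linear_decline_rate = |OLS slope of SPAD on t|.
    """
    t, s = series.times, series.spad
    slope = float(np.polyfit(t, s, 1)[0]) if len(t) >= 2 else np.nan
    if len(t) < 3:
        return SenescenceFit(np.nan, np.nan, np.nan, np.nan, abs(slope), np.nan,
                             quadratic_available=False)
    coeffs = np.polyfit(t, s, 2)
    a, b, c = (float(v) for v in coeffs)
    resid = s - np.polyval(coeffs, t)
    return SenescenceFit(
        a=a, b=b, c=c,
        cdr=abs(2.0 * a),
        linear_decline_rate=abs(slope),
        rss=float(np.sum(resid ** 2)),
    )


class SpadDeclineModel:
    """Quadratic model of post-anthesis flag-leaf SPAD decline."""

    def __init__(self, times, spad, plot_id: str = "series"):
        self.series = SpadSeries(plot_id, np.asarray(times, float), np.asarray(spad, float))

    @classmethod
    def from_dataframe(cls, df, time_col="day_post_anthesis", spad_col="spad",
                       plot_id: str = "series"):
        d = df.sort_values(time_col)
        return cls(d[time_col].to_numpy(), d[spad_col].to_numpy(), plot_id=plot_id)

    def fit(self) -> "SenescenceResults":
        return SenescenceResults(self, fit_spad(self.series))


@dataclass
class SenescenceResults:
    model: SpadDeclineModel
    fit: SenescenceFit

    def predict(self, t):
        f = self.fit
        if not f.quadratic_available:
            raise ValueError("quadratic fit unavailable (fewer than 3 points)")
        return np.polyval([f.a, f.b, f.c], np.asarray(t, float))

    def summary(self) -> str:
        f = self.fit
        lines = [f"SPAD senescence fit: {self.model.series.plot_id}"]
        if f.quadratic_available:
            lines += [
                f"  SPAD(t) = {f.a:.5f} t^2 + {f.b:.5f} t + {f.c:.3f}",
                f"  CDR (|2a|) = {f.cdr:.5f} SPAD/d^2",
                f"  linear decline rate = {f.linear_decline_rate:.5f} SPAD/d",
                f"  rss = {f.rss:.6g}",
            ]
        else:
            lines += [
                "  quadratic unavailable (fewer than 3 points)",
                f"  linear decline rate = {f.linear_decline_rate:.5f} SPAD/d",
            ]
        return "\n".join(lines)
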