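"""Synthetic wheat field-trial generator.

Emulates a two-year split-plot trial: five cultivars spanning a gradient of
nitrogen responsiveness, four fertilizer rates (0/75/150/225 kg N/ha) and
three replicates.  For every plot the generator produces

* a grain-weight time series sampled every 6 d from 0-36 d post-anthesis,
  drawn from a Richards curve whose fast-increase duration (T_fast) and
  final weight respond linearly to N up to the cultivar's critical supply;
* flag-leaf SPAD readings at 7/14/21/28 d following a concave quadratic
  whose curvature |2a| equals the cultivar's chlorophyll degradation rate
  at that N rate;
* organ-level N pools at anthesis and maturity satisfying the whole-plant
  mass balance (n_am = n_vtm + n_gm and n_gm = NTA + post-anthesis uptake)
  exactly before noise injection;
* plot yields following a linear-plateau response, plus yield components.

Cultivar profiles are invented but encode the qualitative gradients seen in
N-responsiveness trials: yield, N_r, N_cs, anthesis N accumulation and
T_fast sensitivity all increase from the oldest cultivar (BM1) to the most
modern (JM22) while the chlorophyll degradation rate decreases, and the
pre-anthesis share of grain N spans roughly 60-78 %.

All randomness flows from a single seed expanded into independent
per-table substreams, so regenerating with the same seed and design is
byte-identical and adding a table cannot perturb existing ones.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .richards import RichardsParams, _inflection_u, filling_traits, richards_weight

__all__ = [
    "CultivarProfile",
    "TrialDesign",
    "TrialDataset",
    "default_profiles",
    "derive_richards",
    "generate_trial",
    "load_trial_config",
]

WEIGHT_FLOOR = 0.01  # mg; truncation floor for noise-driven negative weights


@dataclass(frozen=True)
class CultivarProfile:
    """Generating parameters of one cultivar.

    Responses to fertilizer N are linear with saturation at ``ncs_true``:
    e.g. the Richards asymptote is a_base + a_per_n * min(N, ncs_true).
    ``trans_frac`` is the fraction of anthesis N translocated to grain and
    ``post_uptake_frac`` the fraction of grain N taken up post-anthesis, so
    the generated CNTA equals 100 * (1 - post_uptake_frac).
    """

    name: str
    a_base: float            # final grain weight at N0 (mg per grain)
    a_per_n: float           # mg per kg N/ha
    tfast_base: float        # d at N0
    tfast_per_n: float       # d per kg N/ha
    n_shape: float           # Richards N exponent
    b_coef: float            # Richards B
    nr_true: float           # yield slope (t/ha per kg N/ha)
    ncs_true: float          # kg N/ha
    gy0: float               # t/ha at N0
    cdr_base: float          # SPAD/d^2 at N0
    cdr_per_n: float         # SPAD/d^2 per kg N/ha (negative: N delays senescence)
    naa_base: float          # anthesis N at N0 (g/m^2)
    naa_per_n: float         # g/m^2 per kg N/ha
    post_uptake_frac: float  # fraction of grain N from post-anthesis uptake
    trans_frac: float        # fraction of anthesis N translocated to grain
    wshoot_base: float = 6.0     # anthesis shoot biomass at N0 (t/ha)
    wshoot_per_n: float = 0.02   # t/ha per kg N/ha
    gps_base: float = 30.0       # grains per spike at N0
    gps_per_n: float = 0.02
    spua_base: float = 520.0     # spikes per m^2 (scaled) at N0
    spua_per_n: float = 0.20
    spad_base: float = 48.0      # SPAD intercept at N0
    spad_per_n: float = 0.025

    def __post_init__(self) -> None:
        if self.tfast_base <= 0:
            raise ValueError("tfast_base must be positive")
        if not 0 <= self.post_uptake_frac < 1:
            raise ValueError("post_uptake_frac must lie in [0, 1)")
        if not 0 < self.trans_frac < 0.9:
            raise ValueError("trans_frac must lie in (0, 0.9)")


@dataclass(frozen=True)
class TrialDesign:
    """Trial layout, sampling cadence and noise levels."""

    years: tuple[str, ...] = ("2018", "2019")
    n_rates: tuple[float, ...] = (0.0, 75.0, 150.0, 225.0)
    reps: int = 3
    sampling_days: tuple[float, ...] = (0.0, 6.0, 12.0, 18.0, 24.0, 30.0, 36.0)
    spad_days: tuple[float, ...] = (7.0, 14.0, 21.0, 28.0)
    grain_sigma: float = 0.5     # weight units
    spad_sigma: float = 0.8      # SPAD units
    yield_sigma: float = 0.2     # t/ha
    npool_cv: float = 0.05       # relative, biomass and concentration
    soil_n_kg_ha: float = 60.0   # available soil N entering N_e
    seed: int = 42

    def __post_init__(self) -> None:
        for s in (self.grain_sigma, self.spad_sigma, self.yield_sigma, self.npool_cv):
            if s < 0:
                raise ValueError("noise levels must be non-negative")
        rates = tuple(float(r) for r in self.n_rates)
        if len(set(rates)) != len(rates) or any(r < 0 for r in rates):
            raise ValueError("N rates must be distinct and non-negative")
        object.__setattr__(self, "n_rates", rates)


@dataclass
class TrialDataset:
    """The four plot-level tables plus generator truth."""

    grain_series: pd.DataFrame
    spad_series: pd.DataFrame
    organ_n: pd.DataFrame
    yields: pd.DataFrame
    truth: pd.DataFrame
    n_floored: int = 0

    def write(self, outdir: str | Path) -> dict[str, Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {}
        for name in ("grain_series", "spad_series", "organ_n", "yields", "truth"):
            p = outdir / f"{name}.csv"
            getattr(self, name).to_csv(p, index=False)
            paths[name] = p
        return paths

    @classmethod
    def read(cls, indir: str | Path) -> "TrialDataset":
        indir = Path(indir)
        tables = {}
        for name in ("grain_series", "spad_series", "organ_n", "yields"):
            tables[name] = pd.read_csv(indir / f"{name}.csv")
        truth_path = indir / "truth.csv"
        tables["truth"] = pd.read_csv(truth_path) if truth_path.exists() else pd.DataFrame()
        return cls(**tables)


def default_profiles() -> list[CultivarProfile]:
    """Five cultivars spanning the era gradient from BM1 (1950s) to JM22 (2000s)."""
    return [
        CultivarProfile("BM1", a_base=34.0, a_per_n=0.010, tfast_base=10.0,
                        tfast_per_n=0.006, n_shape=1.0, b_coef=18.0,
                        nr_true=0.014, ncs_true=130.0, gy0=4.0,
                        cdr_base=0.050, cdr_per_n=-4.0e-5,
                        naa_base=8.0, naa_per_n=0.030,
                        post_uptake_frac=0.40, trans_frac=0.55),
        CultivarProfile("JN2", a_base=36.0, a_per_n=0.011, tfast_base=10.8,
                        tfast_per_n=0.009, n_shape=1.0, b_coef=19.0,
                        nr_true=0.016, ncs_true=138.0, gy0=4.3,
                        cdr_base=0.047, cdr_per_n=-4.2e-5,
                        naa_base=8.6, naa_per_n=0.035,
                        post_uptake_frac=0.35, trans_frac=0.60),
        CultivarProfile("TS1", a_base=38.0, a_per_n=0.012, tfast_base=11.6,
                        tfast_per_n=0.012, n_shape=1.0, b_coef=20.0,
                        nr_true=0.018, ncs_true=144.0, gy0=4.6,
                        cdr_base=0.044, cdr_per_n=-4.4e-5,
                        naa_base=9.2, naa_per_n=0.040,
                        post_uptake_frac=0.30, trans_frac=0.65),
        CultivarProfile("JM26", a_base=40.0, a_per_n=0.013, tfast_base=12.4,
                        tfast_per_n=0.015, n_shape=1.0, b_coef=20.0,
                        nr_true=0.020, ncs_true=149.0, gy0=4.9,
                        cdr_base=0.041, cdr_per_n=-4.6e-5,
                        naa_base=9.8, naa_per_n=0.047,
                        post_uptake_frac=0.25, trans_frac=0.68),
        CultivarProfile("JM22", a_base=42.0, a_per_n=0.014, tfast_base=13.2,
                        tfast_per_n=0.018, n_shape=1.0, b_coef=21.0,
                        nr_true=0.022, ncs_true=152.0, gy0=5.2,
                        cdr_base=0.038, cdr_per_n=-4.8e-5,
                        naa_base=10.4, naa_per_n=0.055,
                        post_uptake_frac=0.22, trans_frac=0.72),
    ]


def load_trial_config(path: str | Path) -> tuple[list[CultivarProfile], TrialDesign]:
    """Read cultivar profiles and trial design from a JSON config file.

    Layout: {"profiles": [{profile fields}, ...], "design": {design fields}};
    either key may be omitted to use the defaults.
    """
    import json

    cfg = json.loads(Path(path).read_text())
    profiles = [CultivarProfile(**p) for p in cfg.get("profiles", [])] or default_profiles()
    d = dict(cfg.get("design", {}))
    for key in ("years", "n_rates", "sampling_days", "spad_days"):
        if key in d:
            d[key] = tuple(d[key])
    return profiles, TrialDesign(**d)


def _clamped(base: float, per_n: float, n_rate: float, ncs: float) -> float:
    return base + per_n * min(n_rate, ncs)


def derive_richards(profile: CultivarProfile, n_rate: float) -> RichardsParams:
    """Richards parameters whose T_fast hits the profile's target exactly.

    T_fast = ln(u1/u2)/k depends only on (k, N), so k is solved from the
    target duration; B then fixes the phase onset and A the asymptote.
    """
    tfast = _clamped(profile.tfast_base, profile.tfast_per_n, n_rate, profile.ncs_true)
    if tfast <= 0:
        raise ValueError(f"target T_fast must be positive, got {tfast}")
    u1, u2 = _inflection_u(profile.n_shape)
    k = math.log(u1 / u2) / tfast
    if not 1e-6 < k <= 1e3:
        raise ValueError(f"infeasible T_fast target {tfast}: k = {k} out of bounds")
    a = _clamped(profile.a_base, profile.a_per_n, n_rate, profile.ncs_true)
    return RichardsParams(A=a, B=profile.b_coef, k=k, N=profile.n_shape)


# organ shares of anthesis N and biomass; leaves translocate a slightly
# smaller share of their pool than stems+chaff
ANTHESIS_SHARES = {"stem": 0.45, "leaf": 0.35, "chaff": 0.20}
LEAF_TRANS_RELATIVE = 0.85
MATURITY_BIOMASS_RETENTION = 0.92


def _organ_translocation_fracs(trans_frac: float) -> dict[str, float]:
    """Per-organ translocated fractions whose share-weighted sum is trans_frac."""
    f_leaf = LEAF_TRANS_RELATIVE * trans_frac
    other_share = ANTHESIS_SHARES["stem"] + ANTHESIS_SHARES["chaff"]
    f_other = (trans_frac - ANTHESIS_SHARES["leaf"] * f_leaf) / other_share
    return {"stem": f_other, "leaf": f_leaf, "chaff": f_other}


def _year_offset(year_index: int) -> float:
    # mild season effect: second year slightly less favourable
    return 0.0 if year_index == 0 else -0.15


def generate_trial(
    profiles: list[CultivarProfile] | None = None,
    design: TrialDesign | None = None,
) -> TrialDataset:
    """Generate the full synthetic trial (four tables + truth).

    Deterministic given ``design.seed``; the seed is expanded into four
    independent substreams (grain, SPAD, yields, organ N).
    """
    profiles = profiles if profiles is not None else default_profiles()
    design = design or TrialDesign()
    ss = np.random.SeedSequence(design.seed)
    rng_grain, rng_spad, rng_yield, rng_organ = (
        np.random.default_rng(s) for s in ss.spawn(4)
    )

    grain_rows, spad_rows, organ_rows, yield_rows = [], [], [], []
    n_floored = 0
    t_grain = np.asarray(design.sampling_days, float)
    t_spad = np.asarray(design.spad_days, float)

    for yi, year in enumerate(design.years):
        dy = _year_offset(yi)
        for prof in profiles:
            for rate in design.n_rates:
                params = derive_richards(prof, rate)
                params = replace_a(params, params.A + dy)
                cdr = prof.cdr_base + prof.cdr_per_n * rate
                spad0 = _clamped(prof.spad_base, prof.spad_per_n, rate, prof.ncs_true) + dy
                gy_true = _clamped(prof.gy0, prof.nr_true, rate, prof.ncs_true) + dy * 0.1
                n_aa = _clamped(prof.naa_base, prof.naa_per_n, rate, prof.ncs_true)
                w_shoot = _clamped(prof.wshoot_base, prof.wshoot_per_n, rate, prof.ncs_true)
                nta = prof.trans_frac * n_aa
                n_vtm = n_aa - nta
                n_gm = nta / (1.0 - prof.post_uptake_frac)
                fracs = _organ_translocation_fracs(prof.trans_frac)
                for rep in range(1, design.reps + 1):
                    plot = f"{year}-{prof.name}-N{int(rate)}-R{rep}"

                    w = richards_weight(params, t_grain)
                    w_noisy = w + rng_grain.normal(0.0, design.grain_sigma, len(t_grain))
                    floored = w_noisy < WEIGHT_FLOOR
                    n_floored += int(floored.sum())
                    w_noisy = np.maximum(w_noisy, WEIGHT_FLOOR)
                    for t, wt in zip(t_grain, w_noisy):
                        grain_rows.append((year, prof.name, rate, rep, plot, t, wt))

                    spad = (
                        spad0 - 0.05 * t_spad - 0.5 * cdr * t_spad ** 2
                        + rng_spad.normal(0.0, design.spad_sigma, len(t_spad))
                    )
                    spad = np.maximum(spad, 0.0)
                    for t, s in zip(t_spad, spad):
                        spad_rows.append((year, prof.name, rate, rep, plot, t, s))

                    gy = gy_true + rng_yield.normal(0.0, design.yield_sigma)
                    gy = max(gy, 0.5)
                    gw = params.A + rng_yield.normal(0.0, 0.6)
                    gps = _clamped(prof.gps_base, prof.gps_per_n, rate, prof.ncs_true) \
                        + rng_yield.normal(0.0, 1.0)
                    spua = _clamped(prof.spua_base, prof.spua_per_n, rate, prof.ncs_true) \
                        + rng_yield.normal(0.0, 12.0)
                    yield_rows.append((year, prof.name, rate, rep, gy, gw, gps, spua))

                    # exact pools first; noise multiplies biomass and conc
                    shoot_g_m2 = w_shoot * 100.0
                    organ_states = []
                    for org, share in ANTHESIS_SHARES.items():
                        n_amt = share * n_aa
                        bio = share * shoot_g_m2
                        organ_states.append(("anthesis", org, bio, n_amt))
                    for org, share in ANTHESIS_SHARES.items():
                        n_amt = share * n_aa * (1.0 - fracs[org])
                        bio = share * shoot_g_m2 * MATURITY_BIOMASS_RETENTION
                        organ_states.append(("maturity", org, bio, n_amt))
                    organ_states.append(("maturity", "grain", gy_true * 100.0, n_gm))
                    for stage, org, bio, n_amt in organ_states:
                        bio_n = bio * (1.0 + rng_organ.normal(0.0, design.npool_cv))
                        amt_n = n_amt * (1.0 + rng_organ.normal(0.0, design.npool_cv))
                        bio_n = max(bio_n, 1e-6)
                        amt_n = max(amt_n, 1e-9)
                        conc = 100.0 * amt_n / bio_n  # percent
                        organ_rows.append(
                            (year, prof.name, rate, rep, plot, stage, org, bio_n, conc)
                        )

    grain_series = pd.DataFrame(grain_rows, columns=[
        "year", "cultivar", "n_rate_kg_ha", "rep", "plot_id",
        "day_post_anthesis", "grain_weight"])
    spad_series = pd.DataFrame(spad_rows, columns=[
        "year", "cultivar", "n_rate_kg_ha", "rep", "plot_id",
        "day_post_anthesis", "spad"])
    organ_n = pd.DataFrame(organ_rows, columns=[
        "year", "cultivar", "n_rate_kg_ha", "rep", "plot_id", "stage", "organ",
        "biomass_g_m2", "n_conc_pct"])
    yields = pd.DataFrame(yield_rows, columns=[
        "year", "cultivar", "n_rate_kg_ha", "rep", "grain_yield_t_ha",
        "gw_mg", "gps", "spua"])

    truth = _truth_table(profiles, design)
    return TrialDataset(grain_series, spad_series, organ_n, yields, truth,
                        n_floored=n_floored)


def replace_a(params: RichardsParams, new_a: float) -> RichardsParams:
    return RichardsParams(A=max(new_a, 1e-6), B=params.B, k=params.k, N=params.N)


def _ols_slope(x: np.ndarray, y: np.ndarray) -> float:
    xm, ym = x.mean(), y.mean()
    sxx = float(np.sum((x - xm) ** 2))
    if sxx == 0.0:  # degenerate single-rate design: sensitivity undefined
        return float("nan")
    return float(np.sum((x - xm) * (y - ym)) / sxx)


def _truth_table(profiles: list[CultivarProfile], design: TrialDesign) -> pd.DataFrame:
    """Generator parameters plus the effective (design-rate OLS) sensitivities."""
    rates = np.asarray(design.n_rates, float)
    rows = []
    for prof in profiles:
        tfast = np.array([
            _clamped(prof.tfast_base, prof.tfast_per_n, r, prof.ncs_true) for r in rates])
        naa = np.array([
            _clamped(prof.naa_base, prof.naa_per_n, r, prof.ncs_true) for r in rates])
        nta = prof.trans_frac * naa
        cdr = prof.cdr_base + prof.cdr_per_n * rates
        rows.append({
            "cultivar": prof.name,
            "nr_true": prof.nr_true,
            "ncs_true": prof.ncs_true,
            "gy0": prof.gy0,
            "a_base": prof.a_base,
            "a_per_n": prof.a_per_n,
            "tfast_base": prof.tfast_base,
            "tfast_per_n": prof.tfast_per_n,
            "tfast_sens_true": _ols_slope(rates, tfast),
            "naa_sens_true": _ols_slope(rates, naa),
            "nta_sens_true": _ols_slope(rates, nta),
            "cdr_sens_true": _ols_slope(rates, cdr),
            "cdr_base": prof.cdr_base,
            "post_uptake_frac": prof.post_uptake_frac,
            "trans_frac": prof.trans_frac,
            "cnta_true_pct": 100.0 * (1.0 - prof.post_uptake_frac),
        })
    return pd.DataFrame(rows)
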