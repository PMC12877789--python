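"""End-to-end analysis pipeline: read -> fit -> aggregate -> sensitivity.

Sequences the per-plot model fits (Richards grain filling, SPAD decline),
the per-cultivar x year linear-plateau yield response, the plot-level N
budget/efficiency accounting, the trait-sensitivity regressions and the
yield-component path analysis, and bundles every output table with a run
manifest.  Per-plot fit failures are logged, excluded from aggregates and
counted in the manifest; a failure fraction above 20 % is a pipeline-level
error.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .nitrogen import OrganNSample, efficiency_indices, nni, translocation
from .nresponse import LinearPlateauModel
from .richards import FitConfig, RichardsModel, TraitOrderingError
from .senescence import SpadDeclineModel
from .sensitivity import PathAnalysisModel, sensitivity_slope

logger = logging.getLogger("wheatnr")

PLOT_KEYS = ["year", "cultivar", "n_rate_kg_ha", "rep"]

#: traits entering the sensitivity regressions, with their source table
SENSITIVITY_TRAITS = {
    "t_slow": "richards",
    "t_fast": "richards",
    "t_slight": "richards",
    "gfr_max": "richards",
    "gfr_mean": "richards",
    "cdr": "senescence",
    "nta": "nitrogen",
    "n_aa": "nitrogen",
}


class ValidationError(ValueError):
    """Input tables violate the documented schema or invariants."""


class FitFailureError(RuntimeError):
    """More than the tolerated fraction of per-plot fits failed."""


@dataclass(frozen=True)
class AnalysisConfig:
    """Options of one analysis run.

    ``fit_level`` chooses between fitting each replicate plot ("plot",
    default: preserves error structure) or cultivar x N mean series
    ("mean"); ``cdr_mode`` selects which senescence statistic feeds the
    sensitivity regressions (quadratic-curvature "cdr" per the printed
    formula, or "linear" for the straight-line decline rate).
    """

    fit_level: str = "plot"          # "plot" | "mean"
    cdr_mode: str = "cdr"            # "cdr" | "linear"
    soil_n_kg_ha: float = 60.0
    dilution_biomass_unit: str = "t_ha"   # "t_ha" | "kg_ha"
    breakpoint_grid_step: float = 1.0
    max_failure_frac: float = 0.2
    seed: int = 0
    fit: FitConfig = field(default_factory=FitConfig)

    def __post_init__(self) -> None:
        if self.fit_level not in ("plot", "mean"):
            raise ValueError("fit_level must be 'plot' or 'mean'")
        if self.cdr_mode not in ("cdr", "linear"):
            raise ValueError("cdr_mode must be 'cdr' or 'linear'")
        if self.dilution_biomass_unit not in ("t_ha", "kg_ha"):
            raise ValueError("dilution_biomass_unit must be 't_ha' or 'kg_ha'")


@dataclass
class ResultBundle:
    """All output tables of one run plus the manifest."""

    richards_fits: pd.DataFrame
    n_response: pd.DataFrame
    senescence_fits: pd.DataFrame
    n_budget: pd.DataFrame
    efficiency: pd.DataFrame
    nni: pd.DataFrame
    sensitivity: pd.DataFrame
    path_analysis: pd.DataFrame
    manifest: dict

    _tables = ("richards_fits", "n_response", "senescence_fits", "n_budget",
               "efficiency", "nni", "sensitivity", "path_analysis")

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for name in self._tables:
            getattr(self, name).to_csv(outdir / f"{name}.csv", index=False)
        (outdir / "manifest.json").write_text(json.dumps(self.manifest, indent=2))

    def content_hash(self) -> str:
        """Stable hash of every output table (excludes the manifest)."""
        h = hashlib.sha256()
        for name in self._tables:
            h.update(getattr(self, name).to_csv(index=False).encode())
        return h.hexdigest()


# ---------------------------------------------------------------------------
# validation
# ---------------------------------------------------------------------------

_SCHEMAS = {
    "grain_series": ["year", "cultivar", "n_rate_kg_ha", "rep", "plot_id",
                     "day_post_anthesis", "grain_weight"],
    "spad_series": ["year", "cultivar", "n_rate_kg_ha", "rep", "plot_id",
                    "day_post_anthesis", "spad"],
    "organ_n": ["year", "cultivar", "n_rate_kg_ha", "rep", "plot_id", "stage",
                "organ", "biomass_g_m2", "n_conc_pct"],
    "yields": ["year", "cultivar", "n_rate_kg_ha", "rep", "grain_yield_t_ha",
               "gw_mg", "gps", "spua"],
}


def validate_dataset(tables: dict[str, pd.DataFrame]) -> dict:
    """Schema, key-uniqueness and invariant checks on the input tables.

    Returns a machine-readable report: {"passed": bool, "errors": [...],
    "warnings": [...]}.  A grain weight dropping more than 3 series standard
    deviations between consecutive samples is a warning, not an error.
    """
    errors: list[str] = []
    warnings: list[str] = []

    for name, cols in _SCHEMAS.items():
        if name not in tables:
            errors.append(f"{name}: table missing")
            continue
        df = tables[name]
        missing = [c for c in cols if c not in df.columns]
        if missing:
            errors.append(f"{name}: missing columns {missing}")

    g = tables.get("grain_series")
    if g is not None and not g.empty and "plot_id" in g and "day_post_anthesis" in g:
        dup = g.duplicated(["plot_id", "day_post_anthesis"])
        if dup.any():
            errors.append(
                f"grain_series: {int(dup.sum())} duplicated (plot_id, day) rows, "
                f"e.g. {g.loc[dup, ['plot_id', 'day_post_anthesis']].iloc[0].tolist()}")
        if "grain_weight" in g:
            if (g["grain_weight"] <= 0).any():
                errors.append("grain_series: non-positive grain weights")
            for pid, grp in g.groupby("plot_id"):
                w = grp.sort_values("day_post_anthesis")["grain_weight"].to_numpy()
                d = np.diff(w)
                if len(d) < 3:
                    continue
                # robust step scale: MAD of consecutive differences
                sd = 1.4826 * np.median(np.abs(d - np.median(d)))
                if sd > 0 and np.any(d < np.median(d) - 3 * sd):
                    warnings.append(f"grain_series: {pid}: weight drop > 3 sd")

    s = tables.get("spad_series")
    if s is not None and not s.empty and "plot_id" in s:
        dup = s.duplicated(["plot_id", "day_post_anthesis"])
        if dup.any():
            errors.append(f"spad_series: {int(dup.sum())} duplicated (plot_id, day) rows")
        if "spad" in s and (s["spad"] < 0).any():
            errors.append("spad_series: negative SPAD values")

    o = tables.get("organ_n")
    if o is not None and not o.empty and {"plot_id", "stage", "organ"} <= set(o.columns):
        dup = o.duplicated(["plot_id", "stage", "organ"])
        if dup.any():
            errors.append(f"organ_n: {int(dup.sum())} duplicated (plot, stage, organ) rows")
        bad = o[(o["stage"] == "anthesis") & (o["organ"] == "grain")]
        if len(bad):
            errors.append("organ_n: grain rows at anthesis")

    y = tables.get("yields")
    if y is not None and not y.empty and "grain_yield_t_ha" in y:
        if (y["grain_yield_t_ha"] <= 0).any():
            errors.append("yields: non-positive grain yields")

    return {"passed": not errors, "errors": errors, "warnings": warnings}


# ---------------------------------------------------------------------------
# stage runners
# ---------------------------------------------------------------------------

def _series_groups(df: pd.DataFrame, level: str):
    """Yield (key_dict, sub-frame) per plot or per cultivar x rate mean series."""
    if level == "plot":
        for keys, grp in df.groupby(PLOT_KEYS, sort=True):
            yield dict(zip(PLOT_KEYS, keys)), grp
    else:
        value_col = [c for c in ("grain_weight", "spad") if c in df.columns][0]
        mean_keys = ["year", "cultivar", "n_rate_kg_ha"]
        agg = (df.groupby(mean_keys + ["day_post_anthesis"], sort=True)[value_col]
                 .mean().reset_index())
        for keys, grp in agg.groupby(mean_keys, sort=True):
            yield {**dict(zip(mean_keys, keys)), "rep": 0}, grp


def fit_grain_series(grain: pd.DataFrame, config: AnalysisConfig) -> pd.DataFrame:
    rows = []
    for keys, grp in _series_groups(grain, config.fit_level):
        grp = grp.sort_values("day_post_anthesis")
        label = "-".join(str(v) for v in keys.values())
        row = dict(keys)
        try:
            res = RichardsModel(grp["day_post_anthesis"].to_numpy(),
                                grp["grain_weight"].to_numpy(),
                                plot_id=label).fit(config.fit)
        except Exception as exc:
            logger.warning("Richards fit failed for %s: %s", label, exc)
            row.update({"converged": False, "flagged": True})
            rows.append(row)
            continue
        p, d = res.params, res.diagnostics
        row.update({"A": p.A, "B": p.B, "k": p.k, "N": p.N,
                    "rss": d.rss, "r_squared": d.r_squared,
                    "converged": d.converged, "n_restarts": d.n_restarts_used})
        try:
            tr = res.traits
            row.update({"gfr_max": tr.gfr_max, "gfr_mean": tr.gfr_mean,
                        "t1": tr.t1, "t2": tr.t2, "t3": tr.t3,
                        "t_slow": tr.t_slow, "t_fast": tr.t_fast,
                        "t_slight": tr.t_slight})
            row["flagged"] = (not d.converged) or tr.t1_nonpositive
        except TraitOrderingError as exc:
            logger.warning("trait ordering violated for %s: %s", label, exc)
            row["flagged"] = True
        rows.append(row)
    return pd.DataFrame(rows)


def fit_yield_response(yields: pd.DataFrame, config: AnalysisConfig) -> pd.DataFrame:
    rows = []
    for (year, cult), grp in yields.groupby(["year", "cultivar"], sort=True):
        res = LinearPlateauModel.from_dataframe(grp, cultivar=str(cult), year=str(year)).fit(
            grid_step=config.breakpoint_grid_step)
        f = res.fit
        rows.append({"year": year, "cultivar": cult, "intercept": f.intercept,
                     "n_r": f.n_r, "n_cs": f.n_cs, "gy_max": f.gy_max, "rss": f.rss,
                     "plateau_observed": f.plateau_observed,
                     "degenerate": f.degenerate, "negative_slope": f.negative_slope})
    return pd.DataFrame(rows)


def fit_spad_series(spad: pd.DataFrame, config: AnalysisConfig) -> pd.DataFrame:
    rows = []
    for keys, grp in _series_groups(spad, config.fit_level):
        grp = grp.sort_values("day_post_anthesis")
        label = "-".join(str(v) for v in keys.values())
        row = dict(keys)
        try:
            res = SpadDeclineModel(grp["day_post_anthesis"].to_numpy(),
                                   grp["spad"].to_numpy(), plot_id=label).fit()
        except Exception as exc:
            logger.warning("SPAD fit failed for %s: %s", label, exc)
            row["flagged"] = True
            rows.append(row)
            continue
        f = res.fit
        row.update({"a": f.a, "b": f.b, "c": f.c, "cdr": f.cdr,
                    "linear_decline_rate": f.linear_decline_rate, "rss": f.rss,
                    "flagged": not f.quadratic_available})
        rows.append(row)
    return pd.DataFrame(rows)


def compute_nitrogen_tables(
    organ: pd.DataFrame, yields: pd.DataFrame, config: AnalysisConfig
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Per-plot N budget, efficiency indices and NNI from organ snapshots."""
    budget_rows, eff_rows, nni_rows = [], [], []
    ymeans = yields.set_index(PLOT_KEYS)["grain_yield_t_ha"]
    for keys, grp in organ.groupby(PLOT_KEYS, sort=True):
        kd = dict(zip(PLOT_KEYS, keys))
        samples = [
            OrganNSample(plot_id=str(r.plot_id), stage=r.stage, organ=r.organ,
                         biomass=r.biomass_g_m2, n_conc=r.n_conc_pct / 100.0)
            for r in grp.itertuples()
        ]
        anth = {s.organ: s.n_amount for s in samples if s.stage == "anthesis"}
        matu = {s.organ: s.n_amount for s in samples if s.stage == "maturity"}
        if not anth or "grain" not in matu:
            logger.warning("incomplete organ snapshots for %s", kd)
            continue
        n_aa = sum(anth.values())
        n_gm = matu["grain"]
        n_vtm = sum(v for o, v in matu.items() if o != "grain")
        bud = translocation(n_aa, n_vtm, n_gm, organ_anthesis=anth,
                            organ_maturity={o: v for o, v in matu.items() if o != "grain"})
        budget_rows.append({**kd, "n_aa": bud.n_aa, "n_am": bud.n_am,
                            "n_vtm": bud.n_vtm, "n_gm": bud.n_gm, "nta": bud.nta,
                            "nte": bud.nte, "cnta": bud.cnta,
                            "nta_leaf": bud.nta_by_organ["leaf"],
                            "nta_stem_chaff": bud.nta_by_organ["stem"]
                            + bud.nta_by_organ["chaff"],
                            "negative_nta": bud.negative_nta})

        n_e = kd["n_rate_kg_ha"] + config.soil_n_kg_ha
        gy = ymeans.get(keys)
        if gy is not None and np.isfinite(gy):
            eff = efficiency_indices(float(gy), bud.n_am, float(n_e))
            eff_rows.append({**kd, "n_e_kg_ha": n_e, "nute": eff.nute,
                             "nupe": eff.nupe, "nue": eff.nue})

        shoot_bio = sum(s.biomass for s in samples if s.stage == "anthesis")
        if shoot_bio > 0:
            nc_act = 100.0 * n_aa / shoot_bio  # % of dry matter
            w_shoot = shoot_bio / 100.0        # g/m^2 -> t/ha
            if config.dilution_biomass_unit == "kg_ha":
                w_shoot = shoot_bio * 10.0
            res = nni(nc_act, w_shoot)
            nni_rows.append({**kd, "w_shoot": res.w_shoot, "nc_act": res.nc_act,
                             "nc_cri": res.nc_cri, "nni": res.nni})
    return pd.DataFrame(budget_rows), pd.DataFrame(eff_rows), pd.DataFrame(nni_rows)


def compute_sensitivity(
    richards_fits: pd.DataFrame,
    senescence_fits: pd.DataFrame,
    n_budget: pd.DataFrame,
    config: AnalysisConfig,
) -> pd.DataFrame:
    """OLS slope of each trait against N rate per cultivar x year.

    Treatment means over reps feed the regression (flagged fits excluded);
    the CDR column follows ``config.cdr_mode``.
    """
    frames = {}
    if not richards_fits.empty and "t_fast" in richards_fits:
        ok = richards_fits[~richards_fits.get("flagged", False).astype(bool)]
        frames["richards"] = ok
    if not senescence_fits.empty and "cdr" in senescence_fits:
        ok = senescence_fits[~senescence_fits.get("flagged", False).astype(bool)].copy()
        if config.cdr_mode == "linear":
            ok["cdr"] = ok["linear_decline_rate"]
        frames["senescence"] = ok
    if not n_budget.empty:
        frames["nitrogen"] = n_budget[~n_budget["negative_nta"].astype(bool)]

    rows = []
    for trait, source in SENSITIVITY_TRAITS.items():
        df = frames.get(source)
        if df is None or trait not in df.columns:
            continue
        means = (df.groupby(["year", "cultivar", "n_rate_kg_ha"], sort=True)[trait]
                   .mean().reset_index())
        for (year, cult), grp in means.groupby(["year", "cultivar"], sort=True):
            if grp[trait].isna().any() or len(grp) < 3:
                continue
            try:
                s = sensitivity_slope(grp["n_rate_kg_ha"], grp[trait], trait=trait,
                                      cultivar=str(cult), year=str(year))
            except ValueError:
                continue
            rows.append({"trait": trait, "cultivar": cult, "year": year,
                         "k": s.k, "b": s.b, "r_squared": s.r_squared})
    return pd.DataFrame(rows)


def compute_path(yields: pd.DataFrame) -> pd.DataFrame:
    """Pooled path decomposition of yield on GW, GPS, SPUA (long format)."""
    decomp = PathAnalysisModel(yields).fit()
    rows = []
    for i, pred in enumerate(decomp.predictors):
        row = {"response": decomp.response, "predictor": pred,
               "correlation": decomp.correlations[i],
               "direct": decomp.direct[i],
               "r_squared_single": decomp.r_squared_single[i],
               "r_squared_full": decomp.r_squared_full, "n": decomp.n}
        for j, other in enumerate(decomp.predictors):
            if j != i:
                row[f"indirect_via_{other}"] = decomp.indirect[i, j]
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# entry point
# ---------------------------------------------------------------------------

def run_analysis(
    tables: dict[str, pd.DataFrame], config: AnalysisConfig | None = None
) -> ResultBundle:
    """Run the full pipeline on in-memory tables.

    ``tables`` must hold the four input frames (grain_series, spad_series,
    organ_n, yields).  Raises :class:`ValidationError` on schema violations
    and :class:`FitFailureError` when more than ``config.max_failure_frac``
    of per-plot fits fail.
    """
    config = config or AnalysisConfig()
    report = validate_dataset(tables)
    if not report["passed"]:
        raise ValidationError("; ".join(report["errors"]))
    for w in report["warnings"]:
        logger.warning("%s", w)

    richards_fits = fit_grain_series(tables["grain_series"], config)
    senescence_fits = fit_spad_series(tables["spad_series"], config)
    n_response = fit_yield_response(tables["yields"], config)
    n_budget, efficiency, nni_table = compute_nitrogen_tables(
        tables["organ_n"], tables["yields"], config)
    sensitivity = compute_sensitivity(richards_fits, senescence_fits, n_budget, config)
    path = compute_path(tables["yields"])

    n_fits = len(richards_fits) + len(senescence_fits)
    n_failed = int(richards_fits.get("flagged", pd.Series(dtype=bool)).sum()
                   + senescence_fits.get("flagged", pd.Series(dtype=bool)).sum())
    failure_frac = n_failed / n_fits if n_fits else 0.0

    cfg_dict = {k: (asdict(v) if hasattr(v, "__dataclass_fields__") else v)
                for k, v in asdict(config).items()}
    manifest = {
        "package": "wheatnr",
        "version": __version__,
        "config": cfg_dict,
        "config_hash": hashlib.sha256(
            json.dumps(cfg_dict, sort_keys=True).encode()).hexdigest(),
        "n_plots_grain": len(richards_fits),
        "n_plots_spad": len(senescence_fits),
        "n_fits_flagged": n_failed,
        "failure_frac": failure_frac,
        "validation_warnings": report["warnings"],
    }
    if failure_frac > config.max_failure_frac:
        raise FitFailureError(
            f"{n_failed}/{n_fits} fits failed ({failure_frac:.1%} > "
            f"{config.max_failure_frac:.0%}); manifest: {manifest}")

    return ResultBundle(richards_fits, n_response, senescence_fits, n_budget,
                        efficiency, nni_table, sensitivity, path, manifest)


def run_analysis_from_paths(indir: str | Path,
                            config: AnalysisConfig | None = None) -> ResultBundle:
    """Read the four input CSVs from ``indir`` and run the pipeline."""
    indir = Path(indir)
    tables = {}
    for name in _SCHEMAS:
        p = indir / f"{name}.csv"
        if not p.exists():
            raise ValidationError(f"input file missing: {p}")
        tables[name] = pd.read_csv(p)
    return run_analysis(tables, config)
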