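"""Nitrogen accumulation, nutrition index, efficiency and translocation.

Organ-level N snapshots (stem / leaf / chaff at anthesis; plus grain at
maturity) are aggregated into a whole-plant N budget:

* total N accumulation  N_TAA = N_stem + N_chaff + N_leaf (+ N_grain)
* translocation         NTA  = N_aa - N_vtm          (g m^-2)
* translocation eff.    NTE  = 100 * NTA / N_aa      (%)
* contribution to grain CNTA = 100 * NTA / N_gm      (%)

where N_aa is aboveground N at anthesis, N_vtm vegetative N at maturity and
N_gm grain N at maturity.  CNTA is the pre-anthesis share of grain N;
100 - CNTA is the post-anthesis uptake share.

Efficiency indices relate yield and plant N to the effective N supply
N_e = fertilizer N + soil available N (kg/ha):

    NUtE = GY / N_am,   NUpE = N_am / N_e,   NUE = GY / N_e = NUtE * NUpE

with GY and N_am converted to kg/ha before the ratios (g m^-2 -> x10,
t ha^-1 -> x1000).

The N nutrition index NNI = NC_act / NC_cri compares the actual shoot N
concentration at anthesis against the critical dilution curve
NC_cri = 4.59 * W_shoot^-0.41 (N in %, shoot biomass in t/ha); NNI near 1
indicates optimal N status.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

__all__ = [
    "OrganNSample",
    "NitrogenBudget",
    "EfficiencyIndices",
    "NniResult",
    "total_n",
    "critical_n_conc",
    "nni",
    "efficiency_indices",
    "translocation",
    "g_m2_to_kg_ha",
    "kg_ha_to_g_m2",
]

STAGES = ("anthesis", "maturity")
ORGANS = ("stem", "leaf", "chaff", "grain")
VEGETATIVE_ORGANS = ("stem", "leaf", "chaff")

#: Critical dilution curve NC_cri = DILUTION_COEF * W^DILUTION_EXP, W in t/ha, N in %
DILUTION_COEF = 4.59
DILUTION_EXP = -0.41


def g_m2_to_kg_ha(x: float) -> float:
    return x * 10.0


def kg_ha_to_g_m2(x: float) -> float:
    return x / 10.0


@dataclass(frozen=True)
class OrganNSample:
    """N snapshot of one organ of one plot at one stage.

    ``n_amount`` (g N m^-2) = biomass (g m^-2) x n_conc (fraction); when all
    three are supplied they must be mutually consistent.
    """

    plot_id: str
    stage: str
    organ: str
    biomass: float
    n_conc: float
    n_amount: float | None = None

    def __post_init__(self) -> None:
        if self.stage not in STAGES:
            raise ValueError(f"unknown stage {self.stage!r}; expected one of {STAGES}")
        if self.organ not in ORGANS:
            raise ValueError(f"unknown organ {self.organ!r}; expected one of {ORGANS}")
        if self.organ == "grain" and self.stage != "maturity":
            raise ValueError("grain samples exist only at maturity")
        if self.biomass < 0 or self.n_conc < 0:
            raise ValueError("biomass and n_conc must be non-negative")
        if self.n_amount is None:
            object.__setattr__(self, "n_amount", self.biomass * self.n_conc)
        elif abs(self.n_amount - self.biomass * self.n_conc) > 1e-9:
            raise ValueError(
                f"inconsistent sample: n_amount {self.n_amount} != biomass x n_conc "
                f"{self.biomass * self.n_conc}"
            )


@dataclass(frozen=True)
class NitrogenBudget:
    """Whole-plant N budget of one plot across anthesis and maturity."""

    n_aa: float
    n_am: float
    n_vtm: float
    n_gm: float
    nta: float
    nte: float
    cnta: float
    nta_by_organ: dict[str, float] | None = None
    negative_nta: bool = False


@dataclass(frozen=True)
class EfficiencyIndices:
    """N-use efficiency partition; nue = nute * nupe holds by construction."""

    nute: float
    nupe: float
    nue: float
    n_e: float


@dataclass(frozen=True)
class NniResult:
    nc_act: float
    nc_cri: float
    w_shoot: float
    nni: float


def total_n(samples: Iterable[OrganNSample], stage: str) -> float:
    """Total N accumulation (g m^-2) at a stage: sum of organ N amounts.

    All samples must come from a single plot; duplicate organs are rejected.
    The grain term is present only at maturity.
    """
    if stage not in STAGES:
        raise ValueError(f"unknown stage {stage!r}")
    picked = [s for s in samples if s.stage == stage]
    if not picked:
        raise ValueError(f"no samples at stage {stage!r}")
    plots = {s.plot_id for s in picked}
    if len(plots) > 1:
        raise ValueError(f"samples span multiple plots: {sorted(plots)}")
    organs = [s.organ for s in picked]
    if len(set(organs)) != len(organs):
        raise ValueError(f"duplicate organ samples at {stage}: {sorted(organs)}")
    return sum(s.n_amount for s in picked)


def critical_n_conc(w_shoot: float) -> float:
    """Critical shoot N concentration (%) from the dilution curve.

    NC_cri = 4.59 * W_shoot^-0.41 with W_shoot in t/ha (dry matter).
    """
    if not w_shoot > 0:
        raise ValueError("shoot biomass must be positive")
    return DILUTION_COEF * w_shoot ** DILUTION_EXP


def nni(nc_act: float, w_shoot: float) -> NniResult:
    """N nutrition index: actual over critical shoot N concentration."""
    if not nc_act > 0:
        raise ValueError("actual N concentration must be positive")
    nc_cri = critical_n_conc(w_shoot)
    return NniResult(nc_act=nc_act, nc_cri=nc_cri, w_shoot=w_shoot, nni=nc_act / nc_cri)


def efficiency_indices(gy_t_ha: float, n_am_g_m2: float, n_e_kg_ha: float) -> EfficiencyIndices:
    """NUtE, NUpE and NUE from yield, maturity plant N and effective N supply.

    Inputs are in the units they are usually reported in (GY t/ha, N_am
    g/m^2, N_e kg/ha) and are converted to kg/ha internally.
    """
    if not (gy_t_ha > 0 and n_am_g_m2 > 0 and n_e_kg_ha > 0):
        raise ValueError("gy, n_am and n_e must all be positive")
    gy_kg = gy_t_ha * 1000.0
    n_am_kg = g_m2_to_kg_ha(n_am_g_m2)
    nute = gy_kg / n_am_kg
    nupe = n_am_kg / n_e_kg_ha
    return EfficiencyIndices(nute=nute, nupe=nupe, nue=nute * nupe, n_e=n_e_kg_ha)


def translocation(
    n_aa: float,
    n_vtm: float,
    n_gm: float,
    organ_anthesis: dict[str, float] | None = None,
    organ_maturity: dict[str, float] | None = None,
) -> NitrogenBudget:
    """N translocation quantities from stage totals (all g m^-2).

    nta = n_aa - n_vtm; nte = 100 nta / n_aa; cnta = 100 nta / n_gm.
    When per-organ anthesis/maturity N amounts are supplied the translocation
    is also split organ-wise (anthesis minus maturity, vegetative organs);
    the split sums to nta whenever the organ dictionaries are complete.
    A plot that gained vegetative N post-anthesis (n_vtm > n_aa) yields a
    negative nta carrying the ``negative_nta`` flag, not an exception.
    """
    if not n_aa > 0:
        raise ValueError("n_aa must be positive")
    if not n_gm > 0:
        raise ValueError("n_gm must be positive")
    if n_vtm < 0:
        raise ValueError("n_vtm must be non-negative")
    nta = n_aa - n_vtm
    by_organ = None
    if organ_anthesis is not None and organ_maturity is not None:
        by_organ = {
            org: organ_anthesis.get(org, 0.0) - organ_maturity.get(org, 0.0)
            for org in VEGETATIVE_ORGANS
        }
    return NitrogenBudget(
        n_aa=n_aa,
        n_am=n_vtm + n_gm,
        n_vtm=n_vtm,
        n_gm=n_gm,
        nta=nta,
        nte=100.0 * nta / n_aa,
        cnta=100.0 * nta / n_gm,
        nta_by_organ=by_organ,
        negative_nta=nta < 0,
    )
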