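"""Nitrogen budget arithmetic, dilution curve, efficiency identities."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from wheatnr import (
    OrganNSample,
    critical_n_conc,
    efficiency_indices,
    nni,
    total_n,
    translocation,
)

positive = st.floats(0.1, 100.0, allow_nan=False)


def sample(organ, n_amount, stage="anthesis", plot="p1"):
    # biomass chosen so biomass * conc reproduces the requested amount
    return OrganNSample(plot, stage, organ, biomass=n_amount * 50.0, n_conc=0.02)


class TestTotalN:
    def test_anthesis_sum(self):
        samples = [sample("stem", 5.0), sample("leaf", 3.0), sample("chaff", 2.0)]
        assert total_n(samples, "anthesis") == pytest.approx(10.0)

    def test_maturity_sum_includes_grain(self):
        samples = [sample("grain", 12.0, "maturity"), sample("stem", 3.0, "maturity"),
                   sample("leaf", 1.0, "maturity"), sample("chaff", 1.0, "maturity")]
        assert total_n(samples, "maturity") == pytest.approx(17.0)

    def test_empty_set_rejected(self):
        with pytest.raises(ValueError):
            total_n([], "anthesis")

    def test_duplicate_organ_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            total_n([sample("stem", 5.0), sample("stem", 4.0)], "anthesis")

    def test_grain_only_at_maturity(self):
        with pytest.raises(ValueError):
            OrganNSample("p", "anthesis", "grain", 100.0, 0.02)

    def test_inconsistent_amount_rejected(self):
        with pytest.raises(ValueError, match="inconsistent"):
            OrganNSample("p", "anthesis", "stem", 100.0, 0.02, n_amount=5.0)


class TestDilutionCurve:
    def test_unit_biomass_gives_coefficient(self):
        assert critical_n_conc(1.0) == 4.59

    def test_power_law(self):
        assert critical_n_conc(2.0) == pytest.approx(4.59 * 2 ** -0.41, rel=1e-12)

    def test_monotone_decreasing(self):
        w = np.linspace(0.5, 15, 40)
        vals = [critical_n_conc(x) for x in w]
        assert np.all(np.diff(vals) < 0)

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            critical_n_conc(0.0)


class TestNni:
    def test_optimal_ratio(self):
        assert nni(4.59, 1.0).nni == pytest.approx(1.0)

    def test_halving(self):
        assert nni(2.295, 1.0).nni == pytest.approx(0.5)

    def test_direct_evaluation(self):
        r = nni(3.0, 5.0)
        assert r.nni == pytest.approx(3.0 / (4.59 * 5 ** -0.41), rel=1e-12)


class TestEfficiency:
    def test_printed_formula_arithmetic(self):
        e = efficiency_indices(6.0, 18.0, 200.0)  # 6 t/ha, 180 kg/ha N, 200 kg/ha supply
        assert e.nute == pytest.approx(6000 / 180, rel=1e-9)
        assert e.nupe == pytest.approx(0.9, rel=1e-9)
        assert e.nue == pytest.approx(30.0, rel=1e-9)

    def test_unit_uptake_when_plant_n_equals_supply(self):
        e = efficiency_indices(5.0, 20.0, 200.0)
        assert e.nupe == pytest.approx(1.0)

    @given(gy=positive, nam=positive, ne=positive)
    @settings(max_examples=200, deadline=None)
    def test_product_identity(self, gy, nam, ne):
        e = efficiency_indices(gy, nam, ne)
        assert abs(e.nue - e.nute * e.nupe) < 1e-9 * max(1.0, e.nue)


class TestTranslocation:
    def test_no_translocation(self):
        b = translocation(15.0, 15.0, 12.0)
        assert b.nta == 0.0 and b.nte == 0.0

    def test_printed_arithmetic(self):
        b = translocation(15.0, 5.0, 12.0)
        assert b.nta == pytest.approx(10.0)
        assert b.nte == pytest.approx(100 * 10 / 15)
        assert b.cnta == pytest.approx(100 * 10 / 12)

    def test_maturity_total_identity(self):
        b = translocation(15.0, 5.0, 12.0)
        assert b.n_am == pytest.approx(b.n_vtm + b.n_gm, abs=1e-12)

    def test_grain_origin_split_mass_balance(self):
        # pre-anthesis share = CNTA; the remainder is post-anthesis uptake
        rng = np.random.default_rng(17)
        for _ in range(200):
            n_aa = rng.uniform(5, 25)
            f_trans = rng.uniform(0.3, 0.8)
            puf = rng.uniform(0.0, 0.5)
            nta = f_trans * n_aa
            n_gm = nta / (1 - puf)
            b = translocation(n_aa, n_aa - nta, n_gm)
            post_uptake = n_gm - nta
            assert b.n_gm == pytest.approx(b.nta + post_uptake, abs=1e-9)
            assert b.cnta == pytest.approx(100 * (1 - puf), abs=1e-9)
            assert 0 <= b.nte <= 100 and 0 <= b.cnta <= 100

    def test_negative_nta_flagged_not_raised(self):
        b = translocation(10.0, 12.0, 5.0)
        assert b.negative_nta and b.nta == pytest.approx(-2.0)

    def test_per_organ_split_sums_to_total(self):
        anth = {"stem": 6.0, "leaf": 4.0, "chaff": 2.0}
        matu = {"stem": 3.0, "leaf": 2.5, "chaff": 1.5}
        b = translocation(12.0, 7.0, 10.0, organ_anthesis=anth, organ_maturity=matu)
        assert sum(b.nta_by_organ.values()) == pytest.approx(b.nta, abs=1e-12)
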