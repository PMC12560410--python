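"""Double-log binding fits, van't Hoff thermodynamics, force classification."""

import math

import numpy as np
import pytest

from bsabind import (
    BindingForce,
    TitrationSeries,
    classify_forces,
    double_log_fit,
    gibbs_from_enthalpy,
    gibbs_from_ka,
    thermo_summary,
    vant_hoff_fit,
)
from bsabind.binding import BindingResult
from bsabind.datatypes import GAS_CONSTANT_R

from conftest import TABLE_DG_KJ, TABLE_DH_KJ, TABLE_DS, TABLE_KA

CONC_M = np.array([30.0, 60.0, 90.0, 120.0, 150.0, 180.0]) * 1e-6


def _static_series(ka, f0=1000.0, t=295.0):
    f = f0 / (1.0 + ka * CONC_M)
    return TitrationSeries(
        temperature_K=t, quencher_conc=CONC_M.tolist(), intensity=f.tolist(), f0=f0
    )


class TestDoubleLogFit:
    def test_noiseless_one_to_one_model_recovered_exactly(self):
        # for the static 1:1 model, (F0-F)/F = Ka [Q] identically, so the
        # double-log fit must return n = 1 and Ka to numerical precision
        res = double_log_fit(_static_series(2e4))
        assert res.n_sites == pytest.approx(1.0, rel=1e-9)
        assert res.ka == pytest.approx(2e4, rel=1e-9)
        assert res.ka == pytest.approx(10 ** res.log10_ka, rel=1e-12)

    def test_squared_law_doubles_the_slope(self):
        ka = 5000.0
        f0 = 1000.0
        f = f0 / (1.0 + (ka * CONC_M) ** 2)
        s = TitrationSeries(
            temperature_K=295, quencher_conc=CONC_M.tolist(), intensity=f.tolist(), f0=f0
        )
        res = double_log_fit(s)
        assert res.n_sites == pytest.approx(2.0, rel=1e-9)

    def test_intercept_maps_to_published_ka(self):
        # data manufactured to have intercept exactly 4.1174: the fitted Ka
        # must match the published 13.103e3 L/mol at the printed precision
        x = np.log10(CONC_M)
        y = 4.1174 + 1.086 * x
        f0 = 1000.0
        f = f0 / (1.0 + 10.0 ** y)
        s = TitrationSeries(
            temperature_K=295, quencher_conc=CONC_M.tolist(), intensity=f.tolist(), f0=f0
        )
        res = double_log_fit(s)
        assert res.log10_ka == pytest.approx(4.1174, abs=1e-9)
        assert res.ka == pytest.approx(13103.0, abs=1.5)

    def test_unquenched_points_are_dropped_with_warning(self, caplog):
        f0 = 1000.0
        f = f0 / (1.0 + 2e4 * CONC_M)
        f[:2] = [f0 + 5.0, f0]  # two unusable points
        s = TitrationSeries(
            temperature_K=295, quencher_conc=CONC_M.tolist(), intensity=f.tolist(), f0=f0
        )
        with caplog.at_level("WARNING", logger="bsabind.binding"):
            res = double_log_fit(s)
        assert "dropped 2" in caplog.text
        assert res.fit.n_points == 4

    def test_fewer_than_three_usable_points_error(self):
        s = TitrationSeries(
            temperature_K=295,
            quencher_conc=CONC_M.tolist(),
            intensity=[1000.0] * 6,
            f0=1000.0,
        )
        with pytest.raises(ValueError, match="fewer than 3"):
            double_log_fit(s)

    def test_stoichiometry_annotation(self):
        res = double_log_fit(_static_series(2e4))
        assert res.is_unity_stoichiometry()


class TestVantHoffFit:
    def test_published_table_reproduced(self):
        dh, ds, fit = vant_hoff_fit(sorted(TABLE_KA.items()))
        # printed Ka values are rounded, so 0.5% agreement is expected
        assert dh / 1000 == pytest.approx(TABLE_DH_KJ, rel=0.005)
        assert ds == pytest.approx(TABLE_DS, rel=0.005)
        assert fit.r > 0.99  # exothermic binding: ln Ka rises with 1/T

    def test_flat_line_gives_zero_enthalpy(self):
        dh, ds, _ = vant_hoff_fit([(290.0, 5000.0), (300.0, 5000.0)])
        assert dh == pytest.approx(0.0, abs=1e-9)
        assert ds == pytest.approx(GAS_CONSTANT_R * math.log(5000.0), rel=1e-12)

    def test_generator_round_trip_exact(self):
        dh_true, ds_true = -40000.0, -80.0
        pts = [
            (t, math.exp(-dh_true / (GAS_CONSTANT_R * t) + ds_true / GAS_CONSTANT_R))
            for t in (285.0, 290.0, 295.0, 303.0, 308.0)
        ]
        dh, ds, _ = vant_hoff_fit(pts)
        assert dh == pytest.approx(dh_true, rel=1e-9)
        assert ds == pytest.approx(ds_true, rel=1e-9)

    @pytest.mark.parametrize(
        "points",
        [
            [(295.0, 1e4), (295.0, 2e4), (300.0, 3e4)],  # duplicate T
            [(295.0, 1e4), (300.0, -1.0), (305.0, 3e4)],  # non-positive Ka
        ],
    )
    def test_invalid_inputs(self, points):
        with pytest.raises(ValueError):
            vant_hoff_fit(points)


class TestGibbs:
    @pytest.mark.parametrize(
        "t,ka",
        [(285.0, 24.171e3), (295.0, 13.103e3), (308.0, 4.639e3)],
    )
    def test_published_delta_g(self, t, ka):
        assert gibbs_from_ka(ka, t) / 1000 == pytest.approx(TABLE_DG_KJ[t], abs=5e-4)

    def test_unit_ka_gives_zero(self):
        assert gibbs_from_ka(1.0, 310.0) == 0.0

    def test_enthalpy_route(self):
        # dH - T dS with the published parameters at 285 K; note this route
        # differs from -RT ln Ka by ~0.1 kJ/mol because the printed per-T Ka
        # do not sit exactly on the van't Hoff line
        g = gibbs_from_enthalpy(-52434.0, -99.63, 285.0)
        assert g == pytest.approx(-24039.45, abs=1e-6)
        assert gibbs_from_enthalpy(0.0, 0.0, 300.0) == 0.0
        assert gibbs_from_enthalpy(-10000.0, 0.0, 300.0) == -10000.0

    def test_routes_coincide_on_the_vant_hoff_line(self):
        dh, ds = -45000.0, -90.0
        for t in (285.0, 300.0):
            ka = math.exp(-dh / (GAS_CONSTANT_R * t) + ds / GAS_CONSTANT_R)
            assert gibbs_from_ka(ka, t) == pytest.approx(
                gibbs_from_enthalpy(dh, ds, t), rel=1e-12
            )

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            gibbs_from_ka(0.0, 300.0)
        with pytest.raises(ValueError):
            gibbs_from_ka(100.0, -1.0)


class TestClassifyForces:
    @pytest.mark.parametrize(
        "dh,ds,expected",
        [
            (-52434.0, -99.63, BindingForce.hbond_vdw),
            (5000.0, 30.0, BindingForce.hydrophobic),
            (-5000.0, 30.0, BindingForce.electrostatic),
            (0.0, -10.0, BindingForce.indeterminate),
            (-5000.0, 0.0, BindingForce.indeterminate),
        ],
    )
    def test_sign_rules(self, dh, ds, expected):
        assert classify_forces(dh, ds) is expected


class TestThermoSummary:
    def test_full_workup_from_published_constants(self, config):
        results = [
            BindingResult(
                temperature_K=t,
                log10_ka=math.log10(ka),
                ka=ka,
                n_sites=1.07,
                fit=_dummy_fit(),
            )
            for t, ka in sorted(TABLE_KA.items())
        ]
        th = thermo_summary(results, config)
        assert th.force_call is BindingForce.hbond_vdw
        assert th.spontaneous
        # 1e-3 band: the 290 K table value is truncated (-23.546 vs -23.5468)
        for t, g_kj in TABLE_DG_KJ.items():
            assert th.delta_G_by_T[t] / 1000 == pytest.approx(g_kj, abs=1e-3)


def _dummy_fit():
    from bsabind.fitting import linear_fit

    return linear_fit([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
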