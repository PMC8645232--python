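"""Von Mises mixture fitting and ten-model AICc selection."""

import math

import numpy as np
import pytest
from scipy import special

from emlenkit import (
    MODEL_IDS,
    OrientationModel,
    fit_model,
    model_loglik,
    select_models,
    vm_log_density,
)
from emlenkit.models import get_spec
from emlenkit.simulate import sample_von_mises

I0_AT_1 = 1.2660658777520084  # Bessel-table value of I0(1)


class TestVonMisesDensity:
    def test_uniform_limit(self):
        val = vm_log_density(123.0, 45.0, 0.0)
        assert val == pytest.approx(-math.log(2 * math.pi), abs=1e-12)

    def test_mode_value_against_bessel_table(self):
        val = vm_log_density(30.0, 30.0, 1.0)
        assert val == pytest.approx(1.0 - math.log(2 * math.pi * I0_AT_1), abs=1e-10)

    def test_symmetry_about_mode(self):
        for d in (10, 45, 90, 170):
            assert vm_log_density(100 + d, 100, 2.5) == pytest.approx(
                vm_log_density(100 - d, 100, 2.5)
            )

    def test_negative_kappa_rejected(self):
        with pytest.raises(ValueError):
            vm_log_density(0, 0, -1)

    def test_integrates_to_one(self):
        th = np.linspace(0, 360, 20_001)
        dens = np.exp(vm_log_density(th, 77.0, 5.0))
        integral = np.trapezoid(dens, np.deg2rad(th))
        assert integral == pytest.approx(1.0, abs=1e-6)


class TestLogLikelihood:
    def test_uniform_closed_form(self):
        data = list(range(0, 100, 10))
        val = model_loglik((0, 0, 0, 0, 0.5), "M1", data)
        assert val == pytest.approx(-10 * math.log(2 * math.pi), abs=1e-12)

    def test_unimodal_with_zero_kappa_nests_uniform(self):
        data = [10.0, 80.0, 200.0]
        m1 = model_loglik((0, 0, 0, 0, 0.5), "M1", data)
        m2a = model_loglik((150.0, 0.0, 150.0, 0.0, 1.0), "M2A", data)
        assert m2a == pytest.approx(m1, abs=1e-12)

    def test_hand_summed_mixture(self):
        # term-by-term computation with scipy's plain Bessel I0
        data = [20.0, 140.0, 300.0]
        q1, k1, q2, k2, lam = 30.0, 2.0, 210.0, 1.0, 0.7

        def vm(theta, q, k):
            return math.exp(k * math.cos(math.radians(theta - q))) / (
                2 * math.pi * special.i0(k)
            )

        expected = sum(
            math.log(lam * vm(t, q1, k1) + (1 - lam) * vm(t, q2, k2)) for t in data
        )
        got = model_loglik((q1, k1, q2, k2, lam), "M5B", data)
        assert got == pytest.approx(expected, abs=1e-10)

    def test_invalid_lambda_rejected(self):
        with pytest.raises(ValueError):
            model_loglik((0, 1, 0, 1, 1.5), "M5B", [10.0])


class TestFitting:
    def test_tight_cluster_forces_unimodal_optimum(self):
        rng = np.random.default_rng(0)
        data = sample_von_mises(40, 150, 80, rng)
        fit = fit_model(data, "M2A", seed=0)
        assert abs((fit.q1 - 150 + 180) % 360 - 180) < 2.0
        assert fit.k1 > 20

    def test_uniform_model_closed_form(self):
        fit = fit_model([1.0, 2.0, 3.0, 100.0, 200.0, 300.0], "M1")
        assert fit.loglik == pytest.approx(-6 * math.log(2 * math.pi))
        assert fit.aicc == pytest.approx(-2 * fit.loglik)

    def test_parameter_recovery(self):
        rng = np.random.default_rng(123)
        data = sample_von_mises(200, 152, 2, rng)
        fit = fit_model(data, "M2A", seed=1)
        assert abs((fit.q1 - 152 + 180) % 360 - 180) < 10.0
        assert 1.5 <= fit.k1 <= 2.6

    def test_too_small_sample_is_skipped(self):
        fit = fit_model([10.0, 20.0, 30.0, 40.0, 50.0], "M5B")
        assert fit.status == "skipped_small_n"


@pytest.fixture(scope="module")
def selection_cases():
    rng = np.random.default_rng(321)
    uniform = rng.uniform(0, 360, 60)
    unimodal = sample_von_mises(60, 152, 3, rng)
    axial = np.concatenate(
        [sample_von_mises(30, 152, 3, rng), sample_von_mises(30, 332, 3, rng)]
    )
    skew_bimodal = np.concatenate(
        [sample_von_mises(40, 100, 4, rng), sample_von_mises(20, 250, 2, rng)]
    )
    return {
        "uniform": uniform,
        "unimodal": unimodal,
        "axial": axial,
        "bimodal": skew_bimodal,
    }


class TestSelection:
    def test_weights_sum_and_delta(self, selection_cases):
        sel = select_models(selection_cases["unimodal"], seed=0)
        w = [f.weight for f in sel.fits if f.status == "ok"]
        assert sum(w) == pytest.approx(1.0, abs=1e-9)
        assert sel.best.delta_aicc == 0.0
        assert len(sel.fits) == 10
        assert [f.model_id for f in sel.fits if f.status == "ok"] == sorted(
            (f.model_id for f in sel.fits if f.status == "ok"),
            key=lambda m: next(f.aicc for f in sel.fits if f.model_id == m),
        )

    def test_nesting_invariant(self, selection_cases):
        for name, data in selection_cases.items():
            sel = select_models(data, seed=2)
            lnl = {f.model_id: f.loglik for f in sel.fits}
            top = lnl["M5B"]
            for mid in MODEL_IDS:
                assert top >= lnl[mid] - 1e-6, (name, mid)

    def test_rotation_equivariance(self, selection_cases):
        data = selection_cases["unimodal"]
        delta = 77.0
        a = select_models(data, seed=5)
        b = {f.model_id: f for f in select_models((data + delta) % 360, seed=5).fits}
        for fa in a.fits:
            fb = b[fa.model_id]
            assert fb.loglik == pytest.approx(fa.loglik, abs=1e-3)
            assert fb.aicc == pytest.approx(fa.aicc, abs=1e-2)
            if fa.K >= 2 and fa.k1 > 0.2:
                d = (fb.q1 - fa.q1 - delta) % 360
                d = min(d, 360 - d)
                symmetric_axial = (
                    abs(fa.lam - 0.5) < 1e-3
                    and abs(fa.k1 - fa.k2) < 1e-3
                    and abs((fa.q2 - fa.q1) % 360 - 180) < 1e-3
                )
                if symmetric_axial:  # q1 and q1+180 label the same axis
                    d = min(d, abs(d - 180.0))
                assert d < 2.0

    def test_multi_start_determinism(self, selection_cases):
        data = selection_cases["axial"]
        t1 = select_models(data, seed=9).table()
        t2 = select_models(data, seed=9).table()
        assert t1.equals(t2)

    def test_axial_data_prefers_axial_family(self, selection_cases):
        sel = select_models(selection_cases["axial"], seed=3)
        assert sel.best.model_id in {"M3A", "M3B", "M4A", "M4B", "M5A", "M5B"}

    def test_clustered_data_prefers_unimodal_family(self, selection_cases):
        sel = select_models(selection_cases["unimodal"], seed=3)
        assert sel.best.model_id in {"M2A", "M2B", "M2C"}

    def test_small_sample_skips_are_flagged(self):
        with pytest.warns(UserWarning, match="skipped"):
            sel = select_models([10.0, 50.0, 100.0, 150.0, 200.0, 250.0], seed=0)
        skipped = {f.model_id for f in sel.fits if f.status == "skipped_small_n"}
        assert "M5B" in skipped
        ok_w = [f.weight for f in sel.fits if f.status == "ok"]
        assert sum(ok_w) == pytest.approx(1.0)

    def test_table_schema(self, selection_cases):
        df = select_models(selection_cases["uniform"], seed=1).table()
        assert list(df.columns) == [
            "model_id", "K", "q1_deg", "k1", "q2_deg", "k2", "lambda",
            "lnL", "AICc", "delta_AICc", "weight", "status",
        ]

    def test_aicc_formula(self, selection_cases):
        sel = select_models(selection_cases["unimodal"], seed=0)
        n = 60
        for f in sel.fits:
            if f.status != "ok":
                continue
            expected = -2 * f.loglik + 2 * f.K + 2 * f.K * (f.K + 1) / (n - f.K - 1)
            assert f.aicc == pytest.approx(expected, abs=1e-9)


def test_spec_parameter_counts():
    assert {mid: get_spec(mid).K for mid in MODEL_IDS} == {
        "M1": 0, "M2A": 2, "M2B": 2, "M2C": 3, "M3A": 2,
        "M3B": 3, "M4A": 3, "M4B": 4, "M5A": 4, "M5B": 5,
    }


def test_statsmodels_style_entry_points(selection_cases):
    m = OrientationModel(selection_cases["unimodal"])
    fit = m.fit("M2A", seed=0)
    assert "M2A" in fit.summary()
    res = m.select(seed=0)
    assert "AICc" in res.summary()
    assert res.best.model_id == res.fits[0].model_id
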