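import numpy as np
import pytest

from gdhl.kernels import numerical_kernel
from gdhl.rule import (
    COMPONENTS,
    GDHLCoefficients,
    component_update,
    instantaneous_update,
    integrate,
    preset,
)
from gdhl.signals import EventSpec, Signal, TimeGrid, cosine_event, derivative


def random_signal_pair(rng, n=200, dt=0.01):
    vals = rng.uniform(0.0, 1.0, size=(2, n))
    return Signal(0.0, dt, vals[0]), Signal(0.0, dt, vals[1])


class TestPresets:
    def test_kosko_values(self):
        c = preset("kosko")
        assert (c.sigma_pp, c.sigma_pn, c.sigma_np, c.sigma_nn) == (1, -1, -1, 1)
        assert (c.eta_sp, c.eta_sn, c.eta_ps, c.eta_ns) == (0, 0, 0, 0)

    @pytest.mark.parametrize(
        "name,expected",
        [
            ("porr_worgotter", {"eta_sp": 1.0, "eta_sn": -1.0}),
            ("causal", {"eta_sp": 1.0, "eta_sn": -1.0}),
            ("anticausal", {"eta_sn": 1.0, "eta_ns": -1.0}),
            ("coincidence", {"sigma_pp": 1.0, "sigma_nn": 1.0,
                             "sigma_pn": -1.0, "sigma_np": -1.0}),
            ("flat_at_zero", {"sigma_pn": -1.0, "sigma_np": 1.0}),
            ("hebb", {"sigma_pp": 1.0, "sigma_nn": 1.0}),
        ],
    )
    def test_named_coefficient_sets(self, name, expected):
        d = preset(name).as_dict()
        for key, val in expected.items():
            assert d.pop(key) == val
        d.pop("rate")
        assert all(v == 0.0 for v in d.values())

    def test_unknown_preset(self):
        with pytest.raises(KeyError):
            preset("oja")


class TestInstantaneousUpdate:
    def test_kosko_is_derivative_product(self):
        c = preset("kosko")
        assert instantaneous_update(0.5, 1.0, 0.5, 1.0, c) == pytest.approx(1.0)
        assert instantaneous_update(0.5, 1.0, 0.5, -1.0, c) == pytest.approx(-1.0)

    def test_zero_coefficients_give_zero(self, rng):
        c = GDHLCoefficients()
        u1, du1, u2, du2 = rng.uniform(-1, 1, size=4)
        assert instantaneous_update(abs(u1), du1, abs(u2), du2, c) == 0.0

    def test_negative_activation_rejected(self):
        with pytest.raises(ValueError, match="nonnegative"):
            instantaneous_update(-0.1, 0.0, 0.5, 0.0, preset("kosko"))

    def test_component_sum_reconstructs_update(self, rng):
        # linearity: the rule is the coefficient-weighted sum of components
        c = preset("kosko")
        for _ in range(20):
            u1, u2 = rng.uniform(0, 1, size=2)
            du1, du2 = rng.uniform(-1, 1, size=2)
            total = sum(
                c.coefficient(k) * component_update(k, u1, du1, u2, du2)
                for k in COMPONENTS
            )
            assert instantaneous_update(u1, du1, u2, du2, c) == pytest.approx(
                c.rate * total
            )


class TestComponentUpdate:
    def test_pp_product(self):
        assert component_update("pp", 0.0, 2.0, 0.0, 3.0) == 6.0

    def test_ps_zero_on_negative_derivative(self):
        assert component_update("ps", 0.0, -1.0, 5.0, 0.0) == 0.0

    def test_components_nonnegative(self, rng):
        for _ in range(50):
            u1, u2 = rng.uniform(0, 1, size=2)
            du1, du2 = rng.uniform(-1, 1, size=2)
            for k in COMPONENTS:
                assert component_update(k, u1, du1, u2, du2) >= 0

    def test_unknown_component(self):
        with pytest.raises(KeyError):
            component_update("ss", 1, 1, 1, 1)


class TestLinearity:
    def test_coefficient_additivity_and_scaling(self, rng):
        u1, u2 = 0.4, 0.9
        du1, du2 = 0.3, -0.7
        vals = rng.uniform(-1, 1, size=(2, 8))
        c1 = GDHLCoefficients(*vals[0])
        c2 = GDHLCoefficients(*vals[1])
        csum = GDHLCoefficients(*(vals[0] + vals[1]))
        assert instantaneous_update(u1, du1, u2, du2, csum) == pytest.approx(
            instantaneous_update(u1, du1, u2, du2, c1)
            + instantaneous_update(u1, du1, u2, du2, c2)
        )
        scaled = c1.scaled(3.5)
        assert instantaneous_update(u1, du1, u2, du2, scaled) == pytest.approx(
            3.5 * instantaneous_update(u1, du1, u2, du2, c1)
        )


class TestIntegrate:
    def test_grid_mismatch_rejected(self):
        s1 = Signal(0.0, 0.01, np.ones(100))
        s2 = Signal(0.0, 0.02, np.ones(100))
        with pytest.raises(ValueError, match="grid"):
            integrate(s1, s2, preset("kosko"))

    def test_disjoint_events_no_update(self):
        grid = TimeGrid(0.0, 0.001, 4001)
        s1 = cosine_event(EventSpec(0.5, 0.25, 1.0), grid)
        s2 = cosine_event(EventSpec(3.0, 0.25, 1.0), grid)
        for name in ("kosko", "porr_worgotter", "coincidence"):
            assert integrate(s1, s2, preset(name)).total_dw == 0.0

    def test_porr_worgotter_self_pairing_vanishes(self, grid, event):
        # integral of u * du over a complete event is (1/2) d(u^2) = 0
        s = cosine_event(event, grid)
        traj = integrate(s, s, preset("porr_worgotter"))
        assert abs(traj.total_dw) < 1e-10

    def test_coincidence_maximal_at_zero_delay(self, event):
        curve = numerical_kernel(
            event, preset("coincidence"), np.linspace(-1, 1, 41), dt=0.002
        )
        i0 = np.argmin(np.abs(curve.delta_ts))
        assert curve.dws[i0] > 0
        assert np.argmax(curve.dws) == i0

    def test_weight_is_running_sum(self, rng):
        s1, s2 = random_signal_pair(rng)
        traj = integrate(s1, s2, preset("kosko"), w0=1.5)
        np.testing.assert_allclose(
            traj.w, 1.5 + np.cumsum(traj.wdot) * s1.dt, rtol=1e-12
        )
        assert traj.total_dw == pytest.approx(np.sum(traj.wdot) * s1.dt)

    def test_time_translation_invariance(self, rng):
        s1, s2 = random_signal_pair(rng)
        shifted = integrate(
            Signal(5.0, s1.dt, s1.values),
            Signal(5.0, s2.dt, s2.values),
            preset("kosko"),
        )
        assert shifted.total_dw == pytest.approx(
            integrate(s1, s2, preset("kosko")).total_dw
        )


class TestEquivalences:
    def test_kosko_equals_derivative_product_pointwise(self, rng):
        c = preset("kosko")
        for _ in range(10):
            s1, s2 = random_signal_pair(rng)
            du1 = derivative(s1).values
            du2 = derivative(s2).values
            wdot = integrate(s1, s2, c).wdot
            np.testing.assert_allclose(wdot, du1 * du2, atol=1e-12)

    def test_porr_worgotter_equals_u1_du2_pointwise(self, rng):
        c = preset("porr_worgotter")
        for _ in range(10):
            s1, s2 = random_signal_pair(rng)
            du2 = derivative(s2).values
            wdot = integrate(s1, s2, c).wdot
            np.testing.assert_allclose(wdot, s1.values * du2, atol=1e-12)


class TestSerialisation:
    def test_json_round_trip(self, tmp_path, rng):
        c = GDHLCoefficients(*rng.uniform(-1, 1, size=8), rate=0.5)
        path = tmp_path / "coeffs.json"
        c.to_json(path)
        assert GDHLCoefficients.from_json(path) == c

    def test_from_components_and_lookup(self):
        c = GDHLCoefficients.from_components({"sp": 0.66, "ns": -0.6})
        assert c.coefficient("sp") == 0.66
        assert c.coefficient("ns") == -0.6
        assert c.coefficient("pp") == 0.0
        with pytest.raises(KeyError):
            c.coefficient("ss")
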