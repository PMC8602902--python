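"""Transform family correctness: endpoints, forward-map residuals,
monotonicity, inverses, and parameter-bound enforcement."""

import numpy as np
import pytest

from cytogate import transforms as tr
from cytogate.exceptions import InvalidParams, NotInvertible, UnknownChannel

T, W, M = 1000.0, 1.0, 4.0


class TestClosedForms:
    def test_linear_endpoints(self):
        spec = tr.linear(1000, 0)
        assert tr.apply_closed_form(1000.0, spec) == 1.0
        assert tr.apply_closed_form(0.0, spec) == 0.0
        spec_a = tr.linear(1000, 100)
        assert tr.apply_closed_form(-100.0, spec_a) == 0.0

    def test_log_endpoints_and_sentinel(self):
        spec = tr.log(10000, 4)
        assert tr.apply_closed_form(10000.0, spec) == pytest.approx(1.0)
        assert tr.apply_closed_form(1.0, spec) == pytest.approx(0.0)
        out = tr.apply_closed_form(np.array([-5.0, 0.0, 10000.0]), spec)
        assert np.isneginf(out[0]) and np.isneginf(out[1])
        assert out[2] == pytest.approx(1.0)

    def test_asinh_endpoints(self):
        spec = tr.asinh(1000, 4, 0)
        assert tr.apply_closed_form(0.0, spec) == 0.0
        assert tr.apply_closed_form(1000.0, spec) == pytest.approx(1.0)

    @pytest.mark.parametrize("spec", [
        tr.linear(5000, 10), tr.log(262144, 4.5), tr.asinh(262144, 4.5, 1.0)])
    def test_closed_form_inverse_roundtrip(self, spec):
        x = np.linspace(1.0, spec.T, 257)
        y = tr.apply_closed_form(x, spec)
        back = tr.invert_transform(y, spec)
        assert np.allclose(back, x, rtol=1e-9)


class TestLogicle:
    def test_top_of_scale_maps_to_one(self):
        assert tr.apply_logicle(1000.0, tr.logicle(1000, 0.5, 4.5, 0)) == \
            pytest.approx(1.0, abs=1e-9)

    def test_zero_maps_to_linear_region_centre(self):
        # with A=0, data zero sits W/M up the scale
        y = tr.apply_logicle(0.0, tr.logicle(1000, 1, 4, 0))
        assert y == pytest.approx(0.25, abs=1e-9)

    def test_forward_map_residual_on_grid(self):
        spec = tr.logicle(T, W, M, 0)
        x = np.linspace(-0.2 * T, T, 1000)
        y = tr.apply_logicle(x, spec)
        residual = np.max(np.abs(tr.invert_transform(y, spec) - x))
        assert residual <= 1e-9 * T

    def test_strictly_monotone(self):
        spec = tr.logicle(262144, 0.5, 4.5, 0.2)
        x = np.linspace(-50000, 262144, 5000)
        assert np.all(np.diff(tr.apply_logicle(x, spec)) > 0)

    def test_log_limit_at_w_zero(self):
        # with no linear region the logicle converges to flog in the
        # upper decades (top two decades checked)
        spec = tr.logicle(10000, 0, 4.5, 0)
        flog = tr.log(10000, 4.5)
        x = np.logspace(2, 4, 200)
        diff = np.abs(tr.apply_logicle(x, spec) - tr.apply_closed_form(x, flog))
        assert np.max(diff) <= 1e-6

    @pytest.mark.parametrize("bad", [
        dict(T=-1, W=0.5, M=4.5, A=0),
        dict(T=1000, W=-0.1, M=4.5, A=0),
        dict(T=1000, W=3.0, M=4.5, A=0),     # W > M/2
        dict(T=1000, W=0.5, M=4.5, A=4.0),   # A > M - 2W
        dict(T=1000, W=0.5, M=4.5, A=-1.0),  # A < -W
    ])
    def test_parameter_bounds_raise_before_compute(self, bad):
        with pytest.raises(InvalidParams):
            tr.apply_logicle(np.array([1.0]), tr.logicle(**bad))


class TestHyperlog:
    def test_top_of_scale_maps_to_one(self):
        assert tr.apply_hyperlog(1000.0, tr.hyperlog(1000, 1, 4, 0)) == \
            pytest.approx(1.0, abs=1e-9)

    def test_odd_symmetry_about_zero(self):
        spec = tr.hyperlog(1000, 1, 4, 0)
        x = np.linspace(0.0, 900.0, 200)
        centre = tr.apply_hyperlog(0.0, spec)
        lhs = tr.apply_hyperlog(-x, spec) + tr.apply_hyperlog(x, spec)
        assert np.allclose(lhs, 2 * centre, atol=1e-12)

    def test_forward_map_residual_on_grid(self):
        spec = tr.hyperlog(T, W, M, 0)
        x = np.linspace(-0.2 * T, T, 1000)
        y = tr.apply_hyperlog(x, spec)
        assert np.max(np.abs(tr.invert_transform(y, spec) - x)) <= 1e-9 * T

    def test_w_zero_rejected(self):
        with pytest.raises(InvalidParams):
            tr.apply_hyperlog(np.array([1.0]), tr.hyperlog(1000, 0, 4, 0))


class TestFlowJoBiex:
    def test_max_value_maps_to_one(self):
        spec = tr.flowjo_biex()
        assert tr.apply_flowjo_biex(262144.0, spec) == pytest.approx(1.0)

    def test_monotone_on_dense_grid(self):
        spec = tr.flowjo_biex()
        x = np.linspace(-100000, 262144, 10000)
        assert np.all(np.diff(tr.apply_flowjo_biex(x, spec)) > 0)

    def test_lut_inverse_roundtrip(self):
        spec = tr.flowjo_biex()
        x = np.linspace(-100000, 262144, 3000)
        back = tr.invert_transform(tr.apply_flowjo_biex(x, spec), spec)
        assert np.max(np.abs(back - x)) <= 1e-4 * spec.max_value

    def test_invalid_params(self):
        with pytest.raises(InvalidParams):
            tr.apply_flowjo_biex(np.array([0.0]),
                                 tr.flowjo_biex(width_basis=10.0))


class TestRatio:
    CH = {"A": 0, "B": 1}

    def test_plain_ratio(self):
        spec = tr.ratio("A", "B", 1, 0, 0)
        ev = np.array([[6.0, 3.0]])
        assert tr.apply_ratio(ev, self.CH, spec)[0] == 2.0

    def test_linear_in_scale_coefficient(self):
        ev = np.array([[6.0, 3.0]])
        assert tr.apply_ratio(ev, self.CH, tr.ratio("A", "B", 2, 0, 0))[0] == 4.0

    def test_denominator_at_c_propagates_infinity(self):
        spec = tr.ratio("A", "B", 1, 0, 3.0)
        ev = np.array([[6.0, 3.0], [6.0, 4.0]])
        out = tr.apply_ratio(ev, self.CH, spec)
        assert np.isinf(out[0]) and np.isfinite(out[1])
        assert np.isfinite(out).tolist() == [False, True]

    def test_unknown_channel(self):
        with pytest.raises(UnknownChannel):
            tr.apply_ratio(np.zeros((1, 2)), self.CH, tr.ratio("A", "Z", 1, 0, 0))

    def test_ratio_not_invertible(self):
        with pytest.raises(NotInvertible):
            tr.invert_transform(np.array([1.0]), tr.ratio("A", "B", 1, 0, 0))


@pytest.mark.parametrize("spec", [
    tr.linear(262144, 100), tr.log(262144, 4.5), tr.asinh(262144, 4.5, 1),
    tr.logicle(262144, 0.5, 4.5, 0), tr.hyperlog(262144, 0.5, 4.5, 0),
    tr.flowjo_biex()])
def test_every_family_strictly_monotone(spec):
    lo = 1.0 if spec.kind == "log" else -20000.0
    x = np.linspace(lo, 262144.0, 4000)
    y = tr.apply_transform(x, spec)
    assert np.all(np.diff(y) > 0)


@pytest.mark.parametrize("spec,rtol", [
    (tr.logicle(262144, 0.5, 4.5, 0), 1e-9),
    (tr.hyperlog(262144, 0.5, 4.5, 0), 1e-9),
    (tr.asinh(262144, 4.5, 0), 1e-9),
])
def test_forward_inverse_roundtrip_tight(spec, rtol):
    x = np.linspace(-20000, 262144, 1000)
    back = tr.invert_transform(tr.apply_transform(x, spec), spec)
    assert np.max(np.abs(back - x)) <= rtol * 262144
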