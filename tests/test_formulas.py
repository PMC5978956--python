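"""Hand-evaluation oracles and algebraic properties of the defining formulas."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from acrqa import formulas

REL = 1e-12


class TestHandValues:
    """Each formula against an independent hand evaluation."""

    @pytest.mark.parametrize(
        "actual,measured,expected",
        [
            (190.0, 190.0, 0.0),
            (190.0, 188.1, (190.0 - 188.1) / 190.0 * 100.0),   # +1.0
            (190.0, 191.9, (190.0 - 191.9) / 190.0 * 100.0),   # -1.0
        ],
    )
    def test_geometric_distortion(self, actual, measured, expected):
        assert formulas.percent_geometric_distortion(actual, measured) == pytest.approx(
            expected, rel=REL, abs=1e-15
        )

    @pytest.mark.parametrize(
        "left,right,delta,disp",
        [(40.0, 40.0, 0.0, 0.0), (42.0, 38.0, 4.0, 2.0), (38.0, 42.0, -4.0, -2.0)],
    )
    def test_slice_position(self, left, right, delta, disp):
        assert formulas.slice_position_delta(left, right) == pytest.approx(delta, rel=REL)
        assert formulas.slice_displacement(left, right) == pytest.approx(disp, rel=REL)

    @pytest.mark.parametrize(
        "top,bottom,expected",
        [
            (50.0, 50.0, 0.2 * 50.0 * 50.0 / 100.0),   # 5.00: 0.1 x harmonic mean
            (40.0, 60.0, 0.2 * 40.0 * 60.0 / 100.0),   # 4.80
        ],
    )
    def test_slice_thickness(self, top, bottom, expected):
        assert formulas.slice_thickness(top, bottom) == pytest.approx(expected, rel=REL)

    @pytest.mark.parametrize(
        "smax,smin,expected",
        [(1000.0, 1000.0, 100.0), (1100.0, 900.0, 100.0 * (1 - 200.0 / 2000.0))],
    )
    def test_integral_uniformity(self, smax, smin, expected):
        assert formulas.integral_uniformity(smax, smin) == pytest.approx(expected, rel=REL)

    def test_ghosting_ratio(self):
        # FE sum 40, PE sum 20, mean 1000 -> (40-20)/2000 = 1%
        gr = formulas.ghosting_ratio(25.0, 15.0, 12.0, 8.0, 1000.0)
        assert gr * 100.0 == pytest.approx(1.0, rel=REL)
        assert formulas.ghosting_ratio(0.0, 0.0, 0.0, 0.0, 1000.0) == 0.0

    def test_percent_deviation(self):
        assert formulas.percent_deviation(3.38, 2.5) == pytest.approx(
            (3.38 - 2.5) / 2.5 * 100.0, rel=REL
        )


class TestProperties:
    @given(
        t=st.floats(1.0, 200.0, allow_nan=False),
        b=st.floats(1.0, 200.0, allow_nan=False),
    )
    @settings(max_examples=100, derandomize=True)
    def test_slice_thickness_symmetric(self, t, b):
        assert formulas.slice_thickness(t, b) == pytest.approx(
            formulas.slice_thickness(b, t), rel=1e-12
        )

    @given(t=st.floats(0.5, 100.0, allow_nan=False))
    @settings(max_examples=100, derandomize=True)
    def test_slice_thickness_equal_ramps(self, t):
        """Equal ramps of length L give exactly 0.1 L."""
        assert formulas.slice_thickness(t, t) == pytest.approx(0.1 * t, rel=1e-12)

    @given(
        smin=st.floats(1.0, 1e6, allow_nan=False),
        spread=st.floats(0.0, 1e6, allow_nan=False),
        k=st.floats(1e-3, 1e3, allow_nan=False),
    )
    @settings(max_examples=100, derandomize=True)
    def test_piu_range_and_scale_invariance(self, smin, spread, k):
        piu = formulas.integral_uniformity(smin + spread, smin)
        assert 0.0 <= piu <= 100.0
        scaled = formulas.integral_uniformity(k * (smin + spread), k * smin)
        assert scaled == pytest.approx(piu, rel=1e-9, abs=1e-9)

    @given(
        m1=st.floats(100.0, 300.0, allow_nan=False),
        m2=st.floats(100.0, 300.0, allow_nan=False),
    )
    @settings(max_examples=100, derandomize=True)
    def test_gd_strictly_decreasing_in_measured(self, m1, m2):
        g1 = formulas.percent_geometric_distortion(190.0, m1)
        g2 = formulas.percent_geometric_distortion(190.0, m2)
        if m1 < m2:
            assert g1 > g2
        assert formulas.percent_geometric_distortion(190.0, 190.0) == 0.0

    @given(k=st.floats(1e-3, 1e3, allow_nan=False))
    @settings(max_examples=50, derandomize=True)
    def test_gr_scale_invariance(self, k):
        base = formulas.ghosting_ratio(5.0, 3.0, 2.0, 1.0, 900.0)
        scaled = formulas.ghosting_ratio(5 * k, 3 * k, 2 * k, 1 * k, 900.0 * k)
        assert scaled == pytest.approx(base, rel=1e-9)
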