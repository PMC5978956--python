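"""Measurement operations against generator ground truth and hand oracles."""

import numpy as np
import pytest

from acrqa import MetricResult, PhantomSpec, generate_slices
from acrqa import metrics
from acrqa.metrics import (
    DiameterSet,
    compute_piu,
    count_distinct_peaks,
    evaluate_criteria,
    ghosting_ratio,
    hcsr,
    lcd,
    measure_diameters,
    percent_geometric_distortion,
    slice_position_error,
    slice_thickness,
)
from acrqa.recognition import frame_for, locate_features, segment_phantom
from acrqa.criteria import default_criteria

from conftest import default_meta, make_disk_slice


class TestDiameters:
    def test_ideal_disk_all_angles(self):
        slc = make_disk_slice(spacing=(1.0, 1.0), shape=(256, 256))
        d = measure_diameters(slc, segment_phantom(slc))
        for ang, val in d.measured_mm.items():
            assert val == pytest.approx(190.0, abs=0.5), ang

    def test_scaled_disk(self):
        slc = make_disk_slice(diameter_mm=190.0 * 0.99)
        d = measure_diameters(slc, segment_phantom(slc))
        gd = percent_geometric_distortion(d)
        for ang, val in gd.items():
            assert val == pytest.approx(1.0, abs=0.3), ang

    def test_anisotropic_spacing_symmetry(self):
        slc = make_disk_slice(shape=(512, 256), spacing=(0.5, 1.0))
        d = measure_diameters(slc, segment_phantom(slc))
        assert abs(d.measured_mm[0.0] - d.measured_mm[90.0]) < 0.5

    def test_missing_edge_flags_angle(self):
        # disk clipped by the FOV edge: the 0 deg profile has no crossings
        slc = make_disk_slice(shape=(256, 256), spacing=(1.0, 1.0),
                              diameter_mm=300.0)
        d = measure_diameters(slc, segment_phantom(slc))
        assert d.measured_mm[0.0] is None


class TestSlicePosition:
    def test_encoded_displacement_recovered(self, clean_series):
        spec = PhantomSpec(
            seed=12, noise_sigma=0.0,
            bar_displacement_mm={"S1": -1.95, "S11": 2.0},
        )
        slices, _, sidecar = generate_slices(spec)
        for role in ("S1", "S11"):
            idx = sidecar["role_map"][role]
            feats = locate_features(slices[idx], role)
            bars = slice_position_error(slices[idx], feats)
            expected = sidecar["expected"]["displacement_mm"][role]
            px = slices[idx].pixel_spacing_row_mm
            assert bars.displacement_mm == pytest.approx(expected, abs=0.5 * px)

    def test_symmetric_bars_zero(self, clean_series):
        slices, _, sidecar = clean_series
        idx = sidecar["role_map"]["S1"]
        feats = locate_features(slices[idx], "S1")
        bars = slice_position_error(slices[idx], feats)
        assert bars.delta_sp_mm == pytest.approx(0.0, abs=0.2)

    def test_not_located_gives_none(self, default_series):
        slices, _, sidecar = default_series
        s7 = slices[sidecar["role_map"]["S7"]]
        feats = locate_features(s7, "S7")
        assert slice_position_error(s7, feats) is None


class TestSliceThickness:
    @pytest.mark.parametrize("true_st", [2.5, 5.0])
    def test_ramp_encoded_thickness(self, true_st):
        spec = PhantomSpec(seed=13, noise_sigma=0.0,
                           true_slice_thickness_mm=true_st)
        slices, _, sidecar = generate_slices(spec)
        idx = sidecar["role_map"]["S1"]
        feats = locate_features(slices[idx], "S1")
        st = slice_thickness(slices[idx], feats)
        assert st is not None
        st_mm, ramps = st
        assert st_mm == pytest.approx(true_st, rel=0.10)
        assert ramps.top_mm == pytest.approx(10.0 * true_st, rel=0.05)

    def test_weak_ramp_signal_not_evaluated(self, clean_series):
        slices, _, sidecar = clean_series
        idx = sidecar["role_map"]["S1"]
        s1 = slices[idx]
        feats = locate_features(s1, "S1")
        # plateau ~1000: claiming noise sigma 500 makes plateau < 3 sigma
        assert slice_thickness(s1, feats, noise_sigma=500.0) is None


class TestUniformity:
    def test_perfectly_uniform_disk(self):
        slc = make_disk_slice()
        res = compute_piu(slc, segment_phantom(slc))
        assert res.piu == pytest.approx(100.0, abs=0.2)
        assert res.s_max >= res.s_min

    def test_known_bias_field_matches_exact_kernel(self, default_series):
        slices, _, sidecar = default_series
        idx = sidecar["role_map"]["S7"]
        res = compute_piu(slices[idx], segment_phantom(slices[idx]))
        assert res.piu == pytest.approx(sidecar["expected"]["piu_pct"], abs=2.0)

    def test_small_phantom_not_evaluated(self):
        # 200 cm^2 circle (r = 79.8 mm) cannot fit a 100 mm disk
        slc = make_disk_slice(diameter_mm=100.0)
        assert compute_piu(slc, segment_phantom(slc)) is None


class TestGhosting:
    def test_ghost_free_noise_free_zero(self):
        slc = make_disk_slice()
        res = ghosting_ratio(slc, segment_phantom(slc), default_meta())
        assert res.gr_signed_pct == pytest.approx(0.0, abs=1e-9)

    def test_injected_ghost_recovered(self):
        spec = PhantomSpec(seed=14, noise_sigma=0.0, ghost_fraction=0.01,
                           bias_amplitude=0.0)
        slices, meta, sidecar = generate_slices(spec)
        idx = sidecar["role_map"]["S7"]
        res = ghosting_ratio(slices[idx], segment_phantom(slices[idx]), meta)
        assert 0.7 <= res.gr_abs_pct <= 1.3
        assert res.gr_abs_pct == pytest.approx(
            sidecar["expected"]["gr_abs_pct"], rel=0.3
        )
        assert res.gr_signed_pct < 0  # ghost adds signal on the PE side

    def test_pe_axis_selects_roi_pairs(self):
        spec = PhantomSpec(seed=14, noise_sigma=0.0, ghost_fraction=0.01,
                           bias_amplitude=0.0, phase_encode_axis="col")
        slices, meta, sidecar = generate_slices(spec)
        idx = sidecar["role_map"]["S7"]
        res = ghosting_ratio(slices[idx], segment_phantom(slices[idx]), meta)
        assert res.gr_abs_pct == pytest.approx(
            sidecar["expected"]["gr_abs_pct"], rel=0.3
        )

    def test_insufficient_margin_not_evaluated(self):
        slc = make_disk_slice(shape=(128, 128), spacing=(1.6, 1.6),
                              diameter_mm=190.0)  # FOV 204.8 mm: margin ~7 mm
        res = ghosting_ratio(slc, segment_phantom(slc), default_meta((128, 128)))
        assert res is None


class TestHCSR:
    def test_peak_counter_on_synthetic_profiles(self):
        four = np.array([0, 5, 0, 5, 0, 5, 0, 5, 0], dtype=float)
        assert count_distinct_peaks(four) == 4
        merged = np.array([0, 5, 4.8, 5, 4.8, 5, 4.8, 5, 0], dtype=float)
        assert count_distinct_peaks(merged) == 1
        assert count_distinct_peaks(np.zeros(9)) == 0

    @pytest.mark.parametrize(
        "blur,expected", [(0.0, 0.9), (0.45, 1.0), (0.8, None)]
    )
    def test_blur_ladder_matches_sidecar(self, blur, expected):
        spec = PhantomSpec(seed=15, noise_sigma=0.0, hole_blur_sigma_mm=blur)
        slices, _, sidecar = generate_slices(spec)
        idx = sidecar["role_map"]["S1"]
        feats = locate_features(slices[idx], "S1")
        res = hcsr(slices[idx], feats)
        assert res.resolved_lr_mm == expected
        assert res.resolved_ap_mm == expected
        assert sidecar["expected"]["hcsr_lr_mm"] == expected
        assert sidecar["expected"]["hcsr_ap_mm"] == expected

    def test_display_formatting(self):
        from acrqa.metrics import HCSRResult

        assert HCSRResult(1.0, 1.0).display == "1/1"
        assert HCSRResult(None, 0.9).display == ">1.1/0.9"

    def test_review_override_logged(self, clean_series):
        slices, _, sidecar = clean_series
        idx = sidecar["role_map"]["S1"]
        feats = locate_features(slices[idx], "S1")
        res = hcsr(slices[idx], feats, mode="review",
                   overrides={(0.9, "horiz"): False, (0.9, "vert"): False})
        assert res.resolved_lr_mm == 1.0
        assert res.overridden[(0.9, "horiz")]["auto"] is True


class TestLCD:
    def _wheels(self, spec):
        slices, _, sidecar = generate_slices(spec)
        out = {}
        for role in ("S8", "S9", "S10", "S11"):
            idx = sidecar["role_map"][role]
            out[role] = (slices[idx], locate_features(slices[idx], role))
        return out, sidecar

    def test_full_contrast_total_40(self, clean_series):
        slices, _, sidecar = clean_series
        wheels = {
            r: (slices[sidecar["role_map"][r]],
                locate_features(slices[sidecar["role_map"][r]], r))
            for r in ("S8", "S9", "S10", "S11")
        }
        assert lcd(wheels).total == 40

    def test_zero_contrast_total_0(self):
        spec = PhantomSpec(
            seed=16, noise_sigma=0.0,
            spoke_contrast_pct={"S8": 0.0, "S9": 0.0, "S10": 0.0, "S11": 0.0},
        )
        wheels, _ = self._wheels(spec)
        assert lcd(wheels).total == 0

    def test_partial_spokes_counted_with_stop_rule(self):
        spec = PhantomSpec(seed=17, noise_sigma=0.0,
                           spokes_rendered={"S8": 7, "S9": 10, "S10": 10,
                                            "S11": 10})
        wheels, sidecar = self._wheels(spec)
        res = lcd(wheels)
        assert res.spokes_per_slice["S8"] == 7
        assert res.total == 37
        assert sidecar["expected"]["lcd_total"] == 37

    def test_missing_wheel_marks_partial(self, clean_series):
        slices, _, sidecar = clean_series
        wheels = {
            "S8": (slices[sidecar["role_map"]["S8"]],
                   locate_features(slices[sidecar["role_map"]["S8"]], "S8")),
        }
        res = lcd(wheels)
        assert res.total is None
        assert res.spokes_per_slice["S9"] is None


class TestCriteria:
    def _metric(self, name, value):
        passed = "not-evaluated" if value is None else "pass"
        return MetricResult(name=name, value=value, passed=passed)

    def test_piu_pass_and_lcd_boundary_fail(self):
        ms = [self._metric("piu", 88.76), self._metric("lcd", 36.0)]
        evaluate_criteria(ms, default_criteria())
        assert ms[0].passed == "pass"
        assert ms[1].passed == "fail"

    def test_absent_metric_excluded_from_overall(self):
        from acrqa import QAReport

        ms = [self._metric("st", None), self._metric("piu", 90.0)]
        evaluate_criteria(ms, default_criteria(), nominal_thickness_mm=5.0)
        assert ms[0].passed == "not-evaluated"
        rep = QAReport(metrics=ms)
        assert rep.overall_pass

    def test_st_uses_nominal_reference(self):
        ms = [self._metric("st", 5.6), self._metric("st", 5.8)]
        evaluate_criteria(ms, default_criteria(), nominal_thickness_mm=5.0)
        assert ms[0].passed == "pass"   # |5.6-5| <= 0.7
        assert ms[1].passed == "fail"

    def test_unknown_family_no_criterion(self):
        ms = [self._metric("snr", 120.0)]
        evaluate_criteria(ms, default_criteria())
        assert ms[0].passed == "no-criterion"
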