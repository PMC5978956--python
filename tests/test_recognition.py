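"""Segmentation, slice-role classification and feature location."""

import numpy as np
import pytest

from acrqa import PhantomSpec, generate_slices
from acrqa.layout import BAR_INSERT, RAMP_INSERT
from acrqa.recognition import (
    classify_slices,
    frame_for,
    locate_features,
    segment_phantom,
)
from acrqa.types import PhantomNotFoundError, RecognitionError, SliceImage

from conftest import default_meta, make_disk_slice


class TestSegmentation:
    def test_equivalent_diameter_of_ideal_disk(self):
        slc = make_disk_slice(diameter_mm=190.0)
        m = segment_phantom(slc)
        assert 189.0 <= m.equivalent_diameter_mm <= 191.0

    def test_blank_image_raises(self):
        slc = SliceImage(np.zeros((64, 64)), 1.0, 1.0, 0.0, 5.0)
        with pytest.raises(PhantomNotFoundError, match="phantom not found"):
            segment_phantom(slc)

    def test_centroid_tracks_translation(self):
        a = segment_phantom(make_disk_slice())
        b = segment_phantom(make_disk_slice(center_px=(127.5 + 10, 127.5 + 10)))
        assert abs(b.centroid_row - a.centroid_row - 10.0) < 0.5
        assert abs(b.centroid_col - a.centroid_col - 10.0) < 0.5

    def test_intensity_scale_invariance(self, default_series):
        slices, _, sidecar = default_series
        s1 = slices[sidecar["role_map"]["S1"]]
        m1 = segment_phantom(s1)
        scaled = SliceImage(
            s1.pixels * 3.7, s1.pixel_spacing_row_mm, s1.pixel_spacing_col_mm,
            s1.slice_location_mm, s1.nominal_thickness_mm,
        )
        m2 = segment_phantom(scaled)
        assert abs(m1.centroid_row - m2.centroid_row) < 0.05
        assert abs(m1.centroid_col - m2.centroid_col) < 0.05
        assert abs(m1.equivalent_diameter_mm - m2.equivalent_diameter_mm) < 0.2

    def test_two_candidates_ambiguous(self):
        slc = make_disk_slice(shape=(256, 256), diameter_mm=100.0,
                              center_px=(70.0, 70.0))
        other = make_disk_slice(shape=(256, 256), diameter_mm=90.0,
                                center_px=(190.0, 190.0))
        slc.pixels += other.pixels
        with pytest.raises(PhantomNotFoundError, match="multiple"):
            segment_phantom(slc)


class TestClassification:
    def test_standard_series_ordinal(self, default_series):
        slices, meta, _ = default_series
        roles = classify_slices(slices, meta)
        assert roles["S1"] == 0
        assert roles["S11"] == 10
        assert roles.direction == 1

    def test_reversed_series_autodetected(self):
        spec = PhantomSpec(seed=6, flip_z=True)
        slices, meta, _ = generate_slices(spec)
        roles = classify_slices(slices, meta)
        assert roles["S1"] == 10
        assert roles["S11"] == 0
        assert roles.direction == -1

    def test_body_protocol_nearest_position(self):
        spec = PhantomSpec(
            seed=6, n_slices=21, slice_gap_mm=0.0,
            matrix_rows=352, matrix_cols=352,
            pixel_spacing_row_mm=420 / 352, pixel_spacing_col_mm=420 / 352,
        )
        slices, meta, sidecar = generate_slices(spec)
        roles = classify_slices(slices, meta)
        # ACR positions are 10 mm apart; body slices 5 mm -> every other slice
        assert roles.roles == sidecar["role_map"]
        assert roles["S1"] == 0 and roles["S5"] == 8 and roles["S11"] == 20

    def test_uniform_only_series_rejected(self):
        slices = [
            make_disk_slice(location_mm=-50.0 + 10.0 * i) for i in range(11)
        ]
        with pytest.raises(RecognitionError, match="cannot establish S1 end"):
            classify_slices(slices, default_meta())


class TestFeatureLocation:
    def test_s1_ramp_band_rows_near_truth(self, clean_series):
        slices, _, sidecar = clean_series
        idx = sidecar["role_map"]["S1"]
        s1 = slices[idx]
        feats = locate_features(s1, "S1")
        assert feats.ramps.located
        # ground truth: ramp bands at y in [-12,-7] and [-5,0] mm from centre
        mask = segment_phantom(s1)
        frame = frame_for(s1, mask)
        t0, _ = frame.to_px(-12.0, 0.0)
        assert abs(feats.ramps.top_rows[0] - t0) < 2.0

    def test_uniform_slice_has_no_features(self, default_series):
        slices, _, sidecar = default_series
        s7 = slices[sidecar["role_map"]["S7"]]
        feats = locate_features(s7, "S7")
        assert feats.is_empty()

    def test_erased_bars_flagged_not_located(self, default_series):
        slices, _, sidecar = default_series
        s1 = slices[sidecar["role_map"]["S1"]]
        doctored = SliceImage(
            s1.pixels.copy(), s1.pixel_spacing_row_mm, s1.pixel_spacing_col_mm,
            s1.slice_location_mm, s1.nominal_thickness_mm,
        )
        mask = segment_phantom(doctored)
        frame = frame_for(doctored, mask)
        ri, ci = frame.box_index(BAR_INSERT, doctored.shape)
        doctored.pixels[ri, ci] = 0.0
        feats = locate_features(doctored, "S1")
        assert feats.bars is not None and not feats.bars.located
        assert feats.ramps.located  # untouched inserts still found

    def test_erased_ramps_flagged_not_located(self, default_series):
        slices, _, sidecar = default_series
        s1 = slices[sidecar["role_map"]["S1"]]
        doctored = SliceImage(
            s1.pixels.copy(), s1.pixel_spacing_row_mm, s1.pixel_spacing_col_mm,
            s1.slice_location_mm, s1.nominal_thickness_mm,
        )
        mask = segment_phantom(doctored)
        frame = frame_for(doctored, mask)
        ri, ci = frame.box_index(RAMP_INSERT, doctored.shape)
        doctored.pixels[ri, ci] = 0.0
        feats = locate_features(doctored, "S1")
        assert feats.ramps is not None and not feats.ramps.located
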