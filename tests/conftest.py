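"""Shared fixtures: synthetic series are rendered once per session."""

from __future__ import annotations

import numpy as np
import pytest

from acrqa import PhantomSpec, SeriesMeta, SliceImage, generate_slices


def make_disk_slice(
    shape=(256, 256),
    spacing=(250.0 / 256, 250.0 / 256),
    diameter_mm=190.0,
    center_px=None,
    value=1000.0,
    location_mm=0.0,
    supersample=4,
) -> SliceImage:
    """Analytically rendered uniform disk (partial-volume edges)."""
    rows, cols = shape
    sp_r, sp_c = spacing
    if center_px is None:
        center_px = (rows / 2.0 - 0.5, cols / 2.0 - 0.5)
    F = supersample
    cy = (center_px[0] + 0.5) * sp_r
    cx = (center_px[1] + 0.5) * sp_c
    u = (np.arange(rows * F) + 0.5) * sp_r / F - cy
    v = (np.arange(cols * F) + 0.5) * sp_c / F - cx
    disk = (u[:, None] ** 2 + v[None, :] ** 2) <= (diameter_mm / 2.0) ** 2
    canvas = np.where(disk, value, 0.0)
    img = canvas.reshape(rows, F, cols, F).mean((1, 3))
    return SliceImage(
        pixels=img,
        pixel_spacing_row_mm=sp_r,
        pixel_spacing_col_mm=sp_c,
        slice_location_mm=location_mm,
        nominal_thickness_mm=5.0,
    )


def default_meta(shape=(256, 256)) -> SeriesMeta:
    return SeriesMeta(
        sequence_name="TEST", fov_mm=250.0,
        matrix_rows=shape[0], matrix_cols=shape[1],
        phase_encode_axis="row",
    )


@pytest.fixture(scope="session")
def default_spec() -> PhantomSpec:
    return PhantomSpec(seed=1)


@pytest.fixture(scope="session")
def default_series(default_spec):
    """(slices, meta, sidecar) for the default in-tolerance phantom."""
    return generate_slices(default_spec)


@pytest.fixture(scope="session")
def clean_series():
    """Noise-free, ghost-free, unbiased series: exact-geometry checks."""
    spec = PhantomSpec(
        seed=11, noise_sigma=0.0, ghost_fraction=0.0, bias_amplitude=0.0
    )
    return generate_slices(spec)


@pytest.fixture(scope="session")
def default_report(default_series):
    from acrqa import analyze_series

    slices, meta, _ = default_series
    return analyze_series(slices, meta)
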