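"""Scalar formulas for the seven ACR image-quality parameters.

These are the defining equations of the method, kept free of any image
processing so they can be verified against hand evaluation:

* percent geometric distortion  %GD = (actual - measured) / actual * 100
* slice position error          dSP = left_bar - right_bar, displacement = dSP/2
  (positive displacement = slice mispositioned superiorly)
* slice thickness               ST = 0.2 * top * bottom / (top + bottom)
  from the FWHM lengths of the two crossed 10:1 signal ramps
* percent integral uniformity   PIU = 100 * (1 - (Smax - Smin)/(Smax + Smin))
* ghosting ratio                GR = ((FE1 + FE2) - (PE1 + PE2)) / (2 * S)
  signed as printed; callers usually report |GR| in percent.
"""

from __future__ import annotations

__all__ = [
    "percent_geometric_distortion",
    "slice_position_delta",
    "slice_displacement",
    "slice_thickness",
    "integral_uniformity",
    "ghosting_ratio",
    "percent_deviation",
]


def percent_geometric_distortion(actual_mm: float, measured_mm: float) -> float:
    """Signed %GD; positive when the image under-measures the true dimension."""
    if actual_mm <= 0:
        raise ValueError("actual dimension must be > 0")
    return (actual_mm - measured_mm) / actual_mm * 100.0


def slice_position_delta(left_bar_mm: float, right_bar_mm: float) -> float:
    """Bar-length difference dSP = left - right (mm)."""
    return left_bar_mm - right_bar_mm


def slice_displacement(left_bar_mm: float, right_bar_mm: float) -> float:
    """Actual slice displacement = dSP / 2; > 0 means superior mispositioning."""
    return 0.5 * slice_position_delta(left_bar_mm, right_bar_mm)


def slice_thickness(top_mm: float, bottom_mm: float) -> float:
    """ST from crossed 10:1 ramp FWHM lengths: 0.2 * top * bottom / (top + bottom).

    The ramps magnify slice thickness tenfold, so equal ramps of length L give
    ST = 0.1 * L.
    """
    if top_mm <= 0 or bottom_mm <= 0:
        raise ValueError("ramp lengths must be > 0")
    return 0.2 * top_mm * bottom_mm / (top_mm + bottom_mm)


def integral_uniformity(s_max: float, s_min: float) -> float:
    """PIU in percent from the extremal 1 cm^2 ROI means."""
    if s_max < s_min:
        raise ValueError("s_max must be >= s_min")
    if s_max + s_min <= 0:
        raise ValueError("ROI means must be positive")
    return 100.0 * (1.0 - (s_max - s_min) / (s_max + s_min))


def ghosting_ratio(
    s_fe1: float, s_fe2: float, s_pe1: float, s_pe2: float, s_mean: float
) -> float:
    """Signed ghosting ratio (dimensionless fraction, not percent)."""
    if s_mean <= 0:
        raise ValueError("phantom mean must be > 0")
    return ((s_fe1 + s_fe2) - (s_pe1 + s_pe2)) / (2.0 * s_mean)


def percent_deviation(measured: float, nominal: float) -> float:
    """Relative deviation from a nominal value, in percent of the nominal."""
    if nominal == 0:
        raise ValueError("nominal must be nonzero")
    return (measured - nominal) / nominal * 100.0
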