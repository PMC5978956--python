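"""Geometric prior for the ACR large phantom and protocol presets.

All feature positions are expressed in millimetres in a phantom-centred frame
for the nominal 190 mm inside-diameter cylinder: ``y`` increases
anterior -> posterior (down the image), ``x`` left -> right.  The recognizer
scales these offsets by the measured phantom diameter and the synthetic
renderer draws from the same table, so recognition is deterministic by
construction.  The coordinates are an idealization of the published ACR
internal layout, not a metrological copy; they are the single point of truth
should a different layout be needed.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import yaml

PHANTOM_DIAMETER_MM = 190.0
PHANTOM_LENGTH_MM = 148.0
PHANTOM_RADIUS_MM = PHANTOM_DIAMETER_MM / 2.0

ROLES = tuple(f"S{i}" for i in range(1, 12))

# Analysis-slice centres along the scan axis, phantom frame (S6 at mid-length).
ROLE_Z_MM = {f"S{i}": -50.0 + 10.0 * (i - 1) for i in range(1, 12)}


@dataclass(frozen=True)
class Box:
    """Axis-aligned rectangle in phantom-frame mm: y0 <= y <= y1, x0 <= x <= x1."""

    y0: float
    y1: float
    x0: float
    x1: float

    def contains(self, y, x):
        return (self.y0 <= y) & (y <= self.y1) & (self.x0 <= x) & (x <= self.x1)


# --- S1 crossed 10:1 signal ramps (slice thickness) -------------------------
# Dark insert housing with two bright ramp bands; each band's bright extent is
# 10x the excited slice thickness.
RAMP_INSERT = Box(-14.0, 2.0, -62.0, 62.0)
RAMP_TOP_Y = (-12.0, -7.0)      # row band of the negative-slope ramp
RAMP_BOTTOM_Y = (-5.0, 0.0)     # row band of the positive-slope ramp
RAMP_SLOPE = 10.0               # ramp length = RAMP_SLOPE * slice thickness

# --- S1/S11 slice-position bars ---------------------------------------------
# Two bright vertical bars in a dark housing near the anterior wall.  The bars
# grow/shrink in opposite directions as the slice mispositions; their length
# difference is dSP.
BAR_INSERT = Box(-90.0, -40.0, -20.0, 20.0)
BAR_BASE_Y = -42.0              # inferior (bottom) end of both bars
BAR_NOMINAL_LEN_MM = 40.0
BAR_LEFT_X = (-12.0, -6.0)
BAR_RIGHT_X = (6.0, 12.0)

# --- S1 high-contrast resolution hole arrays --------------------------------
# Three pairs of 4x4 bright-hole arrays (pitch = 2x hole diameter) in a dark
# housing: one array per size for the horizontal (FE-profile) assessment and
# one for the vertical.
RES_INSERT = Box(22.0, 55.0, -45.0, 45.0)
RES_SIZES_MM = (1.1, 1.0, 0.9)
RES_X_CENTERS = {1.1: -30.0, 1.0: 0.0, 0.9: 30.0}
RES_Y_HORIZ = 30.0              # arrays profiled along x
RES_Y_VERT = 45.0               # arrays profiled along y
RES_GRID_OFFSETS = (-3.0, -1.0, 1.0, 3.0)  # times hole size -> centre offsets

# --- S8-S11 low-contrast spoke wheels ---------------------------------------
# Ten spokes of three disks each; disk diameter decreases from spoke 1 to 10,
# spokes read clockwise from 12 o'clock.
SPOKE_COUNT = 10
SPOKE_DISK_RADII_MM = (16.0, 28.0, 40.0)   # radial positions of the 3 disks
SPOKE_DIAM_MAX_MM = 7.0
SPOKE_DIAM_MIN_MM = 1.5
LCD_CONTRAST_PCT = {"S8": 1.4, "S9": 2.5, "S10": 3.6, "S11": 5.1}

# --- uniformity / ghosting ROIs ---------------------------------------------
UNIFORMITY_CIRCLE_CM2 = 200.0
UNIFORMITY_ROI_CM2 = 1.0
GHOST_ROI_CM2 = 10.0
GHOST_ROI_LONG_MM = 80.0        # tangent long side of each 10 cm^2 rectangle

ROLE_FEATURES = {
    "S1": ("ramps", "bars", "resolution"),
    "S11": ("bars", "spokes"),
    "S8": ("spokes",),
    "S9": ("spokes",),
    "S10": ("spokes",),
}


def spoke_diameter_mm(k: int) -> float:
    """Disk diameter of spoke k (0-based, 0 = largest)."""
    if not 0 <= k < SPOKE_COUNT:
        raise ValueError("spoke index out of range")
    step = (SPOKE_DIAM_MAX_MM - SPOKE_DIAM_MIN_MM) / (SPOKE_COUNT - 1)
    return SPOKE_DIAM_MAX_MM - step * k


def spoke_disk_centers_mm(k: int) -> list[tuple[float, float]]:
    """(y, x) centres of the three disks of spoke k, clockwise from 12 o'clock."""
    import math

    # screen-clockwise with y pointing down: angle measured from "up" direction
    theta = math.radians(36.0 * k)
    uy, ux = -math.cos(theta), math.sin(theta)
    return [(r * uy, r * ux) for r in SPOKE_DISK_RADII_MM]


RES_ROW_STAGGER = (-0.75, -0.25, 0.25, 0.75)  # times hole size, quarter-pitch


def hole_centers_mm(size_mm: float, direction: str) -> list[list[tuple[float, float]]]:
    """Hole centres of the 4x4 array for one size/direction.

    Returned as rows-of-holes for the "horiz" array (profiles run along x) or
    columns-of-holes for the "vert" array (profiles run along y): the outer
    list enumerates the four profiles, the inner the four holes on each.
    Successive rows are staggered by a quarter of the hole pitch along the
    profile direction, as on the physical insert, so the hole phase relative
    to the pixel grid varies row to row.
    """
    xc = RES_X_CENTERS[size_mm]
    yc = RES_Y_HORIZ if direction == "horiz" else RES_Y_VERT
    lines = []
    for a, shift in zip(RES_GRID_OFFSETS, RES_ROW_STAGGER):
        line = []
        for b in RES_GRID_OFFSETS:
            if direction == "horiz":
                line.append((yc + a * size_mm, xc + (b + shift) * size_mm))
            else:
                line.append((yc + (b + shift) * size_mm, xc + a * size_mm))
        lines.append(line)
    return lines


# --- protocol presets --------------------------------------------------------


def load_protocols() -> dict:
    """Protocol presets shipped as YAML package data."""
    text = resources.files("acrqa.data").joinpath("protocols.yaml").read_text()
    return yaml.safe_load(text)


def role_locations_mm(locations: list[float]) -> dict[str, int]:
    """Map each ACR role to the series slice nearest its canonical position.

    ``locations`` are sorted slice locations with S1 assumed at the low end;
    role positions are laid out relative to the series centre so protocols
    with different slice counts (e.g. 42 x 2.5 mm) still map correctly.
    """
    import numpy as np

    locs = np.asarray(locations, dtype=float)
    center = 0.5 * (locs.min() + locs.max())
    mapping = {}
    for role in ROLES:
        target = center + ROLE_Z_MM[role]
        mapping[role] = int(np.argmin(np.abs(locs - target)))
    return mapping
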