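"""Phantom segmentation, slice-role assignment, and insert location.

The phantom is segmented by global Otsu thresholding, morphological closing,
largest-connected-component selection and hole filling — phantom/background
contrast is high, so the simplest robust pipeline suffices.  All insert
positions are then derived from the published internal layout (`layout`),
scaled by the measured equivalent diameter and anchored at the mask centroid,
which makes recognition translation-invariant and deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu

from . import layout
from .types import PhantomNotFoundError, RecognitionError, SeriesMeta, SliceImage

__all__ = [
    "PhantomMask",
    "PhantomFrame",
    "SliceRoleMap",
    "FeatureLocations",
    "segment_phantom",
    "classify_slices",
    "locate_features",
]


@dataclass
class PhantomMask:
    mask: np.ndarray
    centroid_row: float
    centroid_col: float
    equivalent_diameter_mm: float


@dataclass
class PhantomFrame:
    """Maps phantom-frame mm coordinates to (fractional) pixel coordinates.

    ``scale`` is measured diameter / nominal 190 mm, so layout offsets follow
    any isotropic geometric scaling of the acquisition.
    """

    centroid_row: float
    centroid_col: float
    spacing_row_mm: float
    spacing_col_mm: float
    scale: float = 1.0

    def to_px(self, y_mm: float, x_mm: float) -> tuple[float, float]:
        return (
            self.centroid_row + y_mm * self.scale / self.spacing_row_mm,
            self.centroid_col + x_mm * self.scale / self.spacing_col_mm,
        )

    def box_px(self, box: layout.Box) -> tuple[float, float, float, float]:
        r0, c0 = self.to_px(box.y0, box.x0)
        r1, c1 = self.to_px(box.y1, box.x1)
        return r0, r1, c0, c1

    def box_index(
        self, box: layout.Box, shape: tuple[int, int]
    ) -> tuple[slice, slice]:
        r0, r1, c0, c1 = self.box_px(box)
        ri = slice(max(0, int(np.ceil(r0))), min(shape[0], int(np.floor(r1)) + 1))
        ci = slice(max(0, int(np.ceil(c0))), min(shape[1], int(np.floor(c1)) + 1))
        return ri, ci


@dataclass
class RampBand:
    located: bool
    top_rows: Optional[tuple[float, float]] = None
    bottom_rows: Optional[tuple[float, float]] = None
    col_window: Optional[tuple[float, float]] = None


@dataclass
class BarPair:
    located: bool
    row_window: Optional[tuple[float, float]] = None
    left_cols: Optional[tuple[float, float]] = None
    right_cols: Optional[tuple[float, float]] = None


@dataclass
class ResolutionBlocks:
    located: bool


@dataclass
class SpokeWheel:
    located: bool
    center_row: float = 0.0
    center_col: float = 0.0
    radius_px: float = 0.0


@dataclass
class FeatureLocations:
    role: str
    frame: PhantomFrame
    ramps: Optional[RampBand] = None
    bars: Optional[BarPair] = None
    resolution: Optional[ResolutionBlocks] = None
    spokes: Optional[SpokeWheel] = None

    def is_empty(self) -> bool:
        return all(f is None for f in (self.ramps, self.bars, self.resolution, self.spokes))


@dataclass
class SliceRoleMap:
    roles: dict[str, int] = field(default_factory=dict)
    direction: int = 1  # +1: S1 at the low-location end

    def __getitem__(self, role: str) -> int:
        return self.roles[role]


def segment_phantom(slc: SliceImage) -> PhantomMask:
    """Segment the bright quasi-circular phantom on one slice."""
    img = slc.pixels
    if img.max() <= 0:
        raise PhantomNotFoundError("phantom not found: blank image")
    thr = threshold_otsu(img)
    binary = img > thr
    binary = ndimage.binary_closing(binary, structure=np.ones((3, 3)))
    labels, n = ndimage.label(binary)
    if n == 0:
        raise PhantomNotFoundError("phantom not found")
    sizes = ndimage.sum_labels(np.ones_like(labels), labels, index=range(1, n + 1))
    order = np.argsort(sizes)[::-1]
    largest = sizes[order[0]]
    min_area = 0.25 * img.size * 0.25  # >= 25% of FOV area for a ~quarter-FOV disk
    if largest < min_area:
        raise PhantomNotFoundError("phantom not found: largest region too small")
    if n > 1 and sizes[order[1]] >= 0.5 * largest:
        raise PhantomNotFoundError(
            "multiple phantom-sized candidates found; cannot choose"
        )
    mask = labels == (order[0] + 1)
    mask = ndimage.binary_fill_holes(mask)
    cr, cc = ndimage.center_of_mass(mask)
    area_mm2 = mask.sum() * slc.pixel_spacing_row_mm * slc.pixel_spacing_col_mm
    eq_diam = 2.0 * np.sqrt(area_mm2 / np.pi)
    return PhantomMask(mask=mask, centroid_row=cr, centroid_col=cc,
                       equivalent_diameter_mm=eq_diam)


def frame_for(slc: SliceImage, mask: PhantomMask) -> PhantomFrame:
    return PhantomFrame(
        centroid_row=mask.centroid_row,
        centroid_col=mask.centroid_col,
        spacing_row_mm=slc.pixel_spacing_row_mm,
        spacing_col_mm=slc.pixel_spacing_col_mm,
        scale=mask.equivalent_diameter_mm / layout.PHANTOM_DIAMETER_MM,
    )


def _interior_median(slc: SliceImage, mask: PhantomMask) -> float:
    return float(np.median(slc.pixels[mask.mask]))


def _dark_fraction(slc: SliceImage, mask: PhantomMask, box: layout.Box) -> float:
    """Fraction of in-phantom pixels inside a layout box darker than half the
    interior median — evidence that a dark insert housing is present there."""
    frame = frame_for(slc, mask)
    ri, ci = frame.box_index(box, slc.shape)
    region = slc.pixels[ri, ci]
    inmask = mask.mask[ri, ci]
    if inmask.sum() == 0:
        return 0.0
    med = _interior_median(slc, mask)
    return float(np.mean(region[inmask] < 0.5 * med))


INSERT_EVIDENCE_THRESHOLD = 0.15


def _s1_score(slc: SliceImage, mask: PhantomMask) -> tuple[float, float, float]:
    """(ramp, bars, resolution) dark-insert evidence scores."""
    return (
        _dark_fraction(slc, mask, layout.RAMP_INSERT),
        _dark_fraction(slc, mask, layout.BAR_INSERT),
        _dark_fraction(slc, mask, layout.RES_INSERT),
    )


def classify_slices(
    slices: list[SliceImage],
    meta: SeriesMeta,
    masks: Optional[list[PhantomMask]] = None,
) -> SliceRoleMap:
    """Assign ACR roles S1..S11 by position along the scan axis.

    The S1 end is auto-detected from feature evidence (the crossed-ramp and
    resolution inserts exist only on S1), preferred over any header-order
    convention; header order decides only exact ties.
    """
    if masks is None:
        masks = [segment_phantom(s) for s in slices]
    locs = [s.slice_location_mm for s in slices]
    if locs != sorted(locs):
        raise RecognitionError("slices must be sorted by location ascending")

    fwd = layout.role_locations_mm(locs)
    rev = {role: fwd[f"S{12 - int(role[1:])}"] for role in layout.ROLES}

    scores = {}
    for direction, mapping in ((1, fwd), (-1, rev)):
        i1, i11 = mapping["S1"], mapping["S11"]
        ramp1, bars1, res1 = _s1_score(slices[i1], masks[i1])
        ramp11, _, res11 = _s1_score(slices[i11], masks[i11])
        ok = (
            ramp1 > INSERT_EVIDENCE_THRESHOLD
            and bars1 > INSERT_EVIDENCE_THRESHOLD
            and res1 > INSERT_EVIDENCE_THRESHOLD
            # the far end carries bars only: no ramp/resolution evidence there
            and ramp11 < INSERT_EVIDENCE_THRESHOLD
            and res11 < INSERT_EVIDENCE_THRESHOLD
        )
        scores[direction] = (ok, ramp1 + bars1 + res1, mapping)

    candidates = [d for d in (1, -1) if scores[d][0]]
    if not candidates:
        raise RecognitionError(
            "cannot establish S1 end: insert evidence missing in both directions"
        )
    direction = max(candidates, key=lambda d: scores[d][1])
    return SliceRoleMap(roles=dict(scores[direction][2]), direction=direction)


def _bars_present(slc: SliceImage, mask: PhantomMask, frame: PhantomFrame) -> bool:
    """Bright left/right bars must both stand above the dark housing."""
    ri, _ = frame.box_index(layout.BAR_INSERT, slc.shape)
    med = _interior_median(slc, mask)
    for xs in (layout.BAR_LEFT_X, layout.BAR_RIGHT_X):
        _, c0 = frame.to_px(0.0, xs[0])
        _, c1 = frame.to_px(0.0, xs[1])
        ci = slice(max(0, int(round(c0))), int(round(c1)) + 1)
        col_profile = slc.pixels[ri, ci].mean(axis=1)
        if col_profile.max() < 0.5 * med:
            return False
    return True


def _ramps_present(slc: SliceImage, mask: PhantomMask, frame: PhantomFrame) -> bool:
    med = _interior_median(slc, mask)
    for band in (layout.RAMP_TOP_Y, layout.RAMP_BOTTOM_Y):
        r0, _ = frame.to_px(band[0], 0.0)
        r1, _ = frame.to_px(band[1], 0.0)
        ri = slice(max(0, int(round(r0))), int(round(r1)) + 1)
        _, ci = frame.box_index(layout.RAMP_INSERT, slc.shape)
        prof = slc.pixels[ri, ci].mean(axis=0)
        if prof.max() < 0.5 * med:
            return False
    return True


def _resolution_present(slc: SliceImage, mask: PhantomMask, frame: PhantomFrame) -> bool:
    med = _interior_median(slc, mask)
    ri, ci = frame.box_index(layout.RES_INSERT, slc.shape)
    region = slc.pixels[ri, ci]
    return region.size > 0 and region.max() > 0.4 * med


def locate_features(
    slc: SliceImage,
    role: str,
    mask: Optional[PhantomMask] = None,
) -> FeatureLocations:
    """Locate the inserts expected for ``role``; absent inserts are flagged
    not-located (downstream metrics then report not-evaluated, never zero)."""
    if mask is None:
        mask = segment_phantom(slc)
    frame = frame_for(slc, mask)
    feats = FeatureLocations(role=role, frame=frame)
    expected = layout.ROLE_FEATURES.get(role, ())

    if "ramps" in expected:
        if _ramps_present(slc, mask, frame):
            t0, _ = frame.to_px(layout.RAMP_TOP_Y[0], 0.0)
            t1, _ = frame.to_px(layout.RAMP_TOP_Y[1], 0.0)
            b0, _ = frame.to_px(layout.RAMP_BOTTOM_Y[0], 0.0)
            b1, _ = frame.to_px(layout.RAMP_BOTTOM_Y[1], 0.0)
            _, _, c0, c1 = frame.box_px(layout.RAMP_INSERT)
            feats.ramps = RampBand(
                located=True, top_rows=(t0, t1), bottom_rows=(b0, b1),
                col_window=(c0, c1),
            )
        else:
            feats.ramps = RampBand(located=False)

    if "bars" in expected:
        if _dark_fraction(slc, mask, layout.BAR_INSERT) > INSERT_EVIDENCE_THRESHOLD \
                and _bars_present(slc, mask, frame):
            r0, r1, _, _ = frame.box_px(layout.BAR_INSERT)
            _, l0 = frame.to_px(0.0, layout.BAR_LEFT_X[0])
            _, l1 = frame.to_px(0.0, layout.BAR_LEFT_X[1])
            _, g0 = frame.to_px(0.0, layout.BAR_RIGHT_X[0])
            _, g1 = frame.to_px(0.0, layout.BAR_RIGHT_X[1])
            feats.bars = BarPair(
                located=True, row_window=(r0, r1),
                left_cols=(l0, l1), right_cols=(g0, g1),
            )
        else:
            feats.bars = BarPair(located=False)

    if "resolution" in expected:
        feats.resolution = ResolutionBlocks(
            located=_resolution_present(slc, mask, frame)
        )

    if "spokes" in expected:
        _, cpx = frame.to_px(0.0, layout.SPOKE_DISK_RADII_MM[-1]
                             + layout.SPOKE_DIAM_MAX_MM)
        feats.spokes = SpokeWheel(
            located=True,
            center_row=frame.centroid_row,
            center_col=frame.centroid_col,
            radius_px=cpx - frame.centroid_col,
        )
    return feats
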