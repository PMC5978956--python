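"""Synthetic ACR-like phantom series with fully known ground truth.

The renderer draws the cylindrical phantom (inside diameter 190 mm, length
148 mm) and its inserts from the same layout prior the recognizer uses, on a
4x super-sampled canvas that is box-downsampled so sub-pixel edges carry
physically meaningful partial volume (FWHM oracles stay valid).  Corruptions
are applied in a fixed order: geometry (isotropic scale, translation) ->
features -> bias field -> ghost -> noise.

Ghosting is modelled as a single half-FOV-shifted attenuated replica along the
phase-encode axis; noise is Gaussian (at phantom SNR the Rician/Gaussian
difference is immaterial to these metrics and Gaussian keeps expectations
analytic).  Every generated series comes with a ground-truth sidecar holding
the generated parameters and the generator-computed expected value of each
metric, which drives all recovery tests.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional

import numpy as np
from scipy import ndimage

from . import formulas, layout
from .io import write_series
from .metrics import _coverage_kernel, _hole_profiles, ghost_roi_rects
from .recognition import PhantomFrame
from .types import SeriesMeta, SliceImage

__all__ = ["PhantomSpec", "expected_metrics", "generate_slices", "generate_series"]

RESCALE_SLOPE = 0.1  # uint16 storage quantum of the synthetic DICOM writer


def _default_bar_displacement() -> dict:
    return {"S1": 0.0, "S11": 0.0}


def _default_contrasts() -> dict:
    return dict(layout.LCD_CONTRAST_PCT)


def _default_spokes() -> dict:
    return {r: layout.SPOKE_COUNT for r in ("S8", "S9", "S10", "S11")}


@dataclass
class PhantomSpec:
    """Ground-truth parameters driving the renderer.

    Defaults reproduce the ACR large phantom scanned with the standard axial
    protocol (11 slices of 5 mm with 5 mm gap, 25 cm FOV, 256 x 256) under
    benign acquisition conditions: a mild smooth bias field, a faint ghost and
    phantom-level SNR, i.e. a series that passes every criterion.
    """

    inside_diameter_mm: float = layout.PHANTOM_DIAMETER_MM
    inside_length_mm: float = layout.PHANTOM_LENGTH_MM
    matrix_rows: int = 256
    matrix_cols: int = 256
    pixel_spacing_row_mm: float = 250.0 / 256
    pixel_spacing_col_mm: float = 250.0 / 256
    n_slices: int = 11
    slice_thickness_mm: float = 5.0
    slice_gap_mm: float = 5.0
    slice_locations_mm: Optional[list[float]] = None
    flip_z: bool = False

    # feature ground truth
    true_slice_thickness_mm: float = 5.0
    bar_displacement_mm: dict = field(default_factory=_default_bar_displacement)
    hole_blur_sigma_mm: float = 0.0
    spoke_contrast_pct: dict = field(default_factory=_default_contrasts)
    spokes_rendered: dict = field(default_factory=_default_spokes)

    # corruptions
    mean_intensity: float = 1000.0
    scale: float = 1.0                # isotropic geometric scale factor
    bias_amplitude: float = 0.08      # fractional amplitude of the bias field
    ghost_fraction: float = 0.002
    noise_sigma: float = 5.0
    translation_px: tuple[float, float] = (0.0, 0.0)
    phase_encode_axis: str = "row"

    sequence_name: str = "SYN_ACR_T1WI"
    coil_name: str = "synthetic"
    seed: int = 0
    supersample: int = 4

    def __post_init__(self) -> None:
        if min(self.inside_diameter_mm, self.inside_length_mm,
               self.pixel_spacing_row_mm, self.pixel_spacing_col_mm,
               self.true_slice_thickness_mm, self.scale) <= 0:
            raise ValueError("physical dimensions and scale must be > 0")
        if not 0.0 <= self.ghost_fraction <= 0.5:
            raise ValueError("ghost fraction must lie in [0, 0.5]")
        for role, c in self.spoke_contrast_pct.items():
            if not 0.0 <= c < 100.0:
                raise ValueError(f"spoke contrast for {role} must be in [0, 100)%")
        fov_r = self.matrix_rows * self.pixel_spacing_row_mm
        fov_c = self.matrix_cols * self.pixel_spacing_col_mm
        if self.scale * self.inside_diameter_mm >= min(fov_r, fov_c):
            raise ValueError("phantom disk does not fit in the requested FOV")
        for role, d in self.bar_displacement_mm.items():
            if abs(d) > 6.0:
                raise ValueError(
                    f"slice-position bars for {role}: displacement {d} mm "
                    "exceeds the bar housing"
                )
        if self.phase_encode_axis not in ("row", "col"):
            raise ValueError("phase_encode_axis must be 'row' or 'col'")

    # -- derived geometry ------------------------------------------------------

    @property
    def locations(self) -> list[float]:
        if self.slice_locations_mm is not None:
            return sorted(self.slice_locations_mm)
        pitch = self.slice_thickness_mm + self.slice_gap_mm
        n = self.n_slices
        return [(i - (n - 1) / 2.0) * pitch for i in range(n)]

    @property
    def center_px(self) -> tuple[float, float]:
        """Pixel-centre coordinates of the phantom axis."""
        return (
            self.matrix_rows / 2.0 + self.translation_px[0] - 0.5,
            self.matrix_cols / 2.0 + self.translation_px[1] - 0.5,
        )

    def frame(self) -> PhantomFrame:
        cr, cc = self.center_px
        return PhantomFrame(cr, cc, self.pixel_spacing_row_mm,
                            self.pixel_spacing_col_mm, scale=self.scale)

    def role_map(self) -> dict[str, int]:
        fwd = layout.role_locations_mm(self.locations)
        if not self.flip_z:
            return fwd
        return {r: fwd[f"S{12 - int(r[1:])}"] for r in layout.ROLES}

    def meta(self) -> SeriesMeta:
        return SeriesMeta(
            sequence_name=self.sequence_name,
            coil_name=self.coil_name,
            fov_mm=self.matrix_rows * self.pixel_spacing_row_mm,
            matrix_rows=self.matrix_rows,
            matrix_cols=self.matrix_cols,
            phase_encode_axis=self.phase_encode_axis,
        )

    @property
    def pe_numpy_axis(self) -> int:
        return 1 if self.phase_encode_axis == "row" else 0


# --- rendering -----------------------------------------------------------------


def _phantom_coords(spec: PhantomSpec) -> tuple[np.ndarray, np.ndarray]:
    """Sub-pixel-centre coordinates in the (scaled) phantom frame, mm."""
    F = spec.supersample
    cr, cc = spec.center_px
    cy = (cr + 0.5) * spec.pixel_spacing_row_mm
    cx = (cc + 0.5) * spec.pixel_spacing_col_mm
    u = ((np.arange(spec.matrix_rows * F) + 0.5) * spec.pixel_spacing_row_mm / F
         - cy) / spec.scale
    v = ((np.arange(spec.matrix_cols * F) + 0.5) * spec.pixel_spacing_col_mm / F
         - cx) / spec.scale
    return u, v


def _paint_box(canvas, u, v, box: layout.Box, value: float) -> None:
    iy = np.nonzero((u >= box.y0) & (u <= box.y1))[0]
    ix = np.nonzero((v >= box.x0) & (v <= box.x1))[0]
    if iy.size and ix.size:
        canvas[iy[0]:iy[-1] + 1, ix[0]:ix[-1] + 1] = value


def _paint_circle(canvas, u, v, cy, cx, radius, value, add=False) -> None:
    iy = np.nonzero(np.abs(u - cy) <= radius)[0]
    ix = np.nonzero(np.abs(v - cx) <= radius)[0]
    if not (iy.size and ix.size):
        return
    uu = u[iy[0]:iy[-1] + 1][:, None]
    vv = v[ix[0]:ix[-1] + 1][None, :]
    inside = (uu - cy) ** 2 + (vv - cx) ** 2 <= radius ** 2
    sub = canvas[iy[0]:iy[-1] + 1, ix[0]:ix[-1] + 1]
    if add:
        sub[inside] += value
    else:
        sub[inside] = value


def _bias_field(spec: PhantomSpec, u: np.ndarray, v: np.ndarray) -> np.ndarray:
    """Smooth low-order polynomial shading, 1 + O(bias_amplitude)."""
    R = layout.PHANTOM_RADIUS_MM
    un, vn = (u / R)[:, None], (v / R)[None, :]
    A = spec.bias_amplitude
    return 1.0 + A * (0.45 * vn - 0.30 * un - 0.80 * (un ** 2 + vn ** 2) / 2.0)


def _render_slice_noise_free(spec: PhantomSpec, roles: tuple[str, ...]) -> np.ndarray:
    """One slice: geometry + features + bias (+ PSF blur), downsampled.

    ``roles`` lists the analysis roles carried by this slice ('' for plain
    uniform slices).  Ghost and noise are applied by the callers.
    """
    F = spec.supersample
    u, v = _phantom_coords(spec)
    mu = spec.mean_intensity
    R = layout.PHANTOM_RADIUS_MM
    disk = (u[:, None] ** 2 + v[None, :] ** 2) <= R ** 2
    canvas = np.where(disk, mu, 0.0)

    for role in roles:
        feats = layout.ROLE_FEATURES.get(role, ())
        if "ramps" in feats:
            _paint_box(canvas, u, v, layout.RAMP_INSERT, 0.0)
            half = layout.RAMP_SLOPE * spec.true_slice_thickness_mm / 2.0
            for y0, y1 in (layout.RAMP_TOP_Y, layout.RAMP_BOTTOM_Y):
                _paint_box(canvas, u, v, layout.Box(y0, y1, -half, half), mu)
        if "bars" in feats:
            _paint_box(canvas, u, v, layout.BAR_INSERT, 0.0)
            d = spec.bar_displacement_mm.get(role, 0.0)
            for xs, length in (
                (layout.BAR_LEFT_X, layout.BAR_NOMINAL_LEN_MM + d),
                (layout.BAR_RIGHT_X, layout.BAR_NOMINAL_LEN_MM - d),
            ):
                _paint_box(canvas, u, v, layout.Box(
                    layout.BAR_BASE_Y - length, layout.BAR_BASE_Y, xs[0], xs[1]
                ), mu)
        if "resolution" in feats:
            _paint_box(canvas, u, v, layout.RES_INSERT, 0.0)
            for direction in ("horiz", "vert"):
                for size in layout.RES_SIZES_MM:
                    for line in layout.hole_centers_mm(size, direction):
                        for (hy, hx) in line:
                            _paint_circle(canvas, u, v, hy, hx, size / 2.0, mu)
        if "spokes" in feats:
            contrast = spec.spoke_contrast_pct.get(role, 0.0)
            n_rendered = spec.spokes_rendered.get(role, layout.SPOKE_COUNT)
            amp = mu * contrast / 100.0
            for k in range(min(n_rendered, layout.SPOKE_COUNT)):
                r = layout.spoke_diameter_mm(k) / 2.0
                for (cy, cx) in layout.spoke_disk_centers_mm(k):
                    _paint_circle(canvas, u, v, cy, cx, r, amp, add=True)

    canvas *= _bias_field(spec, u, v)
    if spec.hole_blur_sigma_mm > 0:
        canvas = ndimage.gaussian_filter(canvas, [
            spec.hole_blur_sigma_mm / (spec.pixel_spacing_row_mm / F),
            spec.hole_blur_sigma_mm / (spec.pixel_spacing_col_mm / F),
        ])
    img = canvas.reshape(spec.matrix_rows, F, spec.matrix_cols, F).mean((1, 3))
    return img


def _apply_ghost(spec: PhantomSpec, img: np.ndarray) -> np.ndarray:
    if spec.ghost_fraction <= 0:
        return img
    axis = spec.pe_numpy_axis
    shift = img.shape[axis] // 2
    return img + spec.ghost_fraction * np.roll(img, shift, axis=axis)


def render_noise_free(spec: PhantomSpec) -> tuple[list[np.ndarray], dict[str, int]]:
    """Noise-free (but ghosted) images for all slices plus the role mapping."""
    role_map = spec.role_map()
    by_index: dict[int, list[str]] = {}
    for role, idx in role_map.items():
        by_index.setdefault(idx, []).append(role)
    images = []
    for i in range(len(spec.locations)):
        img = _render_slice_noise_free(spec, tuple(by_index.get(i, ())))
        images.append(_apply_ghost(spec, img))
    return images, role_map


# --- sidecar expectations --------------------------------------------------------


def _clipped_noise_mean(a: np.ndarray, sigma: float) -> np.ndarray:
    """E[max(0, a + sigma*N)] for Gaussian N — what a magnitude-convention
    (clipped) pixel is expected to read in a region of noise-free value a."""
    if sigma <= 0:
        return np.maximum(a, 0.0)
    z = a / sigma
    from scipy.stats import norm

    return a * norm.cdf(z) + sigma * norm.pdf(z)


def _expected_piu(spec: PhantomSpec, img: np.ndarray) -> float:
    frame = spec.frame()
    r200 = np.sqrt(layout.UNIFORMITY_CIRCLE_CM2 * 100.0 / np.pi)
    r1 = np.sqrt(layout.UNIFORMITY_ROI_CM2 * 100.0 / np.pi)
    kernel = _coverage_kernel(r1, spec.pixel_spacing_row_mm, spec.pixel_spacing_col_mm)
    local = ndimage.convolve(img, kernel, mode="constant", cval=0.0)
    rr = (np.arange(img.shape[0]) - frame.centroid_row) * spec.pixel_spacing_row_mm
    cc = (np.arange(img.shape[1]) - frame.centroid_col) * spec.pixel_spacing_col_mm
    dist = np.hypot(rr[:, None], cc[None, :])
    valid = dist <= (r200 - r1)
    s_max = float(local[valid].max())
    s_min = float(local[valid].min())
    return formulas.integral_uniformity(s_max, s_min)


def _expected_gr(spec: PhantomSpec, img: np.ndarray) -> tuple[float, float]:
    """(signed, |GR|) percent expected from replica/ROI overlap, including the
    analytic mean of clipped Gaussian background noise."""
    frame = spec.frame()
    sp_r, sp_c = spec.pixel_spacing_row_mm, spec.pixel_spacing_col_mm
    R = layout.PHANTOM_RADIUS_MM * spec.scale
    cr_mm = (frame.centroid_row + 0.5) * sp_r
    cc_mm = (frame.centroid_col + 0.5) * sp_c
    bbox = (cr_mm - R, cr_mm + R, cc_mm - R, cc_mm + R)
    rois = ghost_roi_rects(img.shape, frame, bbox)
    if rois is None:
        raise ValueError("ghost ROIs do not fit the requested FOV")
    expect = _clipped_noise_mean(img, spec.noise_sigma)
    means = {s: float(expect[r0:r1, c0:c1].mean())
             for s, (r0, r1, c0, c1) in rois.items()}
    r200 = np.sqrt(layout.UNIFORMITY_CIRCLE_CM2 * 100.0 / np.pi)
    rr = (np.arange(img.shape[0]) - frame.centroid_row) * sp_r
    cc = (np.arange(img.shape[1]) - frame.centroid_col) * sp_c
    circle = np.hypot(rr[:, None], cc[None, :]) <= r200
    s_mean = float(expect[circle].mean())
    if spec.pe_numpy_axis == 1:
        fe, pe = ("top", "bottom"), ("left", "right")
    else:
        fe, pe = ("left", "right"), ("top", "bottom")
    gr = formulas.ghosting_ratio(
        means[fe[0]], means[fe[1]], means[pe[0]], means[pe[1]], s_mean
    ) * 100.0
    return gr, abs(gr)


def _distinct_peaks_dp(profile: np.ndarray, depth: float = 0.25) -> int:
    """Independent peak counter: largest chain of local maxima in which every
    adjacent chosen pair is separated by a valley at least ``depth`` deep
    (profile normalized to unit peak-to-valley range)."""
    p = np.asarray(profile, dtype=float)
    rng = p.max() - p.min()
    if rng <= 0:
        return 0
    p = (p - p.min()) / rng
    maxima = [i for i in range(1, len(p) - 1)
              if (p[i] >= p[i - 1] and p[i] > p[i + 1])
              or (p[i] > p[i - 1] and p[i] >= p[i + 1])]
    best = [1] * len(maxima)
    for j in range(len(maxima)):
        for i in range(j):
            valley = p[maxima[i]:maxima[j] + 1].min()
            if min(p[maxima[i]], p[maxima[j]]) - valley >= depth:
                best[j] = max(best[j], best[i] + 1)
    return max(best, default=0)


def _expected_hcsr(spec: PhantomSpec, s1_img: np.ndarray) -> dict[str, Optional[float]]:
    """Resolvable hole sizes judged on the noise-free render at the exact
    geometry (partial volume at the acquisition matrix decides resolvability,
    so there is no closed form — the render itself is the ground truth)."""
    frame = spec.frame()
    slc = SliceImage(
        pixels=s1_img,
        pixel_spacing_row_mm=spec.pixel_spacing_row_mm,
        pixel_spacing_col_mm=spec.pixel_spacing_col_mm,
        slice_location_mm=0.0,
        nominal_thickness_mm=spec.slice_thickness_mm,
    )
    out: dict[str, Optional[float]] = {}
    for key, direction in (("lr", "horiz"), ("ap", "vert")):
        resolved = [
            size for size in layout.RES_SIZES_MM
            if any(_distinct_peaks_dp(p) >= 4
                   for p in _hole_profiles(slc, frame, size, direction))
        ]
        out[key] = min(resolved) if resolved else None
    return out


def expected_metrics(
    spec: PhantomSpec, images: Optional[list[np.ndarray]] = None,
    role_map: Optional[dict[str, int]] = None,
    piu_role: str = "S7",
) -> dict:
    """GroundTruthSidecar: generated parameters plus expected metric values."""
    if images is None:
        images, role_map = render_noise_free(spec)
    gd = 100.0 * (1.0 - spec.scale)
    lcd_per_slice = {}
    for role in ("S8", "S9", "S10", "S11"):
        c = spec.spoke_contrast_pct.get(role, 0.0)
        n = spec.spokes_rendered.get(role, layout.SPOKE_COUNT)
        lcd_per_slice[role] = int(n) if c > 0 else 0
    sidecar = {
        "spec": _spec_to_dict(spec),
        "expected": {
            "gd_pct": {str(a): gd for a in (0.0, 90.0, 45.0, -45.0)},
            "delta_sp_mm": {
                role: 2.0 * d * spec.scale
                for role, d in spec.bar_displacement_mm.items()
            },
            "displacement_mm": {
                role: d * spec.scale
                for role, d in spec.bar_displacement_mm.items()
            },
            "st_mm": spec.true_slice_thickness_mm * spec.scale,
            "piu_pct": _expected_piu(spec, images[role_map[piu_role]]),
            "lcd_per_slice": lcd_per_slice,
            "lcd_total": int(sum(lcd_per_slice.values())),
        },
    }
    gr_signed, gr_abs = _expected_gr(spec, images[role_map[piu_role]])
    sidecar["expected"]["gr_signed_pct"] = gr_signed
    sidecar["expected"]["gr_abs_pct"] = gr_abs
    hc = _expected_hcsr(spec, images[role_map["S1"]])
    sidecar["expected"]["hcsr_lr_mm"] = hc["lr"]
    sidecar["expected"]["hcsr_ap_mm"] = hc["ap"]
    return sidecar


def _spec_to_dict(spec: PhantomSpec) -> dict:
    d = asdict(spec)
    d["translation_px"] = list(d["translation_px"])
    return d


# --- generation ------------------------------------------------------------------


def _quantize(img: np.ndarray) -> np.ndarray:
    """Mimic the uint16/RescaleSlope storage of the DICOM writer exactly."""
    return np.clip(np.round(img / RESCALE_SLOPE), 0, 65535) * RESCALE_SLOPE


def generate_slices(
    spec: PhantomSpec, piu_role: str = "S7"
) -> tuple[list[SliceImage], SeriesMeta, dict]:
    """In-memory synthetic series (identical pixel values to the DICOM path)
    plus its ground-truth sidecar.  Deterministic given the spec seed."""
    images, role_map = render_noise_free(spec)
    sidecar = expected_metrics(spec, images, role_map, piu_role=piu_role)
    slices = []
    for i, (loc, img) in enumerate(zip(spec.locations, images)):
        if spec.noise_sigma > 0:
            rng = np.random.default_rng([spec.seed, i])
            img = img + rng.normal(0.0, spec.noise_sigma, img.shape)
        img = _quantize(np.clip(img, 0.0, None))
        slices.append(SliceImage(
            pixels=img,
            pixel_spacing_row_mm=spec.pixel_spacing_row_mm,
            pixel_spacing_col_mm=spec.pixel_spacing_col_mm,
            slice_location_mm=loc,
            nominal_thickness_mm=spec.slice_thickness_mm,
            acquisition_label=spec.sequence_name,
        ))
    sidecar["role_map"] = {r: int(i) for r, i in role_map.items()}
    return slices, spec.meta(), sidecar


def generate_series(
    spec: PhantomSpec, out_dir, piu_role: str = "S7"
) -> tuple[list[Path], Path, dict]:
    """Render and write a DICOM series plus its JSON sidecar next to it."""
    out = Path(out_dir)
    slices, meta, sidecar = generate_slices(spec, piu_role=piu_role)
    paths = write_series(slices, meta, out, rescale_slope=RESCALE_SLOPE)
    sidecar_path = out / "ground_truth.json"
    sidecar_path.write_text(json.dumps(sidecar, indent=2) + "\n")
    return paths, sidecar_path, sidecar
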