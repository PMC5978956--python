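"""The four-stage analysis pipeline: DICOM processing -> image recognition ->
parameter calculation -> results record.

`analyze_series` turns a sorted series into a QAReport containing the seven
parameters: geometric distortion at four angles on S1 and S5, slice position
on S1/S11, slice thickness on S1, uniformity and ghosting on the uniform slice
(S7 by default, S5 selectable), resolution on S1 and low-contrast spokes on
S8-S11.  A metric whose insert cannot be located is reported not-evaluated,
never silently zero.
"""

from __future__ import annotations

import logging
from typing import Optional

from . import metrics
from .criteria import default_criteria
from .recognition import classify_slices, locate_features, segment_phantom
from .types import MetricResult, QAReport, SeriesMeta, SliceImage

__all__ = ["analyze_series", "analyze_directory"]

log = logging.getLogger("acrqa")

TOOL_VERSION = "0.1.0"

HCSR_UNRESOLVED_SENTINEL = 1.2  # one step above the coarsest tested size


def _metric(name, value, units="", display="", provenance=None) -> MetricResult:
    return MetricResult(
        name=name,
        value=value,
        units=units,
        display=display,
        passed="not-evaluated" if value is None else "pass",
        provenance=provenance or {},
    )


def analyze_series(
    slices: list[SliceImage],
    meta: SeriesMeta,
    protocol: str = "acr_standard",
    criteria: Optional[dict] = None,
    piu_slice: str = "S7",
    review_mode: bool = False,
    hcsr_overrides: Optional[dict] = None,
    lcd_overrides: Optional[dict] = None,
) -> QAReport:
    """Run the full semiautomatic analysis and evaluate criteria."""
    if criteria is None:
        criteria = default_criteria()
    masks = [segment_phantom(s) for s in slices]
    roles = classify_slices(slices, meta, masks)
    log.info("slice roles: %s (direction %+d)", roles.roles, roles.direction)

    feats = {}
    for role in ("S1", "S8", "S9", "S10", "S11"):
        idx = roles[role]
        feats[role] = locate_features(slices[idx], role, masks[idx])

    results: list[MetricResult] = []

    # geometric distortion on S1 and S5
    angle_names = {0.0: "0", 90.0: "90", 45.0: "p45", -45.0: "m45"}
    for role in ("S1", "S5"):
        idx = roles[role]
        dset = metrics.measure_diameters(slices[idx], masks[idx])
        gd = metrics.percent_geometric_distortion(dset)
        for ang, name in angle_names.items():
            prov = {"angle_deg": ang, "slice": role,
                    "measured_mm": dset.measured_mm[ang],
                    "actual_mm": dset.actual_mm}
            results.append(_metric(
                f"gd_{role.lower()}_{name}", gd[ang], units="%", provenance=prov
            ))

    # slice position on S1 and S11
    for role in ("S1", "S11"):
        idx = roles[role]
        bars = metrics.slice_position_error(slices[idx], feats[role])
        if bars is None:
            results.append(_metric(f"sp_{role.lower()}", None, units="mm"))
        else:
            sense = "superior" if bars.displacement_mm > 0 else (
                "inferior" if bars.displacement_mm < 0 else "centred")
            results.append(_metric(
                f"sp_{role.lower()}", bars.displacement_mm, units="mm",
                display=f"{bars.displacement_mm:+.2f} mm ({sense})",
                provenance={"left_bar_mm": bars.left_bar_mm,
                            "right_bar_mm": bars.right_bar_mm,
                            "delta_sp_mm": bars.delta_sp_mm},
            ))

    # slice thickness on S1
    i1 = roles["S1"]
    sigma = metrics.background_sigma(slices[i1], masks[i1])
    st = metrics.slice_thickness(slices[i1], feats["S1"], noise_sigma=sigma)
    if st is None:
        results.append(_metric("st", None, units="mm"))
    else:
        st_mm, ramps = st
        results.append(_metric(
            "st", st_mm, units="mm",
            provenance={"top_mm": ramps.top_mm, "bottom_mm": ramps.bottom_mm},
        ))

    # uniformity and ghosting on the uniform slice
    iu = roles[piu_slice]
    unif = metrics.compute_piu(slices[iu], masks[iu])
    if unif is None:
        results.append(_metric("piu", None, units="%"))
    else:
        results.append(_metric(
            "piu", unif.piu, units="%",
            provenance={"slice": piu_slice, "s_max": unif.s_max,
                        "s_min": unif.s_min,
                        "max_center_px": list(unif.max_center_px),
                        "min_center_px": list(unif.min_center_px)},
        ))
    ghost = metrics.ghosting_ratio(slices[iu], masks[iu], meta)
    if ghost is None:
        results.append(_metric("gr", None, units="%"))
    else:
        log.info("ghost ROIs: %s", ghost.rois)
        results.append(_metric(
            "gr", ghost.gr_abs_pct, units="%",
            provenance={"slice": piu_slice, "signed_pct": ghost.gr_signed_pct,
                        "roi_means": ghost.means,
                        "phantom_mean": ghost.phantom_mean,
                        "rois": {k: list(v) for k, v in ghost.rois.items()}},
        ))

    # high-contrast resolution on S1
    hres = metrics.hcsr(
        slices[i1], feats["S1"],
        mode="review" if review_mode else "auto",
        overrides=hcsr_overrides,
    )
    if hres is None:
        results.append(_metric("hcsr_lr", None, units="mm"))
        results.append(_metric("hcsr_ap", None, units="mm"))
    else:
        for key, val in (("hcsr_lr", hres.resolved_lr_mm),
                         ("hcsr_ap", hres.resolved_ap_mm)):
            results.append(_metric(
                key,
                HCSR_UNRESOLVED_SENTINEL if val is None else val,
                units="mm",
                display=hres.format_value(val),
                provenance={
                    "per_block": {f"{s}mm/{d}": bool(ok)
                                  for (s, d), ok in hres.per_block.items()},
                    "overridden": {f"{s}mm/{d}": v
                                   for (s, d), v in hres.overridden.items()},
                },
            ))

    # low-contrast detectability on S8-S11
    wheels = {r: (slices[roles[r]], feats[r]) for r in ("S8", "S9", "S10", "S11")}
    lres = metrics.lcd(
        wheels, mode="review" if review_mode else "auto",
        overrides=lcd_overrides,
    )
    results.append(_metric(
        "lcd", None if lres.total is None else float(lres.total),
        units="spokes",
        provenance={"per_slice": lres.spokes_per_slice,
                    "contrast_pct": lres.contrast_labels,
                    "overridden": lres.overridden},
    ))

    nominal = slices[0].nominal_thickness_mm
    metrics.evaluate_criteria(results, criteria, nominal_thickness_mm=nominal)

    report = QAReport(
        series={
            "sequence_name": meta.sequence_name,
            "coil_name": meta.coil_name,
            "fov_mm": meta.fov_mm,
            "matrix": [meta.matrix_rows, meta.matrix_cols],
            "phase_encode_axis": meta.phase_encode_axis,
            "n_slices": len(slices),
            "piu_slice": piu_slice,
            "slice_roles": {r: int(i) for r, i in roles.roles.items()},
        },
        protocol=protocol,
        criteria_id="default" if criteria is default_criteria() else "custom",
        tool_version=TOOL_VERSION,
        metrics=results,
    )
    return report


def analyze_directory(
    path,
    protocol: str = "acr_standard",
    criteria: Optional[dict] = None,
    piu_slice: str = "S7",
    phase_encode_axis: Optional[str] = None,
    **kwargs,
) -> QAReport:
    """Read a DICOM directory and analyze it."""
    from .io import read_series

    slices, meta = read_series(path, phase_encode_axis=phase_encode_axis)
    return analyze_series(
        slices, meta, protocol=protocol, criteria=criteria,
        piu_slice=piu_slice, **kwargs,
    )
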