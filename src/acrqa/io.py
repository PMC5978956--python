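"""DICOM series reading, synthetic series writing, and report serialization.

Reading applies the DICOM rescale slope/intercept when present and never
applies window/level: the uniformity and ghosting parameters are ratios of raw
means, so stored values must pass through untouched otherwise.
"""

from __future__ import annotations

import json
import os
from pathlib import Path

import numpy as np
import pydicom
from pydicom.dataset import Dataset, FileDataset, FileMetaDataset
from pydicom.uid import ExplicitVRLittleEndian, generate_uid

from .types import QAReport, SeriesMeta, SeriesReadError, SliceImage

__all__ = [
    "read_series",
    "write_series",
    "write_report",
    "read_report",
    "report_to_csv",
]

MR_IMAGE_STORAGE = "1.2.840.10008.5.1.4.1.1.4"

_PE_MAP = {"ROW": "row", "COL": "col", "COLUMN": "col"}


def _read_one(path: Path) -> pydicom.Dataset:
    try:
        ds = pydicom.dcmread(str(path))
        ds.pixel_array  # force decode so unsupported compression fails here
        return ds
    except Exception as exc:  # noqa: BLE001 - rewrap with file context
        raise SeriesReadError(f"cannot read DICOM file {path}: {exc}") from exc


def read_series(
    path: str | os.PathLike,
    phase_encode_axis: str | None = None,
) -> tuple[list[SliceImage], SeriesMeta]:
    """Read a directory of single-frame axial DICOM files as one series.

    Slices are returned sorted by slice location ascending regardless of file
    naming.  ``phase_encode_axis`` overrides (or supplies, when the header
    lacks it) the phase-encode direction; without either, reading fails
    because the ghosting ratio is undefined.
    """
    directory = Path(path)
    files = sorted(p for p in directory.iterdir() if p.is_file())
    datasets = []
    for p in files:
        try:
            if not pydicom.misc.is_dicom(str(p)):
                continue
        except Exception:
            continue
        datasets.append((p, _read_one(p)))
    if not datasets:
        raise SeriesReadError(f"no DICOM files found in {directory}")

    uids = sorted({str(getattr(ds, "SeriesInstanceUID", "")) for _, ds in datasets})
    if len(uids) > 1:
        raise SeriesReadError(
            "directory mixes multiple series: " + ", ".join(uids)
        )

    slices = []
    for p, ds in datasets:
        spacing = getattr(ds, "PixelSpacing", None)
        if spacing is None:
            raise SeriesReadError(f"{p}: missing PixelSpacing")
        loc = getattr(ds, "SliceLocation", None)
        if loc is None:
            ipp = getattr(ds, "ImagePositionPatient", None)
            if ipp is None:
                raise SeriesReadError(f"{p}: missing SliceLocation")
            loc = ipp[2]
        slope = float(getattr(ds, "RescaleSlope", 1.0))
        intercept = float(getattr(ds, "RescaleIntercept", 0.0))
        pixels = ds.pixel_array.astype(float) * slope + intercept
        slices.append(
            SliceImage(
                pixels=pixels,
                pixel_spacing_row_mm=float(spacing[0]),
                pixel_spacing_col_mm=float(spacing[1]),
                slice_location_mm=float(loc),
                nominal_thickness_mm=float(getattr(ds, "SliceThickness", 0.0)),
                acquisition_label=str(getattr(ds, "SeriesDescription", "")),
            )
        )
    order = np.argsort([s.slice_location_mm for s in slices], kind="stable")
    slices = [slices[i] for i in order]

    ds0 = datasets[0][1]
    pe_header = _PE_MAP.get(
        str(getattr(ds0, "InPlanePhaseEncodingDirection", "")).upper()
    )
    pe = phase_encode_axis or pe_header
    if pe is None:
        raise SeriesReadError(
            "phase-encode direction missing from headers; pass "
            "phase_encode_axis='row' or 'col' explicitly"
        )
    rows, cols = slices[0].shape
    fov = rows * slices[0].pixel_spacing_row_mm
    meta = SeriesMeta(
        sequence_name=str(getattr(ds0, "SeriesDescription", "")),
        coil_name=str(getattr(ds0, "ReceiveCoilName", "")),
        fov_mm=float(fov),
        matrix_rows=rows,
        matrix_cols=cols,
        phase_encode_axis=pe,
    )
    return slices, meta


def write_series(
    slices: list[SliceImage],
    meta: SeriesMeta,
    out_dir: str | os.PathLike,
    rescale_slope: float = 0.1,
) -> list[Path]:
    """Write slices as an explicit-VR little-endian MR DICOM series.

    Intensities are stored as uint16 with the given RescaleSlope (intercept 0);
    negative values are clipped, matching magnitude-image conventions.
    Geometry fields round-trip losslessly through ``read_series``.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    series_uid = generate_uid(entropy_srcs=[meta.sequence_name, "acrqa-series"])
    study_uid = generate_uid(entropy_srcs=[meta.sequence_name, "acrqa-study"])
    pe_tag = "ROW" if meta.phase_encode_axis == "row" else "COL"
    paths = []
    for i, s in enumerate(slices):
        stored = np.clip(np.round(s.pixels / rescale_slope), 0, 65535).astype(
            np.uint16
        )
        file_meta = FileMetaDataset()
        file_meta.MediaStorageSOPClassUID = MR_IMAGE_STORAGE
        file_meta.MediaStorageSOPInstanceUID = generate_uid(
            entropy_srcs=[meta.sequence_name, f"inst{i}"]
        )
        file_meta.TransferSyntaxUID = ExplicitVRLittleEndian

        ds = FileDataset(None, Dataset(), file_meta=file_meta, preamble=b"\0" * 128)
        ds.SOPClassUID = MR_IMAGE_STORAGE
        ds.SOPInstanceUID = file_meta.MediaStorageSOPInstanceUID
        ds.Modality = "MR"
        ds.SeriesInstanceUID = series_uid
        ds.StudyInstanceUID = study_uid
        ds.SeriesDescription = s.acquisition_label or meta.sequence_name
        ds.ReceiveCoilName = meta.coil_name
        ds.InPlanePhaseEncodingDirection = pe_tag
        ds.InstanceNumber = i + 1
        ds.ImageOrientationPatient = [1, 0, 0, 0, 1, 0]
        ds.ImagePositionPatient = [0.0, 0.0, float(s.slice_location_mm)]
        ds.SliceLocation = f"{s.slice_location_mm:.6f}"
        ds.SliceThickness = f"{s.nominal_thickness_mm:.6f}"
        ds.PixelSpacing = [
            f"{s.pixel_spacing_row_mm:.10g}",
            f"{s.pixel_spacing_col_mm:.10g}",
        ]
        ds.Rows, ds.Columns = stored.shape
        ds.SamplesPerPixel = 1
        ds.PhotometricInterpretation = "MONOCHROME2"
        ds.BitsAllocated = 16
        ds.BitsStored = 16
        ds.HighBit = 15
        ds.PixelRepresentation = 0
        ds.RescaleSlope = f"{rescale_slope:.10g}"
        ds.RescaleIntercept = "0"
        ds.PixelData = stored.tobytes()
        p = out / f"slice_{i:03d}.dcm"
        ds.save_as(str(p), enforce_file_format=True)
        paths.append(p)
    return paths


# --- reports ------------------------------------------------------------------


def write_report(report: QAReport, path: str | os.PathLike, format: str = "json"):
    """Serialize a report; JSON round-trips bit-exactly and is deterministic."""
    path = Path(path)
    if format == "json":
        text = json.dumps(report.to_dict(), indent=2, sort_keys=False)
        path.write_text(text + "\n")
    elif format == "csv":
        report_to_csv(report).to_csv(path, index=False)
    else:
        raise ValueError(f"unknown report format: {format}")
    return path


def read_report(path: str | os.PathLike) -> QAReport:
    with open(path) as fh:
        return QAReport.from_dict(json.load(fh))


def report_to_csv(report: QAReport):
    """Flat one-row-per-metric table (pandas DataFrame)."""
    import pandas as pd

    rows = []
    for m in report.metrics:
        rows.append(
            {
                "metric": m.name,
                "value": m.value,
                "units": m.units,
                "criterion": m.criterion,
                "pass": m.passed,
                "display": m.display,
            }
        )
    return pd.DataFrame(rows, columns=["metric", "value", "units", "criterion", "pass", "display"])
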