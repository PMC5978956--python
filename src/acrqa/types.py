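"""Core in-memory model: slices, series metadata, metric results, reports.

Coordinate convention used throughout the package: images are indexed
``[row, col]``, 0-based, pixel-center addressing.  The row index increases
anterior -> posterior ("down" in the displayed image), the column index
left -> right.  All physical measurements are in millimetres and are computed
per-axis so non-square pixels are supported.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Optional

import numpy as np

__all__ = [
    "SliceImage",
    "SeriesMeta",
    "MetricResult",
    "QAReport",
    "SeriesReadError",
    "PhantomNotFoundError",
    "RecognitionError",
]


class SeriesReadError(ValueError):
    """Raised when a DICOM directory cannot be read as one axial series."""


class PhantomNotFoundError(ValueError):
    """Raised when no (or no unique) phantom candidate is found on a slice."""


class RecognitionError(ValueError):
    """Raised when slice roles cannot be established."""


@dataclass
class SliceImage:
    """One axial slice with its physical geometry.

    pixels holds intensities in arbitrary scanner units after DICOM rescale
    slope/intercept; they must be finite and non-negative.
    """

    pixels: np.ndarray
    pixel_spacing_row_mm: float
    pixel_spacing_col_mm: float
    slice_location_mm: float
    nominal_thickness_mm: float
    acquisition_label: str = ""

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixels.ndim != 2 or self.pixels.size == 0:
            raise ValueError("pixels must be a non-empty 2-D array")
        if not (self.pixel_spacing_row_mm > 0 and self.pixel_spacing_col_mm > 0):
            raise ValueError("pixel spacings must be > 0")
        if not np.all(np.isfinite(self.pixels)):
            raise ValueError("pixel intensities must be finite")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


@dataclass
class SeriesMeta:
    """Acquisition metadata shared by all slices of one series.

    phase_encode_axis names the image axis the phase-encode direction lies
    along: "row" means PE runs along image rows (horizontal, i.e. varying
    column index, numpy axis 1); "col" means PE runs down the columns
    (numpy axis 0).  Ghosts replicate along this direction.
    """

    sequence_name: str = ""
    coil_name: str = ""
    fov_mm: float = 0.0
    matrix_rows: int = 0
    matrix_cols: int = 0
    phase_encode_axis: str = "row"

    def __post_init__(self) -> None:
        if self.phase_encode_axis not in ("row", "col"):
            raise ValueError(
                "phase_encode_axis must be 'row' or 'col' "
                "(unknown from header: supply a config override)"
            )

    @property
    def pe_numpy_axis(self) -> int:
        """Numpy axis index along which ghosts replicate."""
        return 1 if self.phase_encode_axis == "row" else 0


@dataclass
class MetricResult:
    """One named QA parameter with its criterion outcome.

    passed is tri-state: "pass" / "fail" / "not-evaluated" (value absent),
    plus "no-criterion" when a value exists but no criterion is configured.
    """

    name: str
    value: Optional[float]
    units: str = ""
    criterion: str = ""
    passed: str = "not-evaluated"
    display: str = ""
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if (self.value is None) != (self.passed == "not-evaluated"):
            raise ValueError("passed must be 'not-evaluated' iff value is absent")


@dataclass
class QAReport:
    """Full result set for one analyzed series; serializable to JSON/CSV."""

    series: dict = field(default_factory=dict)
    protocol: str = ""
    criteria_id: str = "default"
    tool_version: str = ""
    timestamp: Optional[str] = None  # null unless the caller stamps it
    metrics: list[MetricResult] = field(default_factory=list)

    @property
    def overall_pass(self) -> bool:
        evaluated = [m for m in self.metrics if m.passed in ("pass", "fail")]
        return all(m.passed == "pass" for m in evaluated)

    def metric(self, name: str) -> MetricResult:
        for m in self.metrics:
            if m.name == name:
                return m
        raise KeyError(name)

    def to_dict(self) -> dict:
        return {
            "series": dict(self.series),
            "protocol": self.protocol,
            "criteria_id": self.criteria_id,
            "tool_version": self.tool_version,
            "timestamp": self.timestamp,
            "overall_pass": self.overall_pass,
            "metrics": [asdict(m) for m in self.metrics],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "QAReport":
        rep = cls(
            series=dict(d.get("series", {})),
            protocol=d.get("protocol", ""),
            criteria_id=d.get("criteria_id", "default"),
            tool_version=d.get("tool_version", ""),
            timestamp=d.get("timestamp"),
        )
        for md in d.get("metrics", []):
            md = dict(md)
            md.pop("overall_pass", None)
            rep.metrics.append(MetricResult(**md))
        return rep
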