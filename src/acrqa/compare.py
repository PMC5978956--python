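"""Baseline comparison of QA reports across coils/sequences.

Commissioning establishes baseline values per (sequence, coil); routine QA
then tracks per-metric deltas against that baseline.  Deltas are only
meaningful between reports analyzed with the same protocol preset.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .types import QAReport

__all__ = ["BaselineTable", "compare_reports", "mean_metric"]


@dataclass
class BaselineTable:
    """Rows keyed by (sequence, coil); per-metric deltas vs the first report."""

    baseline_key: tuple[str, str]
    values: pd.DataFrame = field(default_factory=pd.DataFrame)
    deltas: pd.DataFrame = field(default_factory=pd.DataFrame)

    def to_csv(self, path) -> None:
        out = self.values.copy()
        delta = self.deltas.add_prefix("delta_")
        out = out.join(delta, how="left")
        out.to_csv(path)

    def to_text(self) -> str:
        lines = [
            f"baseline: sequence={self.baseline_key[0]!r} "
            f"coil={self.baseline_key[1]!r}",
            "",
            "values:",
            self.values.to_string(float_format=lambda v: f"{v:.2f}"),
            "",
            "deltas (report - baseline):",
            self.deltas.to_string(float_format=lambda v: f"{v:+.2f}"),
        ]
        return "\n".join(lines)


def _key(report: QAReport) -> tuple[str, str]:
    return (
        str(report.series.get("sequence_name", "")),
        str(report.series.get("coil_name", "")),
    )


def compare_reports(reports: list[QAReport]) -> BaselineTable:
    """Per-metric deltas (report minus baseline); the first report is the
    baseline.  For PIU the delta is directly the percentage-point difference.
    """
    if len(reports) < 2:
        raise ValueError("need at least two reports to compare")
    protocols = {r.protocol for r in reports}
    if len(protocols) > 1:
        raise ValueError(
            "reports use different protocol presets: " + ", ".join(sorted(protocols))
        )
    rows = {}
    for rep in reports:
        key = _key(rep)
        rows[key] = {m.name: m.value for m in rep.metrics}
    values = pd.DataFrame.from_dict(rows, orient="index")
    values.index = pd.MultiIndex.from_tuples(values.index,
                                             names=["sequence", "coil"])
    baseline = values.iloc[0]
    deltas = values.subtract(baseline, axis=1)
    return BaselineTable(baseline_key=_key(reports[0]), values=values,
                         deltas=deltas)


def mean_metric(reports: list[QAReport], name: str) -> float:
    """Mean of one metric across reports (e.g. mean PIU over sequences)."""
    vals = [r.metric(name).value for r in reports]
    if any(v is None for v in vals):
        raise ValueError(f"metric {name!r} not evaluated in every report")
    return float(sum(vals) / len(vals))
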