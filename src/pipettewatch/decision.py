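"""Rule-based final classification and human-readable reporting.

A frame is normal when every pipette slot has a detected liquid column and
every column is filled to at least the configured minimum level (50% by
default; the right value depends on camera distance and the task's tolerated
false-acceptance rate, so it is a config knob). A video inherits the verdict
of a decisive frame — by default the last post-anchor frame, where fills are
maximal and the rule is sharpest.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .config import PipelineConfig
from .features import PipetteState

__all__ = ["FrameReport", "rule_decision", "video_verdict", "render_report_table"]

VERDICT_NORMAL = "normal"
VERDICT_ANOMALY = "anomaly"


@dataclass(frozen=True)
class FrameReport:
    """Rule outcome for one frame; ``reasons`` is empty iff normal."""

    frame_index: int
    contour_count: int
    fills: tuple[float, ...]
    verdict: str
    reasons: tuple[str, ...]

    def to_dict(self) -> dict:
        return {
            "frame_index": self.frame_index,
            "contour_count": self.contour_count,
            "fill_percent": [round(100.0 * f, 1) for f in self.fills],
            "verdict": self.verdict,
            "reasons": list(self.reasons),
        }


def rule_decision(
    states: Sequence[PipetteState], config: PipelineConfig
) -> FrameReport:
    """Classify one frame: full contour count and every fill above threshold."""
    if len(states) != config.n_pipettes:
        raise ValueError(
            f"expected {config.n_pipettes} slot states, got {len(states)}"
        )
    contour_count = sum(s.box is not None for s in states)
    fills = tuple(s.fill for s in states)
    reasons: list[str] = []
    if contour_count != config.n_pipettes:
        reasons.append("count_mismatch")
    for slot, fill in enumerate(fills):
        if fill < config.fill_threshold:
            reasons.append(f"underfilled_slot {slot}")
    verdict = VERDICT_NORMAL if not reasons else VERDICT_ANOMALY
    return FrameReport(
        frame_index=states[0].frame_index if states else -1,
        contour_count=contour_count,
        fills=fills,
        verdict=verdict,
        reasons=tuple(reasons),
    )


def video_verdict(
    reports: Sequence[FrameReport],
    strategy: str = "last",
    persistence: int = 10,
    plateau_delta: float = 0.005,
) -> str:
    """Video-level verdict from the per-frame reports.

    ``last`` takes the verdict of the final report. ``plateau`` takes the
    verdict at the first frame where the median per-frame fill change over
    ``persistence`` frames falls below ``plateau_delta`` (aspiration has
    settled), falling back to the last frame if no plateau is found.
    """
    if not reports:
        raise ValueError("no post-anchor frame reports")
    if strategy == "last":
        return reports[-1].verdict
    if strategy == "plateau":
        fills = np.array([r.fills for r in reports], dtype=np.float64)
        deltas = np.abs(np.diff(fills, axis=0)).mean(axis=1)
        for t in range(len(deltas) - persistence + 1):
            if float(np.median(deltas[t : t + persistence])) < plateau_delta:
                return reports[t + 1].verdict
        return reports[-1].verdict
    raise ValueError(f"unknown strategy {strategy!r}; use 'last' or 'plateau'")


def render_report_table(report: FrameReport) -> str:
    """Plain-text per-pipette fill table for one frame."""
    lines = [
        f"frame {report.frame_index}: {report.verdict} "
        f"({report.contour_count} contours)"
    ]
    header = " | ".join(f"P{i + 1:>2}" for i in range(len(report.fills)))
    values = " | ".join(f"{100 * f:>3.0f}" for f in report.fills)
    lines.append(header)
    lines.append(values)
    if report.reasons:
        lines.append("reasons: " + ", ".join(report.reasons))
    return "\n".join(lines)


def write_reports(
    reports: Sequence[FrameReport], verdict: str, path: str | Path
) -> None:
    payload = {
        "video_verdict": verdict,
        "frames": [r.to_dict() for r in reports],
    }
    Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))
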