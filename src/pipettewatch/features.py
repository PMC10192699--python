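"""Per-slot pipette state and history-windowed feature vectors.

Each filtered contour box is summarised per pipette slot as (x, y, w, h,
fill), where fill = sqrt(area_contour / area_pipette) approximates how full
the pipette is: area_pipette is the slot's share of the ROI crop (crop height
times crop width / n_pipettes), and taking the square root converts the area
ratio back to a linear fill scale. Temporal context is added by concatenating
the previous ``h`` frames' per-slot tuples after the current frame's.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .selfcomp import ContourBox
from .video import Box

__all__ = [
    "PipetteGeometry",
    "PipetteState",
    "fill_ratio",
    "frame_states",
    "build_feature_vector",
    "video_feature_matrix",
    "write_feature_matrix",
]

FEATURES_PER_SLOT = 5  # x, y, w, h, fill


@dataclass(frozen=True)
class PipetteGeometry:
    """ROI crop geometry shared by all slots."""

    roi_box: Box
    n_pipettes: int

    def __post_init__(self) -> None:
        if self.n_pipettes <= 0:
            raise ValueError("n_pipettes must be positive")

    @property
    def slot_width(self) -> float:
        return self.roi_box.w / self.n_pipettes

    @property
    def area_pipette(self) -> float:
        """Nominal per-pipette area: crop height x slot width, in px^2."""
        return self.roi_box.h * self.slot_width


@dataclass(frozen=True)
class PipetteState:
    """One pipette at one frame: its contour box (if any) and fill fraction."""

    frame_index: int
    slot: int
    box: ContourBox | None
    fill: float

    def __post_init__(self) -> None:
        if self.box is None and self.fill != 0.0:
            raise ValueError("fill must be 0 when no box is present")


def fill_ratio(contour: ContourBox | None, geometry: PipetteGeometry) -> float:
    """sqrt(area_contour / area_pipette), clipped to [0, 1]; 0 when absent."""
    if contour is None:
        return 0.0
    return float(np.clip(np.sqrt(contour.area / geometry.area_pipette), 0.0, 1.0))


def frame_states(
    slot_boxes: Sequence[ContourBox | None],
    geometry: PipetteGeometry,
    frame_index: int,
) -> list[PipetteState]:
    """Per-slot states for one frame; absent slots get fill 0."""
    if len(slot_boxes) != geometry.n_pipettes:
        raise ValueError(
            f"expected {geometry.n_pipettes} slots, got {len(slot_boxes)}"
        )
    states = []
    for slot, contour in enumerate(slot_boxes):
        states.append(
            PipetteState(
                frame_index=frame_index,
                slot=slot,
                box=contour,
                fill=fill_ratio(contour, geometry),
            )
        )
    return states


def _slot_tuple(state: PipetteState | None) -> tuple[float, float, float, float, float]:
    if state is None or state.box is None:
        fill = 0.0 if state is None else state.fill
        return (0.0, 0.0, 0.0, 0.0, fill)
    b = state.box.box
    return (float(b.x), float(b.y), float(b.w), float(b.h), state.fill)


def build_feature_vector(
    states_by_frame: Sequence[Sequence[PipetteState]],
    t: int,
    h: int,
) -> np.ndarray:
    """Feature vector for frame ``t`` with ``h`` frames of history.

    Layout: current frame first, then t-1, ..., t-h; each frame block is the
    per-slot (x, y, w, h, fill) tuples. Frames before the start of the video
    contribute all-zero blocks, so the length is always (h+1)*5*n_pipettes.
    """
    if t < 0 or t >= len(states_by_frame):
        raise IndexError(f"frame {t} outside the available states")
    n = len(states_by_frame[t])
    parts: list[float] = []
    for back in range(h + 1):
        idx = t - back
        if idx < 0:
            parts.extend([0.0] * (FEATURES_PER_SLOT * n))
            continue
        for state in states_by_frame[idx]:
            parts.extend(_slot_tuple(state))
    return np.asarray(parts, dtype=np.float64)


def video_feature_matrix(
    states_by_frame: Sequence[Sequence[PipetteState]], h: int
) -> np.ndarray:
    """Stack feature vectors for every frame of one video."""
    return np.stack(
        [build_feature_vector(states_by_frame, t, h) for t in range(len(states_by_frame))]
    )


def write_feature_matrix(
    path: str | Path,
    matrices: Sequence[np.ndarray],
    labels: Sequence[np.ndarray],
    video_ids: Sequence[str],
) -> None:
    """Dump per-video feature matrices to one CSV: video_id, frame_index, label, f_*."""
    rows = []
    for vid, X, y in zip(video_ids, matrices, labels):
        df = pd.DataFrame(X, columns=[f"f_{j}" for j in range(X.shape[1])])
        df.insert(0, "label", np.asarray(y, dtype=int))
        df.insert(0, "frame_index", np.arange(X.shape[0]))
        df.insert(0, "video_id", vid)
        rows.append(df)
    pd.concat(rows, ignore_index=True).to_csv(path, index=False)
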