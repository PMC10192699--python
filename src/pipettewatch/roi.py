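"""Pipette-block ROI tracking, anchor-frame detection and cropping.

The pipeline needs, per frame, a bounding box around the row of pipettes and
the *anchor frame*: the first frame at which the block has descended onto the
liquid container and stabilised. From the anchor onward every frame is cropped
with one fixed, slightly expanded window so crops stay pixel-aligned for
differencing.

Boxes come from one of three sources: an external object detector via a
JSON-lines interchange file, a motion-based fallback (difference against the
first frame), or simulator ground truth.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from skimage import measure

from .config import PipelineConfig
from .video import Box, VideoSequence

__all__ = [
    "RoiTrack",
    "load_detections",
    "detect_roi_by_motion",
    "detect_anchor",
    "expand_box",
    "crop_sequence",
    "AnchorNotFoundError",
]


class AnchorNotFoundError(RuntimeError):
    """No frame satisfies the descended-and-stable anchor rule."""


@dataclass
class RoiTrack:
    """Per-frame optional pipette-block box with confidence, plus the anchor."""

    boxes: list[Box | None]
    scores: list[float] = field(default_factory=list)
    anchor_index: int | None = None
    source: str = "external"

    def __post_init__(self) -> None:
        if not self.scores:
            self.scores = [1.0 if b is not None else 0.0 for b in self.boxes]
        if len(self.scores) != len(self.boxes):
            raise ValueError("scores and boxes must have equal length")
        if self.anchor_index is not None and self.boxes[self.anchor_index] is None:
            raise ValueError("anchor frame has no box")

    def __len__(self) -> int:
        return len(self.boxes)

    @property
    def n_present(self) -> int:
        return sum(b is not None for b in self.boxes)

    @classmethod
    def from_ground_truth(cls, boxes) -> "RoiTrack":
        return cls(boxes=list(boxes), source="ground_truth")


def load_detections(path: str | Path, n_frames: int) -> RoiTrack:
    """Read a JSON-lines detection file into a track of length ``n_frames``.

    Each record carries frame_index, x, y, w, h, score. On duplicate frames
    the highest-score record wins; frames with no record get an absent box.
    """
    path = Path(path)
    best: dict[int, tuple[float, Box]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            try:
                rec = json.loads(line)
                t = int(rec["frame_index"])
                box = Box(int(rec["x"]), int(rec["y"]), int(rec["w"]), int(rec["h"]))
                score = float(rec["score"])
            except (KeyError, TypeError, ValueError, json.JSONDecodeError) as exc:
                raise ValueError(f"{path}:{lineno}: malformed detection record") from exc
            if not 0 <= t < n_frames:
                raise ValueError(
                    f"{path}:{lineno}: frame_index {t} outside [0, {n_frames})"
                )
            if t not in best or score > best[t][0]:
                best[t] = (score, box)
    if not best:
        raise ValueError(f"{path}: no detection records")
    boxes: list[Box | None] = [None] * n_frames
    scores = [0.0] * n_frames
    for t, (score, box) in best.items():
        boxes[t] = box
        scores[t] = score
    return RoiTrack(boxes=boxes, scores=scores, source="external")


def _grayscale(frame: np.ndarray) -> np.ndarray:
    return frame.astype(np.float64).mean(axis=-1)


def detect_roi_by_motion(video: VideoSequence, config: PipelineConfig) -> RoiTrack:
    """Motion fallback: largest changed region relative to the first frame.

    Per frame: absolute grayscale difference against frame 0, thresholded at
    ``diff_threshold``, cleaned by opening with ``kernel_size``, then the
    bounding box of the largest 8-connected foreground component. Frames with
    no foreground get an absent box.
    """
    if len(video) < 2:
        raise ValueError("motion ROI detection needs at least 2 frames")
    from .selfcomp import open_mask  # local import to avoid a cycle

    ref = _grayscale(video[0])
    boxes: list[Box | None] = [None]
    for t in range(1, len(video)):
        mask = np.abs(_grayscale(video[t]) - ref) > config.diff_threshold
        mask = open_mask(mask, config.kernel_size)
        if not mask.any():
            boxes.append(None)
            continue
        labels = measure.label(mask, connectivity=2)
        largest = max(measure.regionprops(labels), key=lambda r: r.area)
        y1, x1, y2, x2 = largest.bbox
        boxes.append(Box(int(x1), int(y1), int(x2 - x1), int(y2 - y1)))
    return RoiTrack(boxes=boxes, source="motion")


def detect_anchor(track: RoiTrack, config: PipelineConfig,
                  frame_height: int | None = None) -> int:
    """Find the first descended-and-stable frame and store it on the track.

    The block has descended once the box's top edge sits at least ``min_drop``
    pixels below its pre-descent baseline (the median y over frames before the
    first such excursion), and it is stable if the edge stays within
    ``drop_tolerance`` pixels for ``persistence`` consecutive frames, all of
    which must have boxes.
    """
    if track.n_present < config.persistence:
        raise ValueError(
            f"track has {track.n_present} boxes; need >= persistence "
            f"({config.persistence})"
        )
    if frame_height is None:
        present = [b for b in track.boxes if b is not None]
        frame_height = max(b.y2 for b in present)
    min_drop = config.resolved_min_drop(frame_height)

    y = np.array([np.nan if b is None else b.y for b in track.boxes], dtype=np.float64)
    n = len(y)

    # first frame whose top edge exceeds the running pre-descent median
    first_drop = None
    for t in range(1, n):
        prior = y[:t]
        prior = prior[~np.isnan(prior)]
        if prior.size == 0 or np.isnan(y[t]):
            continue
        if y[t] - np.median(prior) >= min_drop:
            first_drop = t
            break
    if first_drop is None:
        raise AnchorNotFoundError(
            f"no frame drops >= {min_drop}px below its pre-descent baseline"
        )
    prior = y[:first_drop]
    baseline = float(np.median(prior[~np.isnan(prior)]))

    for a in range(first_drop, n - config.persistence + 1):
        window = y[a : a + config.persistence]
        if np.isnan(window).any():  # absent boxes disqualify the window
            continue
        if y[a] - baseline < min_drop:
            continue
        if np.max(np.abs(window - y[a])) <= config.drop_tolerance:
            track.anchor_index = a
            return a
    raise AnchorNotFoundError(
        f"no window of {config.persistence} stable frames after the descent"
    )


def expand_box(box: Box, factor: float, frame_w: int, frame_h: int) -> Box:
    """Enlarge width and height by ``factor``, keep the center, clip to frame.

    The added margin is split symmetrically (an odd leftover pixel goes to
    the right/bottom). Clipping slides the box back inside the frame so its
    size is preserved whenever it fits; only a box larger than the frame is
    trimmed.
    """
    if factor < 0:
        raise ValueError("expansion factor must be >= 0")
    new_w = min(round(box.w * (1.0 + factor)), frame_w)
    new_h = min(round(box.h * (1.0 + factor)), frame_h)
    x = box.x - (new_w - box.w) // 2
    y = box.y - (new_h - box.h) // 2
    x = min(max(x, 0), frame_w - new_w)
    y = min(max(y, 0), frame_h - new_h)
    return Box(x, y, new_w, new_h)


def crop_sequence(
    video: VideoSequence, track: RoiTrack, config: PipelineConfig
) -> tuple[VideoSequence, Box]:
    """Crop all frames from the anchor onward with one fixed expanded window.

    A single window (the anchor frame's expanded box) keeps the crops
    pixel-aligned for differencing; the scene is static during the transfer
    phase, so per-frame re-cropping would only introduce jitter. Returns the
    cropped sequence and the window in full-frame coordinates.
    """
    if track.anchor_index is None:
        raise ValueError("track has no anchor; run detect_anchor first")
    anchor_box = track.boxes[track.anchor_index]
    if anchor_box is None:
        raise ValueError("anchor frame has no box")
    window = expand_box(
        anchor_box, config.expansion_factor, video.frame_width, video.frame_height
    )
    return video.crop(window, start=track.anchor_index), window
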