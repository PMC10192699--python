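"""Self-comparison: difference frames, cleanup and prior-knowledge filtering.

Every post-anchor ROI crop is differenced against the anchor crop; because
the scene is static during the transfer phase, the thresholded difference
foreground is (up to noise) exactly the moved liquid. Morphological opening
strips shake/ripple artifacts smaller than the structuring element; the
surviving connected components become candidate liquid-column boxes, filtered
by what is known about the rig: the number of pipettes, the columns' tall
aspect ratio, their fixed horizontal slots, and the fact that a filling
column only ever grows vertically. Finally the boxes' widths are snapped to
their median, exploiting the identical width of all pipettes.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
from scipy import ndimage
from skimage import measure

from .config import PipelineConfig
from .video import Box

__all__ = [
    "ContourBox",
    "diff_frame",
    "open_mask",
    "extract_contour_boxes",
    "filter_contours",
    "median_width_denoise",
]


@dataclass(frozen=True)
class ContourBox:
    """A connected difference-foreground component: tight box + pixel area."""

    box: Box
    area: int
    slot: int | None = None


def _grayscale(frame: np.ndarray) -> np.ndarray:
    frame = np.asarray(frame, dtype=np.float64)
    if frame.ndim == 3:
        return frame.mean(axis=-1)
    return frame


def diff_frame(crop: np.ndarray, anchor_crop: np.ndarray, threshold: float) -> np.ndarray:
    """Binarized absolute grayscale difference of a crop against the anchor."""
    crop = np.asarray(crop)
    anchor_crop = np.asarray(anchor_crop)
    if crop.shape != anchor_crop.shape:
        raise ValueError(
            f"crop shape {crop.shape} != anchor crop shape {anchor_crop.shape}"
        )
    return np.abs(_grayscale(crop) - _grayscale(anchor_crop)) > threshold


def open_mask(mask: np.ndarray, kernel_size: int) -> np.ndarray:
    """Morphological opening with a square structuring element.

    Erosion treats pixels outside the image as foreground and dilation as
    background, which keeps the operation anti-extensive and idempotent while
    not eating structures that merely touch the border.
    """
    if kernel_size < 1 or kernel_size % 2 == 0:
        raise ValueError(f"kernel_size must be odd and >= 1, got {kernel_size}")
    mask = np.asarray(mask, dtype=bool)
    if kernel_size == 1:
        return mask.copy()
    structure = np.ones((kernel_size, kernel_size), dtype=bool)
    eroded = ndimage.binary_erosion(mask, structure=structure, border_value=1)
    return ndimage.binary_dilation(eroded, structure=structure, border_value=0)


def extract_contour_boxes(mask: np.ndarray) -> list[ContourBox]:
    """Tight bounding box and pixel area of every 8-connected component.

    Components are returned in deterministic reading order (by box x, then y).
    """
    mask = np.asarray(mask, dtype=bool)
    labels = measure.label(mask, connectivity=2)
    boxes = []
    for region in measure.regionprops(labels):
        y1, x1, y2, x2 = region.bbox
        boxes.append(
            ContourBox(
                box=Box(int(x1), int(y1), int(x2 - x1), int(y2 - y1)),
                area=int(region.area),
            )
        )
    boxes.sort(key=lambda c: (c.box.x, c.box.y))
    return boxes


def filter_contours(
    boxes: Sequence[ContourBox],
    prev_states: Sequence,  # per-slot previous PipetteState (or None)
    config: PipelineConfig,
    crop_width: int,
) -> list[ContourBox | None]:
    """Apply the rig priors to candidate boxes; returns one box per slot.

    In order: (1) keep the n_pipettes largest components by area; (2) drop
    boxes flatter than ``r_min`` (height/width); (3) assign survivors to the
    equal-width slot containing their x-center, keeping the largest per slot;
    (4) drop a slot's box if its height fell more than ``growth_tolerance``
    below the slot's previous height — a filling column never shrinks.
    """
    n = config.n_pipettes
    if n <= 0:
        raise ValueError("n_pipettes must be positive")
    if len(prev_states) != n:
        raise ValueError(f"prev_states must have length {n}")

    ranked = sorted(boxes, key=lambda c: (-c.area, c.box.x, c.box.y))[:n]
    tall = [c for c in ranked if c.box.h / c.box.w >= config.r_min]

    slot_width = crop_width / n
    per_slot: list[ContourBox | None] = [None] * n
    for c in tall:
        slot = int(c.box.center[0] // slot_width)
        slot = min(max(slot, 0), n - 1)
        incumbent = per_slot[slot]
        if incumbent is None or c.area > incumbent.area:
            per_slot[slot] = replace(c, slot=slot)

    for slot in range(n):
        c = per_slot[slot]
        prev = prev_states[slot]
        if c is None or prev is None:
            continue
        prev_box = getattr(prev, "box", prev)
        if prev_box is None:
            continue
        prev_h = prev_box.box.h if isinstance(prev_box, ContourBox) else prev_box.h
        if c.box.h < prev_h - config.growth_tolerance:
            per_slot[slot] = None
    return per_slot


def median_width_denoise(
    slot_boxes: Sequence[ContourBox | None],
) -> list[ContourBox | None]:
    """Snap every present box's width to the median width across slots.

    All pipettes share one physical width, so the median of the detected
    widths estimates it robustly; each box keeps its x-center, height, area
    and slot. With an even count the central pair is averaged and rounded to
    the nearest integer. With no boxes present the input is returned as is.
    """
    present = [c for c in slot_boxes if c is not None]
    if not present:
        return list(slot_boxes)
    widths = sorted(c.box.w for c in present)
    k = len(widths)
    if k % 2 == 1:
        median_w = widths[k // 2]
    else:
        median_w = int(round((widths[k // 2 - 1] + widths[k // 2]) / 2.0))
    median_w = max(1, median_w)

    out: list[ContourBox | None] = []
    for c in slot_boxes:
        if c is None:
            out.append(None)
            continue
        cx = c.box.x + c.box.w / 2.0
        new_x = int(round(cx - median_w / 2.0))
        out.append(replace(c, box=Box(new_x, c.box.y, median_w, c.box.h)))
    return out
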