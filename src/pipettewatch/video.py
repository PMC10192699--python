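"""Video frames and pixel boxes.

Frames are 8-bit, 3-channel arrays in row-major (y, x) order; boxes use the
half-open pixel convention [x, x+w) x [y, y+h) with the origin at the top-left,
x increasing rightward (columns) and y downward (rows).
"""

from __future__ import annotations

import os
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterator

import imageio.v3 as iio
import numpy as np

__all__ = ["Box", "VideoSequence", "load_video"]

_FRAME_RE = re.compile(r"^frame_(\d+)\.png$")


@dataclass(frozen=True)
class Box:
    """Axis-aligned pixel rectangle, half-open on both axes."""

    x: int
    y: int
    w: int
    h: int

    def __post_init__(self) -> None:
        if self.w <= 0 or self.h <= 0:
            raise ValueError(f"box must have positive size, got w={self.w}, h={self.h}")

    @property
    def x2(self) -> int:
        return self.x + self.w

    @property
    def y2(self) -> int:
        return self.y + self.h

    @property
    def center(self) -> tuple[float, float]:
        return (self.x + self.w / 2.0, self.y + self.h / 2.0)

    @property
    def area(self) -> int:
        return self.w * self.h

    def clip(self, frame_w: int, frame_h: int) -> "Box":
        """Intersect with the frame rectangle; errors if nothing remains."""
        x1 = max(self.x, 0)
        y1 = max(self.y, 0)
        x2 = min(self.x2, frame_w)
        y2 = min(self.y2, frame_h)
        if x2 <= x1 or y2 <= y1:
            raise ValueError(f"box {self} lies outside a {frame_w}x{frame_h} frame")
        return Box(x1, y1, x2 - x1, y2 - y1)

    def contains(self, other: "Box") -> bool:
        return (
            self.x <= other.x
            and self.y <= other.y
            and self.x2 >= other.x2
            and self.y2 >= other.y2
        )

    def to_list(self) -> list[int]:
        return [self.x, self.y, self.w, self.h]


class VideoSequence:
    """Ordered stack of uniform 8-bit RGB frames, shape (n_frames, h, w, 3)."""

    def __init__(self, frames: np.ndarray, fps: float = 30.0):
        frames = np.asarray(frames)
        if frames.ndim != 4 or frames.shape[-1] != 3:
            raise ValueError(f"expected (n, h, w, 3) frames, got shape {frames.shape}")
        if frames.dtype != np.uint8:
            raise ValueError(f"frames must be uint8, got {frames.dtype}")
        self.frames = frames
        self.fps = float(fps)

    def __len__(self) -> int:
        return self.frames.shape[0]

    def __getitem__(self, index: int) -> np.ndarray:
        return self.frames[index]

    def __iter__(self) -> Iterator[np.ndarray]:
        return iter(self.frames)

    @property
    def frame_height(self) -> int:
        return self.frames.shape[1]

    @property
    def frame_width(self) -> int:
        return self.frames.shape[2]

    def crop(self, box: Box, start: int = 0) -> "VideoSequence":
        b = box.clip(self.frame_width, self.frame_height)
        return VideoSequence(
            self.frames[start:, b.y : b.y2, b.x : b.x2, :].copy(), fps=self.fps
        )

    def to_dir(self, path: str | os.PathLike) -> None:
        """Write frames as zero-padded PNGs frame_000000.png, ..."""
        out = Path(path)
        out.mkdir(parents=True, exist_ok=True)
        for i, frame in enumerate(self.frames):
            iio.imwrite(out / f"frame_{i:06d}.png", frame)

    @classmethod
    def from_dir(cls, path: str | os.PathLike, fps: float = 30.0) -> "VideoSequence":
        d = Path(path)
        entries = []
        for name in os.listdir(d):
            m = _FRAME_RE.match(name)
            if m:
                entries.append((int(m.group(1)), name))
        if not entries:
            raise FileNotFoundError(f"no frame_NNNNNN.png files in {d}")
        entries.sort()
        frames = np.stack([iio.imread(d / name) for _, name in entries])
        if frames.ndim == 3:  # grayscale source
            frames = np.repeat(frames[..., None], 3, axis=-1)
        return cls(frames[..., :3].astype(np.uint8), fps=fps)


def load_video(path: str | os.PathLike, fps: float = 30.0) -> VideoSequence:
    """Load a video from a frame directory (canonical) or a container file.

    Container decoding depends on an imageio plugin able to read the format;
    when none is available the error says so rather than failing obscurely.
    """
    p = Path(path)
    if p.is_dir():
        return VideoSequence.from_dir(p, fps=fps)
    if not p.exists():
        raise FileNotFoundError(f"video path does not exist: {p}")
    try:
        frames = np.stack(list(iio.imiter(p)))
    except Exception as exc:  # plugin- and format-dependent
        raise OSError(
            f"could not decode {p} as a video container (no suitable imageio "
            f"plugin?); convert it to a directory of frame_NNNNNN.png files"
        ) from exc
    return VideoSequence(frames[..., :3].astype(np.uint8), fps=fps)
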