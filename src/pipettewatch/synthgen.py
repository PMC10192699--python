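"""Synthetic liquid-transfer video generator with exact ground truth.

Renders a desk-scale emulation of an automated pipetting station: a static
background with distractor texture, an 8-pipette block that descends into the
scene and then rapidly aspirates colored liquid, plus optional acquisition
noise (sensor noise, camera shake, tub ripples). Because every pixel is
rendered from the scene model, the ground truth (anchor frame, per-frame ROI
box, per-pipette fill fraction, anomaly flags) is exact by construction.

Anomalies follow the two mechanisms seen on real stations: a *clogged tip*
lets almost no liquid in from the start, and a *bottom-out* (tip sealed
against the vessel bottom, creating a vacuum) stalls aspiration at a small
residual level. Both are rendered as a reduced liquid column, which is the
observable the detection pipeline keys on.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
from scipy import ndimage

from .config import AnomalySpec, SynthConfig
from .video import Box, VideoSequence

__all__ = [
    "GroundTruth",
    "SimulatedVideo",
    "generate_video",
    "generate_dataset",
    "write_ground_truth",
    "read_ground_truth",
    "write_detections",
    "inject_speckle",
    "LIQUID_PALETTE",
]

#: Liquid colors observed across runs: cyan, red, green, yellow.
LIQUID_PALETTE: tuple[tuple[int, int, int], ...] = (
    (0, 200, 200),
    (200, 0, 0),
    (0, 180, 0),
    (230, 230, 0),
)

LABEL_NORMAL = "normal"
LABEL_ANOMALY = "anomaly"


@dataclass(frozen=True)
class GroundTruth:
    """Exact per-video annotations produced by the renderer.

    fill_fraction[t][i] is the rendered liquid pixel count of slot i at frame
    t divided by the slot's column capacity (both in pixels), so it matches
    the drawn scene exactly.
    """

    anchor_index: int
    roi_boxes: tuple[Box, ...]
    fill_fraction: np.ndarray  # (n_frames, n_pipettes) float
    pipette_anomaly: tuple[str, ...]
    frame_labels: tuple[str, ...]
    video_label: str

    @property
    def n_frames(self) -> int:
        return len(self.roi_boxes)


@dataclass(frozen=True)
class SimulatedVideo:
    video: VideoSequence
    ground_truth: GroundTruth
    config: SynthConfig


def _block_top_at(config: SynthConfig, t: int) -> int:
    e = config.descent_end_frame
    progress = min(t, e) / e
    return config.block_top + round(config.descent_depth * progress)


def _liquid_heights(config: SynthConfig) -> np.ndarray:
    """Integer liquid-column height (rows) per frame and slot."""
    cap = config.column_capacity_px
    heights = np.zeros((config.n_frames, config.n_pipettes), dtype=np.int64)
    for i in range(config.n_pipettes):
        kind = config.anomaly_spec.kind_of(i)
        level = config.target_fill if kind == "none" else config.anomaly_spec.residual_of(i)
        h_cap = round(level * cap)
        for t in range(config.descent_end_frame, config.n_frames):
            grown = int(np.floor((t - config.descent_end_frame) * config.fill_rate))
            heights[t, i] = min(h_cap, grown)
    return heights


def _render_background(config: SynthConfig, rng: np.random.Generator) -> np.ndarray:
    bg = np.full(
        (config.frame_height, config.frame_width, 3),
        config.background_gray,
        dtype=np.uint8,
    )
    # static distractor texture: random gray patches plus a table edge line;
    # patch grays stay > diff_threshold away from every liquid/body intensity
    patch_grays = (25, 100)
    for _ in range(12):
        w = int(rng.integers(8, 40))
        h = int(rng.integers(8, 40))
        x = int(rng.integers(0, config.frame_width - w))
        y = int(rng.integers(0, config.frame_height - h))
        bg[y : y + h, x : x + w] = patch_grays[int(rng.integers(2))]
    table_row = min(config.frame_height - 4, config.block_top + config.descent_depth
                    + config.pipette_height + 16)
    bg[table_row : table_row + 2] = 70
    return bg


def _render_frame(
    config: SynthConfig, background: np.ndarray, t: int, heights: np.ndarray
) -> np.ndarray:
    frame = background.copy()
    top = _block_top_at(config, t)
    bottom = top + config.pipette_height
    # effector head bar: joins the pipettes above the ROI proper; it starts
    # above the frame and becomes visible as the block descends
    frame[max(0, top - config.bar_height) : top,
          config.block_left : config.block_left + config.block_width] = config.bar_color
    for i in range(config.n_pipettes):
        px = config.block_left + i * (config.pipette_width + config.pipette_spacing)
        frame[top:bottom, px : px + config.pipette_width] = config.body_color
        h_liq = int(heights[t, i])
        if h_liq > 0:
            frame[bottom - h_liq : bottom, px : px + config.pipette_width] = (
                config.liquid_color
            )
    return frame


def _apply_ripple(
    config: SynthConfig, frame: np.ndarray, t: int, phase: float
) -> np.ndarray:
    noise = config.noise
    if noise.ripple_amplitude <= 0 or t < config.descent_end_frame:
        return frame
    r0 = config.block_top + config.descent_depth + config.pipette_height + 1
    r1 = min(r0 + noise.ripple_rows, config.frame_height)
    if r1 <= r0:
        return frame
    x = np.arange(config.frame_width)
    wave = noise.ripple_amplitude * np.sin(2 * np.pi * (x / 40.0 - 0.13 * t) + phase)
    band = frame[r0:r1].astype(np.float64)
    band += wave[None, :, None]
    frame = frame.copy()
    frame[r0:r1] = np.clip(np.rint(band), 0, 255).astype(np.uint8)
    return frame


def _apply_shake(
    config: SynthConfig, frame: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    noise = config.noise
    # draws happen every frame so shake_prob only gates the effect, keeping
    # the stream alignment of later frames independent of earlier outcomes
    u = rng.random()
    dx = int(rng.integers(-noise.shake_max, noise.shake_max + 1))
    dy = int(rng.integers(-noise.shake_max, noise.shake_max + 1))
    if u >= noise.shake_prob or (dx == 0 and dy == 0):
        return frame
    return ndimage.shift(frame, (dy, dx, 0), order=0, mode="nearest")


def _apply_gaussian(
    config: SynthConfig, frame: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    sigma = config.noise.gaussian_sigma
    if sigma <= 0:
        return frame
    noisy = frame.astype(np.float64) + rng.normal(0.0, sigma, size=frame.shape)
    return np.clip(np.rint(noisy), 0, 255).astype(np.uint8)


def generate_video(config: SynthConfig) -> tuple[VideoSequence, GroundTruth]:
    """Render one video and its exact ground truth.

    One seeded stream per video, split into independent sub-streams per noise
    process, so toggling one noise source leaves the others' draws unchanged.
    """
    ss = np.random.SeedSequence(config.seed)
    tex_ss, gauss_ss, shake_ss, ripple_ss = ss.spawn(4)
    tex_rng = np.random.default_rng(tex_ss)
    gauss_rng = np.random.default_rng(gauss_ss)
    shake_rng = np.random.default_rng(shake_ss)
    ripple_phase = float(np.random.default_rng(ripple_ss).uniform(0, 2 * np.pi))

    background = _render_background(config, tex_rng)
    heights = _liquid_heights(config)
    cap = config.column_capacity_px

    frames = []
    roi_boxes = []
    for t in range(config.n_frames):
        frame = _render_frame(config, background, t, heights)
        frame = _apply_ripple(config, frame, t, ripple_phase)
        frame = _apply_shake(config, frame, shake_rng)
        frame = _apply_gaussian(config, frame, gauss_rng)
        frames.append(frame)
        roi_boxes.append(
            Box(config.block_left, _block_top_at(config, t),
                config.block_width, config.pipette_height)
        )

    anomalies = tuple(
        config.anomaly_spec.kind_of(i) for i in range(config.n_pipettes)
    )
    anomalous = any(k != "none" for k in anomalies)
    anchor = config.descent_end_frame
    frame_labels = tuple(
        LABEL_ANOMALY if anomalous and t >= anchor else LABEL_NORMAL
        for t in range(config.n_frames)
    )
    gt = GroundTruth(
        anchor_index=anchor,
        roi_boxes=tuple(roi_boxes),
        fill_fraction=heights.astype(np.float64) / cap,
        pipette_anomaly=anomalies,
        frame_labels=frame_labels,
        video_label=LABEL_ANOMALY if anomalous else LABEL_NORMAL,
    )
    return VideoSequence(np.stack(frames), fps=config.fps), gt


def generate_dataset(
    n_normal: int,
    n_anomalous: int,
    base_config: SynthConfig,
    seed: int,
) -> list[SimulatedVideo]:
    """Render a seeded mixed-class dataset.

    Anomalous videos draw their anomaly kind, affected-slot subset and liquid
    color from the dataset stream; normal videos vary only in liquid color.
    """
    if n_normal < 0 or n_anomalous < 0:
        raise ValueError("video counts must be >= 0")
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    videos: list[SimulatedVideo] = []
    flags = [False] * n_normal + [True] * n_anomalous
    for anomalous in flags:
        color = LIQUID_PALETTE[int(rng.integers(len(LIQUID_PALETTE)))]
        video_seed = int(rng.integers(0, 2**31 - 1))
        spec = AnomalySpec()
        if anomalous:
            kind = ("clogged", "bottom_out")[int(rng.integers(2))]
            n_bad = int(rng.integers(1, min(3, base_config.n_pipettes) + 1))
            slots = rng.choice(base_config.n_pipettes, size=n_bad, replace=False)
            spec = AnomalySpec(kinds={int(s): kind for s in sorted(slots)})
        cfg = replace(
            base_config, liquid_color=color, anomaly_spec=spec, seed=video_seed
        )
        video, gt = generate_video(cfg)
        videos.append(SimulatedVideo(video=video, ground_truth=gt, config=cfg))
    return videos


def write_ground_truth(gt: GroundTruth, path: str | Path) -> None:
    payload = {
        "anchor_index": gt.anchor_index,
        "roi_boxes": [b.to_list() for b in gt.roi_boxes],
        "fill_fraction": gt.fill_fraction.tolist(),
        "pipette_anomaly": list(gt.pipette_anomaly),
        "frame_labels": list(gt.frame_labels),
        "video_label": gt.video_label,
    }
    Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))


def read_ground_truth(path: str | Path) -> GroundTruth:
    payload = json.loads(Path(path).read_text())
    return GroundTruth(
        anchor_index=int(payload["anchor_index"]),
        roi_boxes=tuple(Box(*b) for b in payload["roi_boxes"]),
        fill_fraction=np.asarray(payload["fill_fraction"], dtype=np.float64),
        pipette_anomaly=tuple(payload["pipette_anomaly"]),
        frame_labels=tuple(payload["frame_labels"]),
        video_label=payload["video_label"],
    )


def write_detections(gt: GroundTruth, path: str | Path, score: float = 1.0) -> None:
    """Write the ground-truth ROI track in the detection interchange format.

    This is the ground-truth detection provider: it stands in for an external
    object detector when evaluating the downstream pipeline in isolation.
    """
    with open(path, "w") as fh:
        for t, box in enumerate(gt.roi_boxes):
            record = {"frame_index": t, "x": box.x, "y": box.y,
                      "w": box.w, "h": box.h, "score": score}
            fh.write(json.dumps(record) + "\n")


def inject_speckle(
    image: np.ndarray,
    rng: np.random.Generator,
    n_speckles: int = 30,
    max_px: int = 3,
    delta: int = 120,
) -> np.ndarray:
    """Scatter bright speckle clusters of at most ``max_px`` pixels each.

    Emulates the instantaneous artifacts a camera shake or refocus leaves in
    a difference frame; each cluster is a 1-pixel-thin bar so its pixel count
    never exceeds ``max_px``.
    """
    out = image.astype(np.int64).copy()
    h, w = image.shape[:2]
    for _ in range(n_speckles):
        size = int(rng.integers(1, max_px + 1))
        horizontal = bool(rng.integers(2))
        sh, sw = (1, size) if horizontal else (size, 1)
        y = int(rng.integers(0, h - sh + 1))
        x = int(rng.integers(0, w - sw + 1))
        out[y : y + sh, x : x + sw] += delta
    return np.clip(out, 0, 255).astype(np.uint8)
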