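"""Pipeline and simulator configuration.

All tunables of the detection pipeline live in :class:`PipelineConfig`; all
scene parameters of the synthetic liquid-transfer simulator live in
:class:`SynthConfig`. Both round-trip through YAML so a run is reproducible
from its config file plus a seed.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, replace
from pathlib import Path
from typing import Mapping

import yaml

__all__ = ["PipelineConfig", "NoiseConfig", "AnomalySpec", "SynthConfig"]


@dataclass(frozen=True)
class PipelineConfig:
    """Tunables of the ROI / self-comparison / feature / decision stages.

    expansion_factor
        Fractional enlargement of the detected pipette-block box (0.10 means
        10% wider and taller), guarding against detector jitter.
    persistence
        Number of consecutive stable frames required after the descent before
        a frame qualifies as the anchor.
    min_drop
        Minimum downward displacement (pixels) of the box top edge that counts
        as the descent; ``None`` means 5% of the frame height.
    drop_tolerance
        Allowed jitter (pixels) of the top edge inside the stability window.
    diff_threshold
        Grayscale intensity above which an absolute frame difference is
        foreground.
    kernel_size
        Side of the square structuring element of the morphological opening;
        must be odd.
    r_min
        Minimum height/width ratio a contour box must have to look like a
        liquid column.
    growth_tolerance
        Pixels a column may shrink between frames before the vertical-growth
        prior rejects it.
    n_pipettes
        Number of pipettes in the block; equals the expected contour count.
    history
        Number of previous frames whose per-slot features are concatenated
        with the current frame's.
    fill_threshold
        Minimum fill fraction below which a pipette is ruled anomalous.
    """

    expansion_factor: float = 0.10
    persistence: int = 10
    min_drop: int | None = None
    drop_tolerance: int = 2
    diff_threshold: float = 25.0
    kernel_size: int = 5
    r_min: float = 0.5
    growth_tolerance: int = 2
    n_pipettes: int = 8
    history: int = 13
    fill_threshold: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.expansion_factor < 0:
            raise ValueError("expansion_factor must be >= 0")
        if self.persistence < 1:
            raise ValueError("persistence must be >= 1")
        if self.history < 0:
            raise ValueError("history must be >= 0")
        if not 0.0 <= self.fill_threshold <= 1.0:
            raise ValueError("fill_threshold must be in [0, 1]")

    def resolved_min_drop(self, frame_height: int) -> int:
        if self.min_drop is not None:
            return int(self.min_drop)
        return max(1, round(0.05 * frame_height))

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump({"pipeline": asdict(self)}, sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**data.get("pipeline", {}))

    def with_overrides(self, **kwargs) -> "PipelineConfig":
        kwargs = {k: v for k, v in kwargs.items() if v is not None}
        return replace(self, **kwargs) if kwargs else self


@dataclass(frozen=True)
class NoiseConfig:
    """Acquisition-noise processes layered onto rendered frames.

    gaussian_sigma: per-pixel Gaussian intensity noise (8-bit units).
    shake_prob / shake_max: per-frame probability and maximum magnitude
        (pixels) of a whole-frame camera-shake translation.
    ripple_amplitude / ripple_rows: peak brightness (8-bit units) and height
        (pixels) of the travelling sinusoidal band that emulates liquid
        ripples in the source tub, placed just below the pipette tips.
    """

    gaussian_sigma: float = 0.0
    shake_prob: float = 0.0
    shake_max: int = 3
    ripple_amplitude: float = 0.0
    ripple_rows: int = 10

    @classmethod
    def realistic(cls) -> "NoiseConfig":
        """Default noisy-acquisition conditions."""
        return cls(gaussian_sigma=3.0, shake_prob=0.03, shake_max=3,
                   ripple_amplitude=20.0, ripple_rows=10)


@dataclass(frozen=True)
class AnomalySpec:
    """Per-pipette anomaly assignment: slot -> (kind, residual fill fraction).

    ``clogged`` pipettes aspirate at most ``residual`` of the target column
    from the start; ``bottom_out`` pipettes stall at ``residual`` once the tip
    seals against the vessel bottom. Both manifest as a reduced liquid level.
    """

    kinds: Mapping[int, str] = field(default_factory=dict)
    residuals: Mapping[int, float] = field(default_factory=dict)

    VALID_KINDS = ("clogged", "bottom_out")
    DEFAULT_RESIDUAL = {"clogged": 0.05, "bottom_out": 0.10}

    def __post_init__(self) -> None:
        for slot, kind in self.kinds.items():
            if kind not in self.VALID_KINDS:
                raise ValueError(f"unknown anomaly kind {kind!r} for slot {slot}")

    def kind_of(self, slot: int) -> str:
        return self.kinds.get(slot, "none")

    def residual_of(self, slot: int) -> float:
        kind = self.kind_of(slot)
        if kind == "none":
            return 1.0
        return float(self.residuals.get(slot, self.DEFAULT_RESIDUAL[kind]))

    @property
    def any_anomaly(self) -> bool:
        return bool(self.kinds)


@dataclass(frozen=True)
class SynthConfig:
    """Scene parameters of the synthetic liquid-transfer video generator.

    The defaults emulate a desk-scale version of an 8-channel automated
    pipetting station filmed at 30 fps: the pipette block enters high in the
    frame, descends for one second, then rapidly aspirates a small volume of
    colored liquid (the column reaches its target level within two frame
    intervals, ~70 ms).
    """

    n_pipettes: int = 8
    frame_width: int = 320
    frame_height: int = 240
    n_frames: int = 120
    fps: float = 30.0
    descent_depth: int = 100
    descent_end_frame: int = 20
    pipette_width: int = 16
    pipette_height: int = 80
    pipette_spacing: int = 4
    block_top: int = 0
    bar_height: int = 8
    liquid_color: tuple[int, int, int] = (0, 200, 200)
    body_color: tuple[int, int, int] = (205, 205, 205)
    bar_color: tuple[int, int, int] = (60, 60, 60)
    background_gray: int = 95
    fill_rate: float = 40.0
    target_fill: float = 0.8
    anomaly_spec: AnomalySpec = field(default_factory=AnomalySpec)
    noise: NoiseConfig = field(default_factory=NoiseConfig)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_pipettes < 1:
            raise ValueError("n_pipettes must be >= 1")
        if not 0.0 < self.target_fill <= 1.0:
            raise ValueError("target_fill must be in (0, 1]")
        if self.descent_end_frame < 1 or self.descent_end_frame >= self.n_frames:
            raise ValueError("descent_end_frame must lie inside the video")
        if self.block_width > self.frame_width:
            raise ValueError("pipette block wider than the frame")
        if self.block_top + self.descent_depth + self.pipette_height > self.frame_height:
            raise ValueError("pipette block leaves the frame after descent")
        if self.block_top < 0:
            raise ValueError("block_top must be >= 0")
        if self.block_top + self.descent_depth < self.bar_height:
            raise ValueError("effector head bar never enters the frame")
        for slot in self.anomaly_spec.kinds:
            if not 0 <= slot < self.n_pipettes:
                raise ValueError(f"anomaly slot {slot} outside [0, {self.n_pipettes})")
            if self.anomaly_spec.residual_of(slot) >= self.target_fill:
                raise ValueError("anomalous residual fill must be < target_fill")

    @property
    def block_width(self) -> int:
        n = self.n_pipettes
        return n * self.pipette_width + (n - 1) * self.pipette_spacing

    @property
    def block_left(self) -> int:
        return (self.frame_width - self.block_width) // 2

    @property
    def column_capacity_px(self) -> int:
        """Liquid-column capacity in rows (the full pipette interior)."""
        return self.pipette_height
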