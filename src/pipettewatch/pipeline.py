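"""End-to-end orchestration: ROI -> self-comparison -> features -> decision.

The heart is :func:`extract_states`, which turns a video plus an ROI track
into per-frame, per-slot pipette states; everything downstream (the rule
decision, the classifier harness, the ablation experiment) consumes those
states. File-level entry points wrap it for the CLI.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import decision as decision_mod
from . import features as features_mod
from . import predict as predict_mod
from . import roi as roi_mod
from . import selfcomp
from . import synthgen
from .config import PipelineConfig, SynthConfig
from .video import Box, VideoSequence, load_video

__all__ = [
    "PipelineStates",
    "PipelineResult",
    "RunManifest",
    "extract_states",
    "run_pipeline",
    "simulate_dataset",
    "load_dataset_states",
    "run_experiment",
]

logger = logging.getLogger(__name__)


@dataclass
class PipelineStates:
    """Per-frame per-slot states for the post-anchor part of one video."""

    states_by_frame: list[list[features_mod.PipetteState]]
    geometry: features_mod.PipetteGeometry
    anchor_index: int
    window: Box


@dataclass
class PipelineResult:
    states: PipelineStates
    reports: list[decision_mod.FrameReport]
    verdict: str
    scores: np.ndarray | None = None


@dataclass
class RunManifest:
    """Provenance of a run: config, inputs, seed, stage timings, outputs."""

    command: str
    config: dict
    inputs: dict
    seed: int
    outputs: list[str] = field(default_factory=list)
    timings_s: dict = field(default_factory=dict)
    status: str = "running"
    error: str | None = None

    def write(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=1, sort_keys=True))


def extract_states(
    video: VideoSequence, track: roi_mod.RoiTrack, config: PipelineConfig
) -> PipelineStates:
    """Run self-comparison over the post-anchor crops of one video.

    The vertical-growth prior compares each slot's candidate against the
    previous frame's state for that slot; a slot with no previous detection
    is not checked, so a single corrupted frame cannot poison the rest of
    the video.
    """
    if track.anchor_index is None:
        roi_mod.detect_anchor(track, config, frame_height=video.frame_height)
    crops, window = roi_mod.crop_sequence(video, track, config)
    geometry = features_mod.PipetteGeometry(roi_box=window, n_pipettes=config.n_pipettes)
    anchor_crop = crops[0]

    n = config.n_pipettes
    prev_states: list[features_mod.PipetteState | None] = [None] * n
    states_by_frame: list[list[features_mod.PipetteState]] = []
    for k in range(len(crops)):
        mask = selfcomp.diff_frame(crops[k], anchor_crop, config.diff_threshold)
        mask = selfcomp.open_mask(mask, config.kernel_size)
        boxes = selfcomp.extract_contour_boxes(mask)
        slot_boxes = selfcomp.filter_contours(boxes, prev_states, config, window.w)
        slot_boxes = selfcomp.median_width_denoise(slot_boxes)
        states = features_mod.frame_states(
            slot_boxes, geometry, frame_index=track.anchor_index + k
        )
        prev_states = list(states)
        states_by_frame.append(states)
    return PipelineStates(
        states_by_frame=states_by_frame,
        geometry=geometry,
        anchor_index=track.anchor_index,
        window=window,
    )


def _build_track(
    video: VideoSequence,
    detections_path: str | Path | None,
    config: PipelineConfig,
) -> roi_mod.RoiTrack:
    if detections_path is not None:
        return roi_mod.load_detections(detections_path, n_frames=len(video))
    logger.info("no detections file given; falling back to motion-based ROI")
    return roi_mod.detect_roi_by_motion(video, config)


def run_pipeline(
    video_path: str | Path,
    detections_path: str | Path | None,
    config: PipelineConfig,
    model=None,
    eval_strategy: str = "last",
) -> PipelineResult:
    """Process one video end to end: rule reports, verdict, optional scores."""
    video = load_video(video_path)
    track = _build_track(video, detections_path, config)
    states = extract_states(video, track, config)
    reports = [
        decision_mod.rule_decision(frame_states, config)
        for frame_states in states.states_by_frame
    ]
    verdict = decision_mod.video_verdict(
        reports, strategy=eval_strategy, persistence=config.persistence
    )
    scores = None
    if model is not None:
        X = features_mod.video_feature_matrix(states.states_by_frame, config.history)
        scores = predict_mod.score_anomaly(model, X)
    return PipelineResult(states=states, reports=reports, verdict=verdict, scores=scores)


def simulate_dataset(
    out_dir: str | Path,
    n_normal: int,
    n_anomalous: int,
    base_config: SynthConfig,
    seed: int,
) -> list[Path]:
    """Render a dataset to disk: frames, ground truth and detection files.

    Layout: ``<out>/video_000/frames/frame_000000.png``, ``ground_truth.json``
    and ``detections.jsonl`` (the ground-truth detection provider), plus a
    dataset-level ``dataset.json`` index.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    videos = synthgen.generate_dataset(n_normal, n_anomalous, base_config, seed)
    index = []
    dirs = []
    for i, sim in enumerate(videos):
        vdir = out / f"video_{i:03d}"
        sim.video.to_dir(vdir / "frames")
        synthgen.write_ground_truth(sim.ground_truth, vdir / "ground_truth.json")
        synthgen.write_detections(sim.ground_truth, vdir / "detections.jsonl")
        index.append(
            {
                "video": vdir.name,
                "label": sim.ground_truth.video_label,
                "seed": sim.config.seed,
                "anomalous_slots": sorted(sim.config.anomaly_spec.kinds),
            }
        )
        dirs.append(vdir)
    (out / "dataset.json").write_text(json.dumps(index, indent=1, sort_keys=True))
    return dirs


def load_dataset_states(
    dataset_dir: str | Path, config: PipelineConfig
) -> list[tuple[list, np.ndarray, str]]:
    """Extract per-video states and frame labels from an on-disk dataset.

    Returns (states_by_frame, labels, video_id) per video; labels follow the
    ground truth from the detected anchor onward.
    """
    root = Path(dataset_dir)
    vdirs = sorted(d for d in root.iterdir() if d.is_dir() and d.name.startswith("video_"))
    if not vdirs:
        raise FileNotFoundError(f"no video_* directories under {root}")
    out = []
    for vdir in vdirs:
        video = VideoSequence.from_dir(vdir / "frames")
        track = roi_mod.load_detections(vdir / "detections.jsonl", n_frames=len(video))
        states = extract_states(video, track, config)
        gt = synthgen.read_ground_truth(vdir / "ground_truth.json")
        labels = np.array(
            [
                1 if lab == synthgen.LABEL_ANOMALY else 0
                for lab in gt.frame_labels[states.anchor_index :]
            ],
            dtype=int,
        )
        out.append((states.states_by_frame, labels, vdir.name))
    return out


def run_experiment(
    dataset_dir: str | Path,
    config: PipelineConfig,
    model_names: Sequence[str],
    history_lengths: Sequence[int],
    out_dir: str | Path,
) -> pd.DataFrame:
    """History-length x classifier ablation over an on-disk dataset.

    Writes ``ablation.csv`` (model, history, auc, eer), the pooled ROC points
    of the best cell to ``roc_best.csv`` and a plot to ``roc_best.png``.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    t0 = time.perf_counter()
    dataset = load_dataset_states(dataset_dir, config)
    logger.info("extracted states for %d videos in %.1fs", len(dataset),
                time.perf_counter() - t0)
    states_dataset = [(states, labels) for states, labels, _ in dataset]
    table = predict_mod.history_ablation(
        states_dataset, model_names, history_lengths, config
    )
    table.to_csv(out / "ablation.csv", index=False, float_format="%.6f")

    best = table.sort_values(["auc", "eer"], ascending=[False, True]).iloc[0]
    h = int(best["history"])
    feat_dataset = [
        (features_mod.video_feature_matrix(states, h), labels)
        for states, labels in states_dataset
    ]
    scores, labels, _ = predict_mod.grouped_cv_scores(
        feat_dataset, str(best["model"]), config
    )
    curve = predict_mod.roc_auc(scores, labels)
    pd.DataFrame(
        {"threshold": curve.thresholds, "fpr": curve.fpr, "tpr": curve.tpr}
    ).to_csv(out / "roc_best.csv", index=False, float_format="%.6f")
    _plot_roc(curve, str(best["model"]), h, out / "roc_best.png")
    return table


def _plot_roc(curve: predict_mod.RocCurve, model: str, h: int, path: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(4, 4))
    ax.plot(curve.fpr, curve.tpr,
            label=f"{model}, history {h}\nAUC {curve.auc:.3f}, EER {curve.eer:.3f}")
    ax.plot([0, 1], [0, 1], "k:", lw=0.8)
    ax.set_xlabel("false positive rate")
    ax.set_ylabel("true positive rate")
    ax.legend(loc="lower right", fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
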