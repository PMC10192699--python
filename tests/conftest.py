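"""Shared fixtures: seeded synthetic datasets and extracted pipeline states.

The heavy fixtures are session-scoped so the end-to-end tests and the
acceptance tests share one rendering/extraction pass per dataset.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pytest

from pipettewatch import decision as decision_mod
from pipettewatch import pipeline as pipeline_mod
from pipettewatch import roi as roi_mod
from pipettewatch import synthgen
from pipettewatch.config import NoiseConfig, PipelineConfig, SynthConfig

warnings.filterwarnings("ignore", category=FutureWarning)

CLEAN_DATASET_SEED = 101
NOISY_DATASET_SEED = 202


@dataclass
class ProcessedVideo:
    """One synthetic video run through ROI + self-comparison."""

    ground_truth: synthgen.GroundTruth
    states: pipeline_mod.PipelineStates
    labels: np.ndarray  # post-anchor frame labels, 1 = anomaly
    verdict: str  # rule-based video verdict, strategy "last"


def process_simulated(
    sim: synthgen.SimulatedVideo, config: PipelineConfig
) -> ProcessedVideo:
    track = roi_mod.RoiTrack.from_ground_truth(sim.ground_truth.roi_boxes)
    states = pipeline_mod.extract_states(sim.video, track, config)
    labels = np.array(
        [
            1 if lab == synthgen.LABEL_ANOMALY else 0
            for lab in sim.ground_truth.frame_labels[states.anchor_index :]
        ],
        dtype=int,
    )
    reports = [
        decision_mod.rule_decision(frame, config) for frame in states.states_by_frame
    ]
    verdict = decision_mod.video_verdict(reports, persistence=config.persistence)
    return ProcessedVideo(
        ground_truth=sim.ground_truth, states=states, labels=labels, verdict=verdict
    )


@pytest.fixture(scope="session")
def pipeline_config() -> PipelineConfig:
    return PipelineConfig()


@pytest.fixture(scope="session")
def clean_pair():
    """One noise-free normal video and one with clogged + bottom-out slots."""
    from pipettewatch.config import AnomalySpec

    normal = synthgen.generate_video(SynthConfig(seed=5))
    anomalous = synthgen.generate_video(
        SynthConfig(
            seed=6,
            anomaly_spec=AnomalySpec(kinds={2: "clogged", 5: "bottom_out"}),
        )
    )
    return normal, anomalous


@pytest.fixture(scope="session")
def clean_processed20(pipeline_config) -> list[ProcessedVideo]:
    """20 noise-free videos (10 normal, 10 anomalous) run through the pipeline."""
    sims = synthgen.generate_dataset(10, 10, SynthConfig(), seed=CLEAN_DATASET_SEED)
    return [process_simulated(sim, pipeline_config) for sim in sims]


@pytest.fixture(scope="session")
def noisy_processed12(pipeline_config) -> list[ProcessedVideo]:
    """12 videos (6 normal, 6 anomalous) under realistic acquisition noise."""
    base = SynthConfig(noise=NoiseConfig.realistic())
    sims = synthgen.generate_dataset(6, 6, base, seed=NOISY_DATASET_SEED)
    return [process_simulated(sim, pipeline_config) for sim in sims]
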