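import numpy as np
import pytest

from wheelvault import synth
from wheelvault.events import EventParams
from wheelvault.features import build_feature_vector
from wheelvault.model import PerformanceRecord
from wheelvault.pipeline import SYNTH_EVENT_PARAMS


@pytest.fixture(scope="session")
def synth_event_params() -> EventParams:
    return SYNTH_EVENT_PARAMS


@pytest.fixture(scope="session")
def short_config() -> synth.SynthConfig:
    """A fast config: one short performance, default noise."""
    return synth.SynthConfig(
        seed=7, n_days=1, performances_per_day=1, ride_time_range=(0.9, 1.1)
    )


@pytest.fixture(scope="session")
def zero_noise_config() -> synth.SynthConfig:
    return synth.SynthConfig(
        seed=11,
        n_days=1,
        performances_per_day=1,
        ride_time_range=(0.9, 1.1),
        flow_noise_sd=0.0,
        judge_noise_sd=0.0,
    )


@pytest.fixture(scope="session")
def zero_noise_performance(zero_noise_config):
    rng = np.random.default_rng(0)
    return synth.simulate_performance(zero_noise_config, day=1, rng=rng)


def records_from_ground_truth(config: synth.SynthConfig) -> list[PerformanceRecord]:
    """Feature records computed at the *ground-truth* event frames (fast:
    no mask/flow rendering), used when the subject under test is the model,
    not the detectors."""
    records = []
    for perf in synth.iter_dataset(config):
        gt = perf.truth.event_frames
        kp = {
            f: perf.series.keypoint_set(f)
            for f in (gt.takeoff, gt.pikemount, gt.thrust)
        }
        fv = build_feature_vector(gt, kp, config.meta.fps)
        records.append(
            PerformanceRecord(
                gymnast_id="g1",
                day=perf.day,
                features=fv,
                judge_deductions=perf.truth.judge_scores,
            )
        )
    return records


@pytest.fixture(scope="session")
def gt_records():
    """A medium corpus of ground-truth-frame records for model tests."""
    cfg = synth.SynthConfig(seed=5, n_days=5, performances_per_day=6)
    return records_from_ground_truth(cfg)
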