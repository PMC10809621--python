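"""Shared fixtures: small synthetic segments and a reusable mini-cohort."""

import warnings

import numpy as np
import pytest

from wearcog.io_e4 import Channel
from wearcog.segmentation import Segment

warnings.filterwarnings("ignore", message=".*nearly constant.*")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_segment(values, channel=Channel.EDA, rate=4.0, coverage=1.0,
                 subject="S001", date=0, clock=3600):
    return Segment(subject_id=subject, date=date, start_clock=clock,
                   channel=channel, sampling_rate=rate,
                   values=np.asarray(values, dtype=float), coverage=coverage)


@pytest.fixture
def segment_factory():
    return make_segment


@pytest.fixture(scope="session")
def mini_cohort(tmp_path_factory):
    """4-subject, 40-day cohort with planted HF coupling, generated once."""
    from wearcog.synthetic import SimulationConfig, generate_cohort

    out = tmp_path_factory.mktemp("cohort")
    cfg = SimulationConfig(n_subjects=4, observation_days=40,
                           wear_nights_per_interval=2, seed=2024)
    path, truths = generate_cohort(cfg, out)
    return {"path": path, "truths": truths, "config": cfg}


@pytest.fixture(scope="session")
def mini_feature_rows(mini_cohort):
    """Extracted 5-min feature rows for the session cohort."""
    from wearcog.pipeline import PipelineConfig, extract_features

    cfg = PipelineConfig(data_dir=str(mini_cohort["path"]), out_dir="unused",
                         observation_days=mini_cohort["config"].observation_days)
    return cfg, extract_features(cfg)
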