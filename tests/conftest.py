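"""Shared fixtures: small synthetic studies generated once per session."""

import numpy as np
import pytest

from hoglog import StudyConfig, featurize, generate_study, validate_bursts


@pytest.fixture(scope="session")
def day_config() -> StudyConfig:
    """One individual, two full days, 1-s bursts: the labelled-burst fixture."""
    return StudyConfig(
        n_individuals=1,
        pre_days=1,
        festival_days=1,
        post_days=0,
        bursts_per_day=1440,
        burst_len_s=1.0,
        seed=3,
    )


@pytest.fixture(scope="session")
def day_study(day_config):
    return generate_study(day_config)


@pytest.fixture(scope="session")
def day_features(day_config, day_study):
    kept, _ = validate_bursts(day_study.bursts, expected_n=day_config.samples_per_burst)
    feat = featurize(kept, expected_n=day_config.samples_per_burst, hz=day_config.burst_hz)
    labels = day_study.truth.burst_labels.set_index("burst_id")["behavior"]
    feat = feat.copy()
    feat["label"] = feat["burst_id"].map(labels)
    return feat


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(0)
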