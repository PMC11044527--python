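import numpy as np
import pytest
from hypothesis import settings

# deterministic property tests: same examples on every run
settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from cd26flow import (
    GatingConfig,
    SampleSimConfig,
    run_gating_pipeline,
    simulate_sample,
)
from cd26flow.fcs_io import ChannelMeta, EventMatrix
from cd26flow.synthetic import MARKERS


def make_em(sample_id="test", **marker_columns):
    """Build an EventMatrix from per-marker raw-intensity arrays.

    Missing markers are filled with zeros; all seven panel markers are
    always present so the panel resolves.
    """
    n = len(next(iter(marker_columns.values())))
    cols = []
    for m in MARKERS:
        v = marker_columns.get(m)
        cols.append(np.zeros(n) if v is None else np.asarray(v, dtype=float))
    channels = [
        ChannelMeta(i + 1, f"FL{i + 1}", marker=m) for i, m in enumerate(MARKERS)
    ]
    return EventMatrix(np.column_stack(cols), channels, sample_id=sample_id)


@pytest.fixture(scope="session")
def default_sample():
    """One CML-diagnosis-like acquisition at the study's default conditions."""
    return simulate_sample(SampleSimConfig(seed=7))


@pytest.fixture(scope="session")
def default_report(default_sample):
    em, _ = default_sample
    return run_gating_pipeline(em)


@pytest.fixture(scope="session")
def control_sample():
    return simulate_sample(SampleSimConfig(seed=11, group="control"))


@pytest.fixture(scope="session")
def control_report(control_sample):
    em, _ = control_sample
    return run_gating_pipeline(em)


@pytest.fixture()
def gating_config():
    return GatingConfig()
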