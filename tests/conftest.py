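"""Shared fixtures: the deterministic default stimulus set and its
descriptor matrix are expensive (~3 s), so they are built once per session."""

import numpy as np
import pandas as pd
import pytest

import timbreaffect as ta
from timbreaffect import reduction

STIMULUS_SEED = 0


@pytest.fixture(scope="session")
def stimulus_set():
    clips, meta = ta.generate_stimulus_set(seed=STIMULUS_SEED)
    return clips, meta


@pytest.fixture(scope="session")
def descriptor_matrix(stimulus_set) -> pd.DataFrame:
    clips, _ = stimulus_set
    return ta.extract_matrix(clips)


@pytest.fixture(scope="session")
def retained_matrix(descriptor_matrix) -> pd.DataFrame:
    report = ta.reduce_descriptors(descriptor_matrix)
    return descriptor_matrix[report.retained]


@pytest.fixture(scope="session")
def normalized_matrix(retained_matrix) -> pd.DataFrame:
    Xn, _ = reduction.range_normalize(retained_matrix)
    return Xn


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
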