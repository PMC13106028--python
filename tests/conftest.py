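import os
import sys

import numpy as np
import pytest

sys.path.insert(0, os.path.dirname(__file__))  # make tests/oracles.py importable

from copdwl.phenotype import WeightRecord, WeightSeries


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_series(times_days, weights, pid="P1", bmis=None):
    """Build a WeightSeries from parallel day/weight arrays."""
    if bmis is None:
        bmis = [None] * len(weights)
    return WeightSeries(pid, [
        WeightRecord(pid, int(t), float(w), bmi=b)
        for t, w, b in zip(times_days, weights, bmis)])


@pytest.fixture
def series_factory():
    return make_series
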