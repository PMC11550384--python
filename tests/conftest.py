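"""Shared builders for hand-constructed traces, events and tensors."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from soc_calcium.core import EVENT_COLUMNS, TraceMatrix, WindowSpec


def make_trace(values, fs: float = 10.0, phase: str = "test") -> TraceMatrix:
    values = np.atleast_2d(np.asarray(values, dtype=float))
    return TraceMatrix(
        neuron_ids=[f"n{i}" for i in range(values.shape[0])],
        times=np.arange(values.shape[1]) / fs,
        values=values,
        sampling_rate_hz=fs,
        phase=phase,
    )


def make_events(onsets, label: str = "CS2", duration: float = 10.0,
                phase: str = "test") -> pd.DataFrame:
    rows = [(label, float(t), duration, phase, i)
            for i, t in enumerate(onsets)]
    return pd.DataFrame(rows, columns=EVENT_COLUMNS)


@pytest.fixture
def window() -> WindowSpec:
    return WindowSpec(pre_s=10.0, post_s=20.0)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
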