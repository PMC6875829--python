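"""Shared fixtures: small longitudinal designs built programmatically."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from chronomix.core_io import LongitudinalCounts


def make_meta(n_subjects: int, times: np.ndarray) -> pd.DataFrame:
    """Balanced design: every subject observed at every time."""
    n = n_subjects * times.size
    return pd.DataFrame({
        "sample_id": [f"s{i}" for i in range(n)],
        "subject_id": np.repeat([f"ind{j}" for j in range(n_subjects)], times.size),
        "time": np.tile(times, n_subjects),
    })


@pytest.fixture
def grid9() -> np.ndarray:
    return np.linspace(0.0, 1.0, 9)


@pytest.fixture
def meta45(grid9) -> pd.DataFrame:
    """Five subjects, nine shared time points."""
    return make_meta(5, grid9)


@pytest.fixture
def toy_counts() -> LongitudinalCounts:
    """3 features x 4 samples, 2 subjects, 2 time points."""
    meta = pd.DataFrame({
        "sample_id": ["a1", "a2", "b1", "b2"],
        "subject_id": ["A", "A", "B", "B"],
        "time": [0.0, 1.0, 0.0, 1.0],
    })
    counts = np.array([[10, 20, 30, 40], [1, 2, 3, 4], [5, 0, 5, 0]])
    return LongitudinalCounts(counts, ["otu1", "otu2", "otu3"], meta)


def sigmoid_profile(t: np.ndarray, k: float = 10.0) -> np.ndarray:
    y = 1.0 / (1.0 + np.exp(-k * (t - 0.5)))
    return (y - y.mean()) / y.std(ddof=1)


def bump_profile(t: np.ndarray, w: float = 0.15) -> np.ndarray:
    y = np.exp(-((t - 0.5) ** 2) / (2 * w**2))
    return (y - y.mean()) / y.std(ddof=1)
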