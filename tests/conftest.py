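"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import numpy as np
import pytest


def sampen_bruteforce(x, m: int, r: float) -> float:
    """Independent O(N^2) sample-entropy oracle.

    Enumerates every ordered template pair (i != j) over the shared
    index range i = 1..N-m for both the length-m and length-(m+1)
    vectors, with strict Chebyshev tolerance.  Kept deliberately naive:
    it must stay independent of the implementation it checks.
    """
    x = np.asarray(x, dtype=float)
    n = len(x)

    def count(length: int) -> int:
        templates = [x[i:i + length] for i in range(n - m)]
        c = 0
        for i in range(len(templates)):
            for j in range(len(templates)):
                if i != j and np.max(np.abs(templates[i] - templates[j])) < r:
                    c += 1
        return c

    b = count(m)
    a = count(m + 1)
    if a == 0 or b == 0:
        return float("nan")
    return float(-np.log(a / b))


def roc_auc_bruteforce(scores, labels) -> float:
    """Exhaustive pair enumeration AUC oracle (ties count 1/2)."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    total = 0.0
    for p in pos:
        for q in neg:
            total += 1.0 if p > q else (0.5 if p == q else 0.0)
    return total / (len(pos) * len(neg))


@pytest.fixture(scope="session")
def fs() -> float:
    return 400.0


@pytest.fixture(scope="session")
def tone_10hz(fs):
    t = np.arange(4000) / fs
    return np.sin(2 * np.pi * 10 * t)


@pytest.fixture(scope="session")
def small_cohort():
    """A tiny deterministic cohort reused across IO/pipeline tests."""
    from neuromse.synthetic import SimulationConfig, generate_cohort
    cfg = SimulationConfig(n_per_group=2, n_regions=3, n_temporal_regions=1,
                           n_segments=2, segment_seconds=1.0, seed=99)
    return generate_cohort(cfg)
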