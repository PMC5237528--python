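"""Shared fixtures.

The expensive trained-cascade fixture is session-scoped: the
effectiveness tests (probability-map quality, walker benchmark) all
reuse one cascade trained on six 128x128 phantoms.
"""

from __future__ import annotations

import numpy as np
import pytest

from liverseg.cascade import TrainingCase, train_cascade
from liverseg.phantom import generate_dataset

BENCH_SEED = 11


@pytest.fixture(scope="session")
def phantom_bench():
    """6 training + 2 held-out phantoms at the default spec."""
    train, test = generate_dataset(6, 2, seed=BENCH_SEED)
    return train, test


@pytest.fixture(scope="session")
def trained_cascade(phantom_bench):
    train, _ = phantom_bench
    cases = [TrainingCase(image=c.image, label_map=c.truth_mask, id=c.id) for c in train]
    return train_cascade(cases, U=4, rng_seed=BENCH_SEED)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def pixelwise_auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """Rank-statistic AUC (ties get average rank)."""
    from scipy.stats import rankdata

    ranks = rankdata(scores.ravel())
    pos = labels.ravel().astype(bool)
    n1 = int(pos.sum())
    n0 = pos.size - n1
    return float((ranks[pos].sum() - n1 * (n1 + 1) / 2) / (n1 * n0))
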