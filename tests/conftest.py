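"""Shared fixtures: random-weight predictors (no training needed for
contract tests), a tiny trained model, and deterministic RNG helpers."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from dnabend.model import IRLSTMRegressor
from dnabend.nn import IRLSTMNetwork
from dnabend.synth import make_library

settings.register_profile(
    "deterministic",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("deterministic")

#: small architecture for fast training in unit tests (shape contracts only;
#: the full-size default architecture is exercised in the acceptance tests)
TINY = dict(stem_filters=16, filters_per_branch=8, lstm_units=6)


def make_random_model(seed: int = 0, **overrides) -> IRLSTMRegressor:
    """An estimator with freshly initialized (untrained) weights and
    identity calibration — sufficient for every structural contract
    (reverse-complement symmetry, window semantics, serialization)."""
    est = IRLSTMRegressor(random_state=seed, **overrides)
    est.network_ = IRLSTMNetwork(est._config(), seed=seed)
    est.detrend_a_, est.detrend_b_ = 0.0, 1.0
    est.label_mean_, est.label_std_ = 0.0, 1.0
    return est


def random_seqs(n: int, L: int, seed: int = 0, alphabet: str = "ACGT") -> list[str]:
    rng = np.random.default_rng(seed)
    lookup = np.array(list(alphabet))
    return ["".join(row) for row in lookup[rng.integers(0, len(alphabet), (n, L))]]


@pytest.fixture(scope="session")
def random_model() -> IRLSTMRegressor:
    return make_random_model(seed=7)


@pytest.fixture(scope="session")
def tiny_trained_model():
    """A small model actually fitted on a small synthetic library."""
    lib = make_library(600, seed=3)
    est = IRLSTMRegressor(random_state=3, max_epochs=3, **TINY)
    est.fit(lib.sequences, lib.labels)
    return est, lib
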