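"""Shared fixtures: small synthetic datasets generated at test time."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from specmotif.seqio import Dataset, ScoredSequence, fit_markov_background
from specmotif.synth import _random_motif, make_chip_fixture

settings.register_profile(
    "repro",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("repro")


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20230917)


@pytest.fixture(scope="session")
def uniform_bg():
    """Order-0 background fitted on balanced sequence, ~uniform."""
    return fit_markov_background(["ACGTACGTACGT" * 50], order=0, pseudocount=0.0)


@pytest.fixture(scope="session")
def planted_pwm():
    return _random_motif(np.random.default_rng(42), 10, 2)


@pytest.fixture(scope="session")
def chip_fixture(planted_pwm):
    """Small planted-motif ChIP-like dataset (fast smoke-scale)."""
    return make_chip_fixture(
        60, 120, 120, planted_pwm, plant_frac=0.9, seed=11
    )


@pytest.fixture()
def tiny_dataset():
    return Dataset(
        [
            ScoredSequence("a", "ACGTACGTAC", binding_score=5.0),
            ScoredSequence("b", "TTTTACGTTT", binding_score=1.0),
            ScoredSequence("c", "GGGGGGGGGG"),
        ]
    )
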