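"""Shared fixtures: synthetic cohorts and trained models reused across
test modules (training is the expensive part, so fits are session-scoped)."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from survformer import (ModelConfig, SimSpec, TrainPlan, TransformerSurvival,
                        simulate_cohort)

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


@pytest.fixture(scope="session")
def signal_data():
    """Criterion cohort: 600 patients, 12 features, 4 informative
    (linear log-hazard SD 1), 30% censoring."""
    return simulate_cohort(SimSpec(seed=7))


@pytest.fixture(scope="session")
def signal_fit(signal_data):
    """Transformer (2 layers, d_k=64) trained 30 epochs on 10 80/20 splits."""
    cohort, _ = signal_data
    model = TransformerSurvival(
        cohort,
        config=ModelConfig(d_k=64, n_layers=2, n_heads=4),
        plan=TrainPlan(strategy="direct", n_splits=10, finetune_epochs=30,
                       batch_size=64, lr=1e-3, eval_every=10))
    return model.fit(seed=0)


@pytest.fixture(scope="session")
def small_fit():
    """A quick, deliberately small fit for API/explain/perturb unit tests."""
    cohort, truth = simulate_cohort(SimSpec(
        n_patients=150, block_sizes=tuple([1] * 6), seed=3,
        coefficients={"f1": 0.7, "f2": -0.7}))
    model = TransformerSurvival(
        cohort,
        config=ModelConfig(d_k=32, n_layers=2, n_heads=4, dropout=0.1),
        plan=TrainPlan(strategy="direct", n_splits=2, finetune_epochs=25,
                       batch_size=50, lr=1e-3, eval_every=5))
    return model, model.fit(seed=1), truth


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
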