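"""Shared fixtures: small synthetic cohorts generated at test time."""

from __future__ import annotations

import numpy as np
import pytest

import sexnet as sx


@pytest.fixture(scope="session")
def sex_effect_cohort() -> sx.SyntheticCohort:
    """Small, strongly separable cohort: sex intensity effect in region 1."""
    return sx.generate_cohort(
        n=60,
        grid=16,
        effects=[sx.EffectSpec(1, "intensity_shift", "sex", 5.0)],
        seed=42,
    )


@pytest.fixture(scope="session")
def trained_tiny_model(sex_effect_cohort) -> sx.SexNet:
    """A quickly trained model on the small separable cohort."""
    cfg = sx.ModelConfig(grid=16, epochs=8, seed=42)
    model = sx.SexNet(cfg)
    g = sex_effect_cohort.records["sex"].to_numpy().astype(np.float32)
    x = np.concatenate([sex_effect_cohort.volumes, np.flip(sex_effect_cohort.volumes, 1)])
    y = np.concatenate([g, g])
    sx.train(model, x.astype(np.float32), y, cfg)
    return model


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
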