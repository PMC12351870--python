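"""Shared fixtures: the default synthetic study and a trained MLP.

The default study is a three-breed design (Yorkshire, Landrace, Duroc at
divergence F = 0.15 over 1,000 SNPs) with 300 purebreds per breed plus 150
Yorkshire x Landrace F1s for training, and an independent test population
of 100 per breed plus 100 F1s drawn from the same breed frequencies. These
are session-scoped because several end-to-end checks share them.
"""

from __future__ import annotations

import numpy as np
import pytest

from breedcomp import MLPGBCRegressor, QCThresholds, apply_qc
from breedcomp.experiments import Dataset, intersect_panels, prepare_dataset
from breedcomp.simulate import CrossSpec, SimConfig, sample_population_pair

FIXTURE_SEED = 1
MLP_SEED = 2


@pytest.fixture(scope="session")
def default_config() -> SimConfig:
    return SimConfig(seed=FIXTURE_SEED)


@pytest.fixture(scope="session")
def default_study(default_config):
    """(train Dataset, test Dataset, raw pieces) for the default design."""
    cfg = default_config
    (g1, t1), (g2, t2), freqs = sample_population_pair(cfg)
    train = prepare_dataset(g1, t1, cfg.breeds)
    g1_qc, _ = apply_qc(g1)
    g1_al, g2_al = intersect_panels(g1_qc, g2)
    test = prepare_dataset(g2_al, t2, cfg.breeds, qc=QCThresholds(0.0, 0.0, 0.0))
    return {
        "cfg": cfg,
        "train": train,
        "test": test,
        "g1": g1,
        "g2": g2,
        "freqs": freqs,
    }


@pytest.fixture(scope="session")
def default_mlp(default_study) -> MLPGBCRegressor:
    cfg = default_study["cfg"]
    model = MLPGBCRegressor(breeds=cfg.breeds, random_state=MLP_SEED)
    model.fit(default_study["train"].X, default_study["train"].targets())
    return model


@pytest.fixture(scope="session")
def test_predictions(default_study, default_mlp) -> np.ndarray:
    """Default-MLP GBC predictions for the independent test population."""
    return default_mlp.predict(default_study["test"].X)


@pytest.fixture(scope="session")
def tiny_study():
    """A fast three-breed study for CLI and unit-level end-to-end checks."""
    cfg = SimConfig(
        n_snps=120,
        breed_sizes=(40, 40, 40),
        crosses=(CrossSpec("Yorkshire", "Landrace", 0.5, 25),),
        seed=11,
    )
    (g1, t1), (g2, t2), freqs = sample_population_pair(
        cfg, test_breed_sizes=(20, 20, 20), test_cross_sizes=(15,)
    )
    return {"cfg": cfg, "pop1": (g1, t1), "pop2": (g2, t2), "freqs": freqs}
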