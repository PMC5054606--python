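import numpy as np
import pytest

from lincscout.core import PipelineConfig
from lincscout.simulate import GeneratorConfig, simulate_world
from lincscout.tss_model import (
    FeatureInputs,
    build_training_set,
    genome_scan,
    train_and_cv,
)

WORLD_SEED = 11


@pytest.fixture(scope="session")
def cfg():
    return PipelineConfig()


@pytest.fixture(scope="session")
def world():
    """One default-condition synthetic world shared across the suite."""
    return simulate_world(seed=WORLD_SEED)


@pytest.fixture(scope="session")
def small_world():
    return simulate_world(
        GeneratorConfig(n_coding=4, n_linc_known=12, n_linc_novel=4, seed=7)
    )


@pytest.fixture(scope="session")
def feature_inputs(world):
    return FeatureInputs(
        world.genome, world.chromatin, world.cage_track,
        world.cgi, world.repeats, world.pwms,
    )


@pytest.fixture(scope="session")
def training_set(world, feature_inputs, cfg):
    klincs = [l.transcript for l in world.known_lincs]
    return build_training_set(
        klincs, world.known, feature_inputs, expression=world.expression,
        cfg=cfg, seed=WORLD_SEED,
    )


@pytest.fixture(scope="session")
def trained(training_set, cfg):
    report, model = train_and_cv(
        training_set.features, training_set.labels, cfg=cfg, seed=WORLD_SEED
    )
    return report, model


@pytest.fixture(scope="session")
def predicted_regions(trained, feature_inputs, world, cfg):
    _, model = trained
    return genome_scan(model, feature_inputs, world.known, cfg)
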