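import hypothesis
import numpy as np
import pytest

from genofabric.preprocess import preprocess_experiment
from genofabric.synthetic_data import (
    CoordinationModule,
    DesignConfig,
    PlantedFold,
    default_config,
    generate_experiment,
)

hypothesis.settings.register_profile(
    "suite", derandomize=True, max_examples=50, deadline=None
)
hypothesis.settings.load_profile("suite")


@pytest.fixture(scope="session")
def tiny_experiment():
    cfg = default_config("tiny")
    return generate_experiment(cfg)


@pytest.fixture(scope="session")
def tiny_normalized(tiny_experiment):
    tables, _ = tiny_experiment
    return preprocess_experiment(tables)


@pytest.fixture(scope="session")
def tiny_tensor(tiny_normalized):
    return tiny_normalized["MRLp"]


@pytest.fixture(scope="session")
def null1000_experiment():
    """1,000-gene null dataset (no folds, no modules) for calibration checks."""
    cfg = DesignConfig(n_genes=1000, seed=12345)
    return generate_experiment(cfg)


@pytest.fixture(scope="session")
def null1000_normalized(null1000_experiment):
    tables, _ = null1000_experiment
    return preprocess_experiment(tables)


@pytest.fixture(scope="session")
def fold_experiment():
    """200 planted 4x folds in MRLlpr at 10% biological CV, spread through a
    study-scale universe of 17,000 genes (sparse planting keeps the
    median-gene normalization reference unperturbed, as in real data)."""
    folds = tuple(
        PlantedFold(gene=i, phenotype="MRLlpr", fold=4.0)
        for i in range(1, 200 * 85, 85)
    )
    cfg = DesignConfig(
        n_genes=17000, bio_cv_range=(0.10, 0.10), planted_folds=folds, seed=101
    )
    return generate_experiment(cfg)


@pytest.fixture(scope="session")
def module_experiment():
    """300 genes with three planted 10-gene synergistic modules,
    latent factor far above the biological noise."""
    mods = tuple(
        CoordinationModule(
            genes=tuple(range(10 * m + 1, 10 * m + 11)),
            loadings=(1,) * 10,
            latent_sd=1.0,
        )
        for m in range(3)
    )
    cfg = DesignConfig(
        n_genes=300, bio_cv_range=(0.01, 0.03), coordination_modules=mods, seed=202
    )
    return generate_experiment(cfg)


@pytest.fixture(scope="session")
def module_normalized(module_experiment):
    tables, _ = module_experiment
    return preprocess_experiment(tables)
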