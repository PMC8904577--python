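import numpy as np
import pytest

from pgsabs import ContinuousTraitModel, auc_to_d, build_binary_model


@pytest.fixture(scope="session")
def schizophrenia_model():
    """K=1% prevalence, score AUC 0.67 — the standard disease worked example."""
    return build_binary_model(0.01, auc_to_d(0.67))


@pytest.fixture(scope="session")
def iq_model():
    """IQ-scale trait (mean 100, SD 15) with a score explaining 10% of variance."""
    return ContinuousTraitModel(trait_mean=100.0, trait_sd=15.0, r2=0.10)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240915)
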