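import numpy as np
import pytest

from bcnma.datamodel import (
    ADContrastStudy,
    ComponentCatalog,
    NetworkDataset,
    TreatmentCombination,
)
from bcnma.mcmc import MCMCSettings
from bcnma.synthetic import default_plan, ipd_plan, simulate_ad, simulate_ipd


@pytest.fixture(scope="session")
def catalog6():
    return default_plan().catalog


@pytest.fixture(scope="session")
def truth_default():
    return default_plan()


@pytest.fixture(scope="session")
def truth_additive():
    """Default plan with the interaction switched off (purely additive truth)."""
    from dataclasses import replace

    return replace(default_plan(), d_pairs={})


@pytest.fixture(scope="session")
def ds_interaction(truth_default):
    return simulate_ad(truth_default, seed=7)


@pytest.fixture(scope="session")
def ds_additive(truth_additive):
    return simulate_ad(truth_additive, seed=7)


@pytest.fixture(scope="session")
def truth_ipd():
    return ipd_plan()


@pytest.fixture(scope="session")
def ds_ipd(truth_ipd):
    return simulate_ipd(truth_ipd, seed=21)


@pytest.fixture
def quick_mcmc():
    return MCMCSettings(seed=1, chains=2, iterations=600, burnin=300)


def two_treatment_dataset(seed: int = 42, n_studies: int = 12, mu: float = 0.5,
                          tau: float = 0.3):
    """A degenerate network: two treatments, each one distinct component."""
    rng = np.random.default_rng(seed)
    cat = ComponentCatalog(("a", "b"))
    A = TreatmentCombination(frozenset(["a"]))
    B = TreatmentCombination(frozenset(["b"]))
    studies = []
    for i in range(n_studies):
        se = rng.uniform(0.15, 0.3)
        y = rng.normal(mu + rng.normal(0, tau), se)
        studies.append(
            ADContrastStudy(f"s{i}", [(A, None, None), (B, float(y), float(se))])
        )
    return NetworkDataset(catalog=cat, ad_contrast=studies)
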