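import numpy as np
import pandas as pd
import pytest
from hypothesis import settings, HealthCheck

from dietmeth.config import EffectConfig
from dietmeth.simulate import (generate_methylation, generate_phenotypes,
                               generate_probe_annotation)

settings.register_profile(
    "ci", derandomize=True,
    suppress_health_check=[HealthCheck.too_slow], deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_config():
    """Planted-effect cohort at reduced scale for fast unit tests."""
    return EffectConfig(n_probes_total=500, n_a_only=25, n_b_only=25,
                        n_shared_concordant=10, n_shared_discordant=10,
                        effect_size=0.08, noise_sd=0.25, batch_sd=0.2,
                        latent_loading_sd=0.3, seed=7)


@pytest.fixture(scope="session")
def small_cohort(small_config):
    pheno = generate_phenotypes(200, small_config)
    beta, detp, truth = generate_methylation(pheno, small_config)
    return pheno, beta, detp, truth


@pytest.fixture(scope="session")
def small_annotation(small_config):
    annotation, tss, nearest_truth = generate_probe_annotation(
        500, 60, small_config)
    return annotation, tss, nearest_truth


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
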