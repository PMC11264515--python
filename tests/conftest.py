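import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_cohort():
    """A 150-patient synthetic cohort with default planted effects."""
    from crcpanel.synthetic import CohortConfig, generate_clinical, generate_somatic_variants

    cfg = CohortConfig(n_patients=150, seed=7)
    clinical, clin_truth = generate_clinical(cfg)
    variants, var_truth = generate_somatic_variants(cfg, clinical)
    return {
        "config": cfg,
        "clinical": clinical,
        "clinical_truth": clin_truth,
        "variants": variants,
        "variant_truth": var_truth,
    }


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
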