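import numpy as np
import pandas as pd
import pytest

from nephroscan import scoring, synthdata


@pytest.fixture(scope="session")
def cohort_config():
    return synthdata.default_cohort_config(seed=42, n_cells_per_sample=250)


@pytest.fixture(scope="session")
def cohort(cohort_config):
    """Reference synthetic cohort: 3 conditions x 2 samples x 250 cells."""
    return synthdata.generate_cohort(cohort_config)


@pytest.fixture(scope="session")
def clean_cohort():
    """Cohort without planted low-quality cells or doublets."""
    cfg = synthdata.default_cohort_config(seed=7, n_cells_per_sample=250)
    cfg.lowq_fraction = 0.0
    cfg.doublet_fraction = 0.0
    return synthdata.generate_cohort(cfg)


@pytest.fixture(scope="session")
def clean_config():
    cfg = synthdata.default_cohort_config(seed=7, n_cells_per_sample=250)
    cfg.lowq_fraction = 0.0
    cfg.doublet_fraction = 0.0
    return cfg


@pytest.fixture(scope="session")
def lognorm(clean_cohort):
    return scoring.log_normalize(clean_cohort)


@pytest.fixture(scope="session")
def binary_condition(lognorm):
    return lognorm.obs["condition"].map(
        lambda c: "Control" if c == "Control" else "IRI"
    )
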