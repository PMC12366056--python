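import numpy as np
import pandas as pd
import pytest

import cadomics as cd


@pytest.fixture(scope="session")
def small_cohort():
    """Small mixed cohort reused by unit tests (160 subjects, 80 SNPs)."""
    cfg = cd.SimulationConfig(
        n_per_group=(60, 60, 40),
        n_snps=80,
        n_metabolites=20,
        n_informative_features=5,
        effect_size=1.5,
        seed=1,
    )
    return cd.generate_cohort(cfg)


@pytest.fixture(scope="session")
def clustered_cohort():
    """Cohort with five crisply separated metabolite clusters (effect 4 sd)."""
    cfg = cd.SimulationConfig(
        n_per_group=(174, 232, 94),
        n_snps=80,
        n_metabolites=143,
        n_informative_features=0,
        effect_size=4.0,
        seed=2,
    )
    return cd.generate_cohort(cfg)


@pytest.fixture(scope="session")
def feature_table(small_cohort):
    norm = cd.normalize_metabolites(small_cohort.metabolites)
    return cd.assemble_features(small_cohort.cohort, norm.values)
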