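import numpy as np
import pandas as pd
import pytest

from dysreg import sem, synthetic_cohort as sc
from dysreg.workbench import lcv_wide_table


@pytest.fixture(scope="session")
def gen_spec():
    return sc.default_spec()


@pytest.fixture(scope="session")
def cohort(gen_spec):
    """One full simulated observation year at the study's size."""
    return sc.generate_cohort(gen_spec, seed=11)


@pytest.fixture(scope="session")
def lcv_wide(cohort):
    """Yearly LCVs computed from the records, patients x biomarkers."""
    return lcv_wide_table(cohort.records).dropna()


@pytest.fixture(scope="session")
def truth_lcv(gen_spec):
    """True (latent) per-patient LCVs at n = 334, bypassing record noise."""
    lcv, _ = sc.sample_lcv_matrix(gen_spec, seed=17)
    return lcv


@pytest.fixture(scope="session")
def cfa_spec():
    return sem.default_cfa_spec()
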