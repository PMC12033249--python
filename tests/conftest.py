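import numpy as np
import pandas as pd
import pytest

from protclock.preprocess import impute_missing, qc_filter
from protclock.synthgen import Cohort, SimConfig, simulate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """A complete (QC'd + imputed) 400 x 60 cohort with genotypes."""
    cfg = SimConfig(n_samples=400, n_proteins=60, n_variants=30, seed=2)
    cohort, genotypes, truth = simulate_cohort(cfg)
    cohort = impute_missing(qc_filter(cohort))
    genotypes = genotypes.subset_samples(cohort.sample_ids)
    return cohort, genotypes, truth


def make_cohort(values: np.ndarray, sex=None, age=None) -> Cohort:
    """Hand-built cohort from a raw (samples x proteins) array with NaNs."""
    n, p = values.shape
    idx = pd.Index([f"S{i}" for i in range(n)], name="sample_id")
    cols = pd.Index([f"P{j}" for j in range(p)], name="protein_id")
    pheno = pd.DataFrame(
        {
            "age": np.linspace(40, 70, n) if age is None else age,
            "sex": ["female", "male"] * (n // 2) + ["female"] * (n % 2)
            if sex is None
            else sex,
        },
        index=idx,
    )
    return Cohort(pheno, pd.DataFrame(values, index=idx, columns=cols))
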