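"""Shared fixtures: hand-built cohorts and a pooled null-simulation sample."""

import numpy as np
import pandas as pd
import pytest

from gxescreen import (
    Cohort,
    GenotypeStore,
    SampleTable,
    SimulationConfig,
    VariantRecord,
    simulate_null_tests,
)


def make_cohort(calls, status, exposure, exposure_name="alcohol", positions=None,
                chrom="1", probabilities=None, qualities=None, covariates=None):
    """Assemble a Cohort from raw arrays (variants x samples calls)."""
    calls = np.asarray(calls, dtype=np.int8)
    n_var, n_samp = calls.shape
    if positions is None:
        positions = [1 + 10_000 * i for i in range(n_var)]
    variants = [
        VariantRecord(id=f"v{i + 1}", chrom=chrom, pos=int(positions[i]),
                      quality=None if qualities is None else qualities[i])
        for i in range(n_var)
    ]
    sample_ids = [f"s{j + 1}" for j in range(n_samp)]
    data = {"status": np.asarray(status, dtype=np.int64),
            exposure_name: np.asarray(exposure, dtype=np.int64)}
    cov_names = []
    if covariates is not None:
        covariates = np.asarray(covariates, dtype=float)
        for k in range(covariates.shape[1]):
            cov_names.append(f"PC{k + 1}")
            data[f"PC{k + 1}"] = covariates[:, k]
    table = SampleTable(
        data=pd.DataFrame(data, index=pd.Index(sample_ids, name="sample_id")),
        exposure_names=[exposure_name], covariate_names=cov_names,
    )
    store = GenotypeStore(variants=variants, calls=calls, sample_ids=sample_ids,
                         probabilities=probabilities)
    return Cohort(genotypes=store, samples=table)


@pytest.fixture(scope="session")
def null_pairs():
    """20,000 null (p_joint, p_GE) pairs at the study design, shared across tests."""
    return simulate_null_tests(20_000, SimulationConfig(n_variants=1), seed=909)
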