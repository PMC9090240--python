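import numpy as np
import pandas as pd
import pytest

from uameth import CohortConfig, generate_cohort
from uameth.cohort import generate_genomic_context


@pytest.fixture(scope="session")
def default_cohort():
    """One default-scale synthetic cohort shared across tests (seed 1)."""
    cfg = CohortConfig(seed=1)
    matrices, sheet, ann, truth = generate_cohort(cfg)
    return cfg, matrices, sheet, ann, truth


@pytest.fixture(scope="session")
def default_context(default_cohort):
    cfg, matrices, sheet, ann, truth = default_cohort
    return generate_genomic_context(cfg, ann, truth)


@pytest.fixture(scope="session")
def seeded_cohorts():
    """Default-scale cohorts for seeds 0..4 (shared by over-seed checks)."""
    out = []
    for seed in range(5):
        cfg = CohortConfig(seed=seed)
        out.append((cfg, *generate_cohort(cfg)))
    return out


@pytest.fixture(scope="session")
def small_cohort():
    """A fast, small cohort for plumbing tests."""
    cfg = CohortConfig(seed=5, n_probes=1500, n_dmp_ua=60,
                       n_dmp_prognosis=40, n_activity_cpg=12, n_sf_dmp=40,
                       n_hd=6, n_gp=5, n_pp=5, n_sf_patients=6)
    matrices, sheet, ann, truth = generate_cohort(cfg)
    return cfg, matrices, sheet, ann, truth


def toy_matrix(values, probe_prefix="cg", sample_prefix="s"):
    """Build a MethylationMatrix from a nested list (probes x samples)."""
    from uameth import MethylationMatrix

    arr = np.asarray(values, dtype=float)
    return MethylationMatrix(pd.DataFrame(
        arr,
        index=[f"{probe_prefix}{i}" for i in range(arr.shape[0])],
        columns=[f"{sample_prefix}{j}" for j in range(arr.shape[1])],
    ))
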