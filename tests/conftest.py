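import numpy as np
import pandas as pd
import pytest

from gutmet.simulate import SimConfig, generate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """A reduced cohort shared by I/O and pipeline-level tests."""
    cfg = SimConfig(
        n_samples=80,
        n_metabolites=24,
        n_genera=24,
        n_kos=40,
        n_cytokines=6,
        n_cag_blocks=4,
        n_genus_groups=3,
        genus_group_size=5,
        mediation_triplets=(),
        seed=11,
    )
    return generate_cohort(cfg)


@pytest.fixture(scope="session")
def default_cohort():
    """One full-size cohort (the generator's default study conditions)."""
    return generate_cohort(SimConfig(seed=5))


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


def make_block_data(rng, n, sizes, rho, n_noise=0):
    """Samples x features matrix with planted correlated blocks (+ noise features)."""
    cols = {}
    truth = []
    j = 0
    for b, m in enumerate(sizes, start=1):
        f = rng.standard_normal(n)
        for _ in range(m):
            cols[f"f{j:03d}"] = np.sqrt(rho) * f + np.sqrt(1 - rho) * rng.standard_normal(n)
            truth.append(b)
            j += 1
    for _ in range(n_noise):
        cols[f"f{j:03d}"] = rng.standard_normal(n)
        truth.append(0)
        j += 1
    return pd.DataFrame(cols), np.array(truth)
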