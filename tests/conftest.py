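import numpy as np
import pandas as pd
import pytest

from dirdom.genotypes import GenotypeMatrix
from dirdom.gibbs_sampler import PhenotypeTable
from dirdom.synthetic_data import SimScenario, make_fixture, simulate


@pytest.fixture(scope="session")
def tiny_sim():
    """20 sows x 50 SNPs with planted QC violations (deterministic seed)."""
    return make_fixture("tiny")


@pytest.fixture(scope="session")
def small_sim():
    """A small but fittable dataset (60 sows, 150 SNPs)."""
    return simulate(SimScenario(n_sows=60, n_snp=150, n_groups=20, seed=5))


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)


@pytest.fixture(scope="session")
def micro_dataset():
    """8 records on 4 sows, 3 SNPs: the closed-form-oracle instance."""
    g_rng = np.random.default_rng(7)
    counts = g_rng.integers(0, 3, size=(4, 3))
    G = GenotypeMatrix(counts, [f"s{i}" for i in range(4)], ["A", "B", "C"])
    P = PhenotypeTable(
        pd.DataFrame(
            {
                "animal_id": ["s0", "s0", "s1", "s1", "s2", "s2", "s3", "s3"],
                "parity": [1] * 8,
                "group_id": ["g1", "g2"] * 4,
                "y": g_rng.normal(11, 2, 8),
            }
        )
    )
    return G, P
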