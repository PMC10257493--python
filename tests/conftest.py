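import numpy as np
import pytest

from karyofix import (
    GenotypeMatrix,
    Individual,
    KaryotypeLabel,
    Locus,
    SimConfig,
    simulate_cohort,
)


def build_matrix(calls, karyotypes, populations=None, loci=None):
    """Small-matrix builder: calls is a loci x individuals nested list."""
    calls = np.asarray(calls, dtype=np.int8)
    n_loci, n_ind = calls.shape
    pops = populations or ["bh"] * n_ind
    individuals = [
        Individual(f"i{j}", pops[j], KaryotypeLabel.parse(karyotypes[j]))
        for j in range(n_ind)
    ]
    loci = loci or [Locus(f"L{i}") for i in range(n_loci)]
    return GenotypeMatrix(loci, individuals, calls)


@pytest.fixture(scope="session")
def noiseless_sim():
    """Zero-noise simulated cohort (error 0, missing 0) with planted truth."""
    cfg = SimConfig(seed=11, n_loci=600, genotyping_error=0.0, missing_rate=0.0)
    return simulate_cohort(cfg)


@pytest.fixture(scope="session")
def noisy_sim():
    """Default-noise cohort (error 0.01, missing 0.05)."""
    cfg = SimConfig(seed=7, n_loci=600)
    return simulate_cohort(cfg)
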