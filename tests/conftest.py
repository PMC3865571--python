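import numpy as np
import pytest

from founderscan import SimParams, simulate_cohort


@pytest.fixture(scope="session")
def small_params():
    """Scaled-down cohort: 4 chromosomes, clean genotypes, fixed seed."""
    return SimParams(n_variants=1500, n_chromosomes=4, map_length_cm=80.0,
                     n_pop_controls=8, genotyping_error_rate=0.0,
                     missing_rate=0.0, seed=0)


@pytest.fixture(scope="session")
def small_sim(small_params):
    return simulate_cohort(small_params)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


def marker_grid(n_chrom=30, length_cm=100.0, per_chrom=100, q_low=0.2, q_high=0.8,
                seed=0):
    """Uniformly spaced marker scaffold used by HMM and calibration tests."""
    rng = np.random.default_rng(seed)
    chrom = np.repeat([f"chr{i + 1}" for i in range(n_chrom)], per_chrom)
    cm = np.tile(np.linspace(0.0, length_cm, per_chrom), n_chrom)
    q = rng.uniform(q_low, q_high, n_chrom * per_chrom)
    return chrom, cm, q
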