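import numpy as np
import pytest

from ntrtest.containers import PhenotypeVector, RegionGenotypes
from ntrtest.simulate import ScenarioConfig, sample_case_control


@pytest.fixture
def tiny_region():
    """3 variants x 6 individuals, fully called, minor-allele coded."""
    X = np.array(
        [
            [0, 1, 2, 1, 0, 0],
            [0, 0, 0, 1, 1, 0],
            [1, 0, 1, 0, 0, 1],
        ],
        dtype=np.int8,
    )
    return RegionGenotypes(
        region_id="toy",
        variant_ids=["snp1", "snp2", "snp3"],
        positions=np.array([100, 200, 300]),
        X=X,
        minor_allele=["C", "G", "T"],
        major_allele=["A", "A", "A"],
        chrom=["1", "1", "1"],
    )


@pytest.fixture
def tiny_phenotype():
    return PhenotypeVector(status=np.array([1, 1, 1, 0, 0, 0]))


@pytest.fixture(scope="session")
def small_simulated():
    """One modest simulated dataset with signal, reused across tests."""
    cfg = ScenarioConfig(
        rho=0.2, n_causal=8, n_noise=0, or_model=1.5,
        n_cases=300, n_controls=301,
    )
    return sample_case_control(cfg, seed=123)
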