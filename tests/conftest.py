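import numpy as np
import pandas as pd
import pytest

from rsnpscan.simulate import SimulationConfig, generate_study

# The published 3x3 genotype contingency for a tightly linked
# (regulatory SNP, coding marker) pair in 2504 individuals: rows count
# rare-allele (G) copies at the regulatory site, columns rare-allele (A)
# copies at the coding marker.
TABLE3 = np.array(
    [
        [1084, 5, 0],
        [9, 1042, 5],
        [0, 7, 352],
    ]
)


@pytest.fixture(scope="session")
def table3():
    return TABLE3.copy()


@pytest.fixture(scope="session")
def small_study():
    """A small but complete synthetic study shared across test modules."""
    cfg = SimulationConfig(
        n_individuals=300,
        n_sites=2000,
        n_true_rsnps=60,
        seed=7,
    )
    return generate_study(cfg)


@pytest.fixture()
def allele_count_frame():
    """Hand-written allele-count records for two sites and two samples."""
    return pd.DataFrame(
        {
            "chrom": ["chr1"] * 4,
            "pos": [100, 100, 200, 200],
            "ref": ["A"] * 4,
            "alt": ["G"] * 4,
            "ref_count": [6, 7, 30, 40],
            "alt_count": [5, 6, 2, 3],
            "sample": ["s1", "s2", "s1", "s2"],
            "assay": ["chip"] * 4,
            "site_id": ["chr1:100", "chr1:100", "chr1:200", "chr1:200"],
            "total": [11, 13, 32, 43],
        }
    )
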