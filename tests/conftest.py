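import sys
from pathlib import Path

import numpy as np
import pandas as pd
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # expose _oracles to tests

from recdiff.intervals import GenomeLayout, RegionSet
from recdiff import simulate


@pytest.fixture(scope="session")
def layout2() -> GenomeLayout:
    return GenomeLayout({"chr1": 10_000_000, "chr2": 10_000_000})


@pytest.fixture(scope="session")
def layout4() -> GenomeLayout:
    return GenomeLayout(
        {f"chr{i}": 10_000_000 for i in range(1, 5)}
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240915)


@pytest.fixture(scope="session")
def planted_snps(layout4):
    """SNP dataset with strongly differentiated planted windows."""
    params = simulate.DivergenceParams(
        layout=layout4, n_snps=20_000, f_base=0.02, f_high=0.4,
        n_planted=10, n1=40, n2=40, missing_rate=0.02, seed=11,
    )
    return simulate.simulate_genotypes(params)


@pytest.fixture(scope="session")
def shared_landscapes(layout2):
    """Two-population landscape set with a shared landscape (no divergence)."""
    params = simulate.LandscapeParams(layout=layout2, n_replicates=3, seed=7)
    return simulate.simulate_landscapes(params)


def regions(*triples) -> RegionSet:
    return RegionSet(pd.DataFrame(list(triples), columns=["chrom", "start", "end"]))
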