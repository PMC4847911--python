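import numpy as np
import pytest

from kinpatch.genotype import GenotypeTable
from kinpatch.simulate import SimulationConfig, simulate_study


@pytest.fixture
def tiny_table() -> GenotypeTable:
    """Two sites, two loci, handcheckable genotypes (one missing cell)."""
    alleles = np.array([
        [[100, 102], [200, 200]],
        [[100, 102], [200, 202]],
        [[102, 102], [0, 0]],
        [[100, 100], [202, 202]],
        [[100, 102], [200, 202]],
        [[102, 104], [200, 200]],
    ])
    return GenotypeTable(
        ids=[f"i{k}" for k in range(6)],
        sites=np.asarray(["A", "A", "A", "B", "B", "B"], object),
        loci=["locA", "locB"],
        alleles=alleles,
    )


@pytest.fixture(scope="session")
def kin_study():
    """Small kin-structured study with truth (3 sites, default noise)."""
    cfg = SimulationConfig(seed=2024, n_sites=3, site_size_range=(34, 50))
    return simulate_study(cfg)


@pytest.fixture(scope="session")
def panmictic_study():
    """Panmictic control of comparable size."""
    cfg = SimulationConfig(seed=2025, n_sites=3, site_size_range=(34, 50),
                           panmictic=True)
    return simulate_study(cfg)
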