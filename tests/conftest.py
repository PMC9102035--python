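import numpy as np
import pandas as pd
import pytest

from diallelmeth.pipeline import run_analysis
from diallelmeth.simulate import SimulationConfig, simulate_dataset


@pytest.fixture(scope="session")
def small_dataset():
    """A fast, fully featured synthetic diallel dataset for unit tests."""
    cfg = SimulationConfig(
        seed=7,
        n_chrom=4,
        chrom_len=500_000,
        n_genes=150,
        n_te=120,
        n_sites_per_context=1500,
        library_size_mean=150_000,
    )
    return simulate_dataset(cfg)


@pytest.fixture(scope="session")
def small_result(small_dataset):
    d = small_dataset
    return run_analysis(d["table"], d["design"], d["genes"], d["tes"], d["go_map"])


@pytest.fixture(scope="session")
def recovery_dataset():
    """The spike-recovery benchmark dataset: 20k sites per context, library
    mean 2e6, dispersion 0.01, 5% parental and 5% non-additive spikes at
    effect 2^3 with a uniform pattern mix (the generator defaults)."""
    return simulate_dataset(SimulationConfig(seed=1))


@pytest.fixture(scope="session")
def recovery_result(recovery_dataset):
    d = recovery_dataset
    return run_analysis(d["table"], d["design"], bh_correct=True)


@pytest.fixture
def toy_counts():
    """A tiny handwritten count table shared by several tests."""
    from diallelmeth.types import SiteCountTable

    sites = pd.DataFrame(
        {
            "chrom": ["chr1", "chr1", "chr2", "chr2"],
            "pos": [100, 250, 40, 900],
            "context": ["CCGG", "CCGG", "CCWGG", "CCWGG"],
        }
    )
    counts = np.array([[2, 4], [3, 6], [5, 10], [0, 0]])
    return SiteCountTable(sites, counts, ["s1", "s2"])
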