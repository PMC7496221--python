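import numpy as np
import pytest

from loopdiff.pipeline import run_hic_pipeline
from loopdiff.simulate import simulate_dataset
from loopdiff.fivec.counts_model import make_synthetic_5c_baseline


@pytest.fixture(scope="session")
def small_sim():
    """A small two-condition simulation with a moderate effect size."""
    return simulate_dataset(beta=0.6, p_diff=0.4, seed=42, n_bins=400,
                            n_loops=40, max_dist=100)


@pytest.fixture(scope="session")
def small_result(small_sim):
    return run_hic_pipeline(small_sim.counts, small_sim.design,
                            small_sim.loops, truth=small_sim.truth)


@pytest.fixture(scope="session")
def fivec_data():
    data, truth = make_synthetic_5c_baseline(n_frags=70, n_regions=1, seed=5)
    return data, truth
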