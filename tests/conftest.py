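import numpy as np
import pytest

from hbadeals.io_normalize import CASE, CONTROL, CountMatrix
from hbadeals.inference import build_model_inputs, run_mcmc
from hbadeals.io_normalize import filter_low_counts
from hbadeals.simulator import SimulationConfig, simulate_dataset


@pytest.fixture
def toy_cm() -> CountMatrix:
    """Two genes (one with 2 isoforms, one single-isoform), 4 samples."""
    return CountMatrix(
        isoform_ids=["gA.1", "gA.2", "gB.1"],
        gene_ids=["gA", "gA", "gB"],
        counts=np.array(
            [
                [10.0, 20.0, 30.0, 40.0],
                [30.0, 20.0, 10.0, 40.0],
                [60.0, 60.0, 60.0, 20.0],
            ]
        ),
        sample_ids=["c1", "c2", "k1", "k2"],
        condition_labels=[CONTROL, CONTROL, CASE, CASE],
    )


@pytest.fixture(scope="session")
def sim_small():
    """An 80-gene simulated dataset with DE and DS genes (seed 7)."""
    cfg = SimulationConfig(n_genes=80, seed=7)
    cm, truth = simulate_dataset(cfg)
    return filter_low_counts(cm), truth


@pytest.fixture(scope="session")
def draws_small(sim_small):
    """Short posterior run on the small dataset, shared across tests."""
    cm, _ = sim_small
    mi = build_model_inputs(cm)
    return run_mcmc(mi, warmup=300, steps=1300, seed=5), mi
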