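import numpy as np
import pytest

from erscan import PoolDesign, SelectedLocus, SimConfig, simulate_er_experiment


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_design():
    """G1 + one ambient and one hot treatment, two replicates each."""
    traj = (35,) * 6
    return (
        PoolDesign("G1", "ancestral", "ancestral", "-", 25, ()),
        PoolDesign("CGA", "ambient", "generalised", "A", 25, traj),
        PoolDesign("CGB", "ambient", "generalised", "B", 25, traj),
        PoolDesign("HGA", "hot", "generalised", "A", 25, traj),
        PoolDesign("HGB", "hot", "generalised", "B", 25, traj),
    )


@pytest.fixture
def small_sim(small_design):
    cfg = SimConfig(designs=small_design, n_chromosomes=2,
                    snps_per_chromosome=150, chromosome_length=1_000_000,
                    selected_loci=(SelectedLocus(40, 0.6, 0.6),
                                   SelectedLocus(200, 0.6, -0.6)),
                    depth_mean=100.0, seed=11)
    return simulate_er_experiment(cfg)
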