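import pytest

from refog_bench.benchmark_core import PredictedOGSet, RefOG
from refog_bench.simulator import SimConfig, random_species_tree, simulate_world


@pytest.fixture
def toy_refog():
    return RefOG(
        refog_id="RefOG100",
        members=frozenset({"1.p1", "1.p2", "2.p3", "2.p4", "3.p5", "3.p6"}),
    )


@pytest.fixture
def toy_predictions():
    return PredictedOGSet(
        dataset_name="toy",
        groups={
            "OG1": frozenset({"1.p1", "1.p2", "2.p3", "2.p4", "4.q1", "4.q2"}),
            "OG2": frozenset({"3.p5"}),
            "OG3": frozenset({"9.z1", "9.z2"}),
        },
    )


@pytest.fixture
def small_world_factory():
    """Build a small simulated world quickly; heavy layers optional."""

    def build(seed=0, n_ingroup=10, n_families=6, transfer_rate=0.15, **kwargs):
        tree, clades = random_species_tree(
            n_ingroup=n_ingroup, n_close=3, n_distant=3, seed=seed
        )
        config = SimConfig(
            species_tree=tree,
            n_families=n_families,
            transfer_rate=transfer_rate,
            seed=seed,
        )
        return simulate_world(config, clades=clades, **kwargs)

    return build
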