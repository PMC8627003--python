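import pandas as pd
import pytest

from rearlegacy import AsvTable, CommunityScenario, simulate_asv_experiment


@pytest.fixture
def tiny_table():
    """Six samples, four ASVs, two groups with distinct compositions."""
    counts = pd.DataFrame(
        [
            [30, 10, 0, 0],
            [28, 12, 1, 0],
            [25, 15, 0, 1],
            [2, 1, 20, 17],
            [1, 0, 22, 18],
            [0, 2, 19, 20],
        ],
        index=[f"s{i}" for i in range(6)],
        columns=["A1", "A2", "A3", "A4"],
    )
    meta = pd.DataFrame(
        {"group": ["x", "x", "x", "y", "y", "y"]}, index=counts.index
    )
    return AsvTable(counts, meta)


@pytest.fixture(scope="session")
def small_scenario():
    """Desk-scale version of the two-source convergence experiment."""
    return CommunityScenario(
        n_asvs=60,
        fts_richness=25,
        bfs_richness=50,
        ras_richness=40,
        depth_range=(600, 1800),
        fish_per_tank={15: 4, 63: 4, 105: 4},
        tanks_per_treatment=2,
        seed=42,
    )


@pytest.fixture(scope="session")
def small_experiment(small_scenario):
    return simulate_asv_experiment(small_scenario)
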