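import pandas as pd
import pytest

import structkit as sk


@pytest.fixture
def hand_matrix() -> sk.CoancestryMatrix:
    """4x4 coancestry fixture with hand-checkable copying vectors.

    Individuals a1, a2 (cluster A) and b1, b2 (cluster B).
    """
    ids = ["a1", "a2", "b1", "b2"]
    values = [
        [0.0, 10.0, 2.0, 4.0],
        [8.0, 0.0, 6.0, 2.0],
        [1.0, 3.0, 0.0, 12.0],
        [5.0, 1.0, 10.0, 0.0],
    ]
    return sk.CoancestryMatrix(pd.DataFrame(values, index=ids, columns=ids))


@pytest.fixture
def hand_clusters() -> sk.ClusterAssignment:
    return sk.ClusterAssignment.from_dict(
        {"a1": "A", "a2": "A", "b1": "B", "b2": "B"})


@pytest.fixture
def structured_cohort() -> sk.SyntheticCohort:
    """Strongly structured cohort: 3 demes x 20, large within-deme boost."""
    cfg = sk.ScenarioConfig(n_demes=3, n_per_deme=20, within_deme_boost=50.0,
                            spatial_decay=0.2, seed=7)
    return sk.generate_cohort(cfg)


def no_structure_config(seed: int, n_per_deme: int = 6) -> sk.ScenarioConfig:
    """Exchangeable cohort: no within-deme boost and a flat spatial kernel."""
    return sk.ScenarioConfig(n_demes=2, n_per_deme=n_per_deme,
                             within_deme_boost=0.0, spatial_decay=1e6,
                             dirichlet_concentration=50.0,
                             ibd_rate_within=0.0, ibd_rate_between=0.0,
                             seed=seed)
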