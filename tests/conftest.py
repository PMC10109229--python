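import pandas as pd
import pytest

import acutewell as aw

#: balanced-ish exposure proportions used for small test cohorts, so every
#: group retains enough complete cases after the inclusion filters
TEST_GROUPS = {"high": 0.25, "medium": 0.5, "low": 0.25}


@pytest.fixture(scope="session")
def small_config() -> aw.SimulationConfig:
    return aw.SimulationConfig(n_participants=60, seed=11,
                               group_proportions=dict(TEST_GROUPS))


@pytest.fixture(scope="session")
def small_cohort(small_config) -> dict[str, pd.DataFrame]:
    cfg = aw.SimulationConfig(n_participants=60, seed=11,
                              group_proportions=dict(TEST_GROUPS))
    # keep the GPS table small: 04:00-region samples are all inference needs
    cfg.gps.clock_window = (3.0, 5.0)
    return aw.generate_cohort(cfg)


@pytest.fixture(scope="session")
def cohort_dir(small_cohort, tmp_path_factory):
    cfg = aw.SimulationConfig(n_participants=60, seed=11,
                              group_proportions=dict(TEST_GROUPS))
    cfg.gps.clock_window = (3.0, 5.0)
    d = tmp_path_factory.mktemp("cohort")
    aw.write_cohort(small_cohort, d, cfg)
    return d


@pytest.fixture(scope="session")
def small_bundle(cohort_dir) -> aw.CohortBundle:
    return aw.read_cohort(cohort_dir)
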