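import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

import loomlab as ll
from loomlab.pipeline import simulate_participant_records

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def schedule_config():
    return ll.ScheduleConfig()


@pytest.fixture(scope="session")
def default_session(schedule_config):
    """One default 76-trial session with bets, ratings and timeline."""
    trials = ll.generate_schedule(schedule_config, seed=101)
    trials = ll.simulate_bets(trials, ll.BetPolicy(), seed=102)
    trials["luck_rating"] = ll.simulate_luck_ratings(trials, ll.LuckParams(), seed=103)
    timeline = ll.build_event_timeline(trials, schedule_config, rng=104)
    return trials, timeline


@pytest.fixture(scope="session")
def summary_cohort():
    """Summary-route cohort records for 12 participants (fast)."""
    cfg = ll.RunConfig(n_participants=12, master_seed=42, synthesis="summary")
    return pd.concat(
        [simulate_participant_records(cfg, i) for i in range(cfg.n_participants)],
        ignore_index=True,
    )


@pytest.fixture(scope="session")
def short_config():
    """A short session (few trials, brief rest) for trace-level tests."""
    return ll.ScheduleConfig(
        n_win=3, n_loss=3, n_near_win=2, n_near_loss=2, n_filler=2, rest_duration=20.0
    )
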