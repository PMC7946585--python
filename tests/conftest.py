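import numpy as np
import pandas as pd
import pytest

from uuscore.config import SimulationConfig, load_scenario


def make_config(**overrides) -> SimulationConfig:
    """A small, fully explicit scenario for unit tests."""
    base = load_scenario("trial_calibrated").to_dict()
    base["n_participants"] = 24
    base["seed"] = 123
    cfg = SimulationConfig.from_dict(base)
    return cfg.replace(**overrides) if overrides else cfg


@pytest.fixture(scope="session")
def small_config() -> SimulationConfig:
    return make_config()


@pytest.fixture(scope="session")
def small_cohort(small_config):
    from uuscore.simulate import simulate_cohort
    return simulate_cohort(small_config)


def make_logs(records) -> pd.DataFrame:
    """Build a daily-log frame from (pid, day, smbg, diet, ex, sent, read) rows."""
    return pd.DataFrame(records, columns=[
        "participant_id", "day", "smbg_recorded", "diet_recorded",
        "exercise_recorded", "messages_sent", "messages_read"]).astype({
        "smbg_recorded": bool, "diet_recorded": bool, "exercise_recorded": bool})


def make_visits(trajectories, outcome: str = "hba1c") -> pd.DataFrame:
    """Visit table from {pid: {month: value-or-nan}}; other outcomes constant."""
    from uuscore.io import VISIT_COLUMNS, VISIT_OUTCOMES
    rows = []
    for pid, by_month in trajectories.items():
        for month, value in by_month.items():
            row = {"participant_id": pid, "visit_month": month,
                   "observed": not np.isnan(value)}
            for col in VISIT_OUTCOMES:
                row[col] = value if col == outcome else 1.0
            rows.append(row)
    return pd.DataFrame(rows)[list(VISIT_COLUMNS)]
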