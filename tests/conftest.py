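import numpy as np
import pytest

from petlearn import FrameSchedule
from petlearn.synth import ReferenceModelParams, simulate_reference_tac


@pytest.fixture(scope="session")
def schedule():
    return FrameSchedule.default_90min()


@pytest.fixture(scope="session")
def ref_params():
    return ReferenceModelParams()


@pytest.fixture(scope="session")
def ref_tac(ref_params, schedule):
    return simulate_reference_tac(ref_params, schedule)


@pytest.fixture(scope="session")
def cohort_log():
    """The preset 5+5+4 study cohort trial log (simulated once per session)."""
    from petlearn.synth import simulate_cohort

    return simulate_cohort(seed=20160811)


def random_trial_log(rng: np.random.Generator, n_sessions: int = 2,
                     n_trials: int = 40, p_reward_a: float = 0.7):
    """A small random—but schema-valid—trial log for brute-force oracles."""
    import pandas as pd

    rows = []
    for s in range(1, n_sessions + 1):
        for t in range(1, n_trials + 1):
            a_left = bool(rng.random() < 0.5)
            left, right = ("A", "B") if a_left else ("B", "A")
            chosen = "A" if rng.random() < 0.5 else "B"
            side = "left" if chosen == left else "right"
            rewarded = int(rng.random() < (p_reward_a if chosen == "A" else 1 - p_reward_a))
            rows.append({
                "animal_id": "M1", "group": "control", "phase_label": "N1",
                "task_kind": "novel", "session_index": s, "trial_index": t,
                "left_stim": left, "right_stim": right, "chosen_stim": chosen,
                "chosen_side": side, "rewarded": rewarded,
                "response_time_s": float(rng.lognormal(0, 0.3)),
                "aborted_session": 0, "intertrial_s": 3.0,
            })
    return pd.DataFrame(rows)
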