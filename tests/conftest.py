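import numpy as np
import pandas as pd
import pytest

from slcurves import (
    CohortSpec,
    SessionDesign,
    generate_session,
    label_trials,
    simulate_cohort,
)


@pytest.fixture(scope="session")
def default_design():
    return SessionDesign()


@pytest.fixture(scope="session")
def labeled_session(default_design):
    """One default 36x85 session, condition-labeled, pattern (1,2,3,4)."""
    trials = generate_session(default_design, seed=11)
    return label_trials(trials, default_design.pattern)


@pytest.fixture(scope="session")
def small_cohort():
    """Six participants, 12 blocks: fast but structurally complete."""
    design = SessionDesign(n_blocks=12)
    spec = CohortSpec(n_participants=6)
    return simulate_cohort(design, spec, seed=21)


def make_summaries(
    n_blocks=36,
    rh=280.5,
    rl_offset=9.8,
    ph=284.1,
    noise_sd=0.0,
    seed=0,
    participant_id="group",
):
    """Hand-built condition summaries with a constant RL-RH offset."""
    rng = np.random.default_rng(seed)
    rows = []
    for b in range(1, n_blocks + 1):
        for cond, mu in (("PH", ph), ("RH", rh), ("RL", rh + rl_offset)):
            rows.append(
                {
                    "participant_id": participant_id,
                    "block": b,
                    "condition": cond,
                    "mean_rt_ms": mu + rng.normal(0, noise_sd),
                    "n_trials": 40 if cond == "PH" else (10 if cond == "RH" else 30),
                    "n_correct": 37 if cond == "PH" else (9 if cond == "RH" else 27),
                    "accuracy": 0.92,
                }
            )
    return pd.DataFrame(rows)
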