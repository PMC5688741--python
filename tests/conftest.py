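import numpy as np
import pandas as pd
import pytest

import worklife as wl
from worklife.states import StateSpace, Transition


@pytest.fixture(scope="session")
def survival_space():
    """Two-state pure-survival space (alive -> dead)."""
    return StateSpace(
        states={"A": "transdurable", "Dead": "absorbing"},
        transitions=[Transition(("A",), "Dead")],
        wle_states={"A"},
        pension_age=100.0,
    )


@pytest.fixture(scope="session")
def survival_toy(survival_space):
    """10 subjects: single deaths at ages 1..5, five censored at 6."""
    rows = []
    for i in range(10):
        t = float(i + 1) if i < 5 else 6.0
        to = "Dead" if i < 5 else wl.CENSORED
        rows.append(
            {"subject_id": i, "entry_age": 0.0, "exit_age": t,
             "from_state": "A", "to_state": to, "weight": 1.0}
        )
    return pd.DataFrame(rows)


@pytest.fixture(scope="session")
def illness_death_space():
    """Three-state illness-death model with recovery."""
    return StateSpace(
        states={"W": "transdurable", "S": "transdurable", "D": "absorbing"},
        transitions=[
            Transition(("W",), "S"),
            Transition(("S",), "W"),
            Transition(("W",), "D"),
            Transition(("S",), "D"),
        ],
        wle_states={"W", "S"},
        pension_age=65.0,
    )


def illness_death_config(n, seed, with_cov=False):
    space = StateSpace(
        states={"W": "transdurable", "S": "transdurable", "D": "absorbing"},
        transitions=[
            Transition(("W",), "S"),
            Transition(("S",), "W"),
            Transition(("W",), "D"),
            Transition(("S",), "D"),
        ],
        wle_states={"W", "S"},
        pension_age=65.0,
    )
    return wl.SimulationConfig(
        space=space,
        n_subjects=n,
        baseline={
            "W->S": wl.PiecewiseRate.constant(0.4),
            "S->W": wl.PiecewiseRate.constant(1.5),
            "W->D": wl.PiecewiseRate.constant(0.08),
            "S->D": wl.PiecewiseRate.constant(0.3),
        },
        log_hr=(
            {"W->S": {"x": np.log(2.0)}, "W->D": {"x": np.log(1.5)}}
            if with_cov else {}
        ),
        covariate_prevalence={"x": 0.5} if with_cov else {},
        seed=seed,
    )


@pytest.fixture(scope="session")
def labor_cohort():
    """Shipped labor-market scenario, modest size, with its config."""
    cfg = wl.default_scenario(n_subjects=800, seed=7)
    return cfg, wl.simulate_cohort(cfg)
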