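import numpy as np
import pandas as pd
import pytest

from survdelta import SimulationConfig, simulate_cohort


def random_cohort(rng: np.random.Generator, n: int = 50, n_strata: int = 1,
                  censor_prob: float = 0.3) -> pd.DataFrame:
    """Small arbitrary cohort (not from the mixture model) for algebraic checks."""
    followup = rng.exponential(size=n)
    event = (rng.uniform(size=n) > censor_prob).astype(int)
    if event.sum() == 0:
        event[rng.integers(n)] = 1
    return pd.DataFrame(
        {
            "entry_age": np.zeros(n),
            "followup_age": followup,
            "event": event,
            "marker": rng.standard_normal(n),
            "stratum": rng.integers(0, n_strata, size=n),
        }
    )


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def small_cohort(rng):
    return random_cohort(rng, n=40)


@pytest.fixture
def null_cohort():
    """Cohort simulated with no marker effect, 50% tail defect."""
    return simulate_cohort(SimulationConfig(tail_defect=0.5, n_subjects=300, seed=7))


def mc_delta_mean(alpha_hr, beta_hr, tail, n=500, reps=300, seed0=11, **config_kw):
    """Replication mean of Delta for one simulation cell (degenerate draws dropped)."""
    from survdelta import delta_from_cohort
    from survdelta.exceptions import DegenerateCohortError

    values = []
    for rep in range(reps):
        config = SimulationConfig(
            alpha=float(np.log(alpha_hr)),
            beta=float(np.log(beta_hr)),
            tail_defect=tail,
            n_subjects=n,
            seed=seed0 + rep,
            **config_kw,
        )
        try:
            values.append(delta_from_cohort(simulate_cohort(config)).delta)
        except DegenerateCohortError:
            continue
    assert len(values) >= 0.95 * reps, "too many degenerate replications"
    return float(np.mean(values))
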