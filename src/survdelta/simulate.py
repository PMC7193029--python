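"""Synthetic cohorts from a two-component ("cure"/tail-defect) survival model.

The population is a mixture: with probability ``exp(-theta * e**(alpha*z))`` a
subject is non-susceptible to the event within the projection window (the
*tail defect*), otherwise the event time follows a proper conditional law with
cumulative hazard ``Lambda0(t) * e**(beta*z)``.  ``alpha`` is the *propensity*
effect of the marker ``z`` (on being susceptible at all), ``beta`` its
*dynamic* effect (on the hazard among susceptible subjects).  The marginal
survival function is

    S(t | z) = exp(-theta e^{a z}) + (1 - exp(-theta e^{a z})) exp(-Lambda0(t) e^{b z})

Two families are provided:

* ``exponential-two-part`` — the mixture above with Lambda0(t) = t;
* ``gompertz-improper`` — a single improper Gompertz law
  S(t | z) = exp(-theta e^{a z} (1 - exp(-t e^{b z}))), whose plateau is the
  same tail defect; used to study misspecification of the mixture form.

Censoring, when requested, is uniform on [0, u] for every subject; ``u`` is
calibrated by :func:`censoring_bound` so that the expected fraction of
*susceptible* subjects censored before their event hits the target (the
non-susceptible never have events, so they are excluded from the censoring
percentage by convention).  Without censoring, non-susceptible subjects are
administratively censored at 1.01x the largest susceptible event time.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .exceptions import ConfigurationError

COVARIATE_LAWS = ("standard-normal", "student-t")
SURVIVAL_FAMILIES = ("exponential-two-part", "gompertz-improper")

#: canonical cohort column order used across the package and the CLI
COHORT_COLUMNS = ("entry_age", "followup_age", "event", "marker", "stratum")

# Monte-Carlo sample used to calibrate the censoring bound; fixed seed so the
# bound is a deterministic function of the model parameters only.
_BOUND_MC_SIZE = 200_000
_BOUND_MC_SEED = 1_000_003
_HORIZON_FACTOR = 1.01
_STUDENT_DF = 10


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of one simulated cohort.

    Parameters
    ----------
    alpha : log hazard-ratio of the marker on the propensity of susceptibility.
    beta : log hazard-ratio of the marker on the event dynamic.
    tail_defect : baseline non-susceptible probability exp(-theta), in (0, 1).
    n_subjects : cohort size (>= 2).
    covariate_law : ``"standard-normal"`` or ``"student-t"`` (10 df).
    survival_family : ``"exponential-two-part"`` or ``"gompertz-improper"``.
    censor_fraction : target censored fraction among susceptible subjects, in [0, 1).
    n_strata : 1, or 2 for a Bernoulli(0.5) nuisance stratification label.
    seed : integer seed; cohorts are byte-identical for equal seeds.
    """

    alpha: float = 0.0
    beta: float = 0.0
    tail_defect: float = 0.5
    n_subjects: int = 500
    covariate_law: str = "standard-normal"
    survival_family: str = "exponential-two-part"
    censor_fraction: float = 0.0
    n_strata: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.tail_defect < 1.0:
            raise ConfigurationError(f"tail_defect must be in (0, 1), got {self.tail_defect}")
        if self.n_subjects < 2:
            raise ConfigurationError(f"n_subjects must be >= 2, got {self.n_subjects}")
        if not 0.0 <= self.censor_fraction < 1.0:
            raise ConfigurationError(
                f"censor_fraction must be in [0, 1), got {self.censor_fraction}"
            )
        if self.covariate_law not in COVARIATE_LAWS:
            raise ConfigurationError(
                f"unknown covariate_law {self.covariate_law!r}; choose from {COVARIATE_LAWS}"
            )
        if self.survival_family not in SURVIVAL_FAMILIES:
            raise ConfigurationError(
                f"unknown survival_family {self.survival_family!r}; "
                f"choose from {SURVIVAL_FAMILIES}"
            )
        if self.n_strata not in (1, 2):
            raise ConfigurationError(f"n_strata must be 1 or 2, got {self.n_strata}")

    @property
    def theta(self) -> float:
        """Baseline tail-defect parameter theta = -log(tail_defect) > 0."""
        return -math.log(self.tail_defect)


def _draw_marker(rng: np.random.Generator, law: str, size: int) -> np.ndarray:
    if law == "standard-normal":
        return rng.standard_normal(size)
    return rng.standard_t(_STUDENT_DF, size=size)


def _draw_event_times(
    rng: np.random.Generator, config: SimulationConfig, z: np.ndarray
) -> np.ndarray:
    """Conditional (susceptible-subject) event times given the marker."""
    v = np.exp(config.beta * z)
    if config.survival_family == "exponential-two-part":
        # cumulative hazard t * e^{beta z}  =>  T = E / e^{beta z}, E ~ Exp(1)
        return rng.exponential(size=z.size) / v
    # Improper Gompertz: invert the normalized conditional CDF
    #   F(t|z) = (1 - exp(-q (1 - e^{-t v}))) / (1 - e^{-q}),  q = theta e^{alpha z}
    u = rng.uniform(size=z.size)
    q = config.theta * np.exp(config.alpha * z)
    g = -np.expm1(-q)  # 1 - e^{-q}
    inner = np.log1p(-u * g) / q  # in (-1, 0]
    return -np.log1p(inner) / v


def censoring_bound(config: SimulationConfig) -> float:
    """Upper end ``u`` of the Uniform[0, u] censoring law hitting the target fraction.

    Solves E[min(T, u)] / u = censor_fraction over the susceptible-subject event
    time distribution (P(C < T | susceptible) with C ~ U[0, u]), by root-finding
    on a fixed large Monte-Carlo sample.  Deterministic given the configuration;
    absolute accuracy of the attained fraction is well within 0.005.
    """
    if config.censor_fraction <= 0.0:
        raise ConfigurationError("censoring_bound requires censor_fraction > 0")
    rng = np.random.default_rng(_BOUND_MC_SEED)
    z = _draw_marker(rng, config.covariate_law, _BOUND_MC_SIZE)
    # weight each draw by its susceptibility probability 1 - exp(-theta e^{alpha z})
    w = -np.expm1(-config.theta * np.exp(config.alpha * z))
    t = _draw_event_times(rng, config, z)
    w_total = float(w.sum())

    def censored_fraction(u: float) -> float:
        return float(np.dot(w, np.minimum(t, u))) / (u * w_total)

    target = config.censor_fraction
    hi = max(float(t.max()), 1.0)
    for _ in range(200):
        if censored_fraction(hi) < target:
            break
        hi *= 2.0
    else:
        raise ConfigurationError(
            f"censor_fraction={target} unattainable for this configuration"
        )
    lo = 1e-9 * hi
    while censored_fraction(lo) <= target:  # pragma: no cover - defensive
        lo *= 0.5
    return float(brentq(lambda u: censored_fraction(u) - target, lo, hi, xtol=1e-12, rtol=1e-12))


def simulate_cohort(config: SimulationConfig) -> pd.DataFrame:
    """Simulate one cohort; returns a DataFrame with :data:`COHORT_COLUMNS`.

    Draw order (one ``numpy.random.default_rng(seed)`` stream): marker, stratum
    label, susceptibility uniform, latent event time, censoring time.  Latent
    quantities (true susceptibility, uncensored event times) never leave this
    function.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_subjects
    z = _draw_marker(rng, config.covariate_law, n)
    if config.n_strata == 2:
        stratum = rng.integers(0, 2, size=n)
    else:
        stratum = np.zeros(n, dtype=np.int64)
    p_nonsusceptible = np.exp(-config.theta * np.exp(config.alpha * z))
    susceptible = rng.uniform(size=n) >= p_nonsusceptible
    t = _draw_event_times(rng, config, z)

    if config.censor_fraction > 0.0:
        u = censoring_bound(config)
        c = rng.uniform(0.0, u, size=n)
        followup = np.where(susceptible, np.minimum(t, c), c)
        event = susceptible & (t <= c)
    else:
        horizon = _HORIZON_FACTOR * float(t[susceptible].max()) if susceptible.any() else 1.0
        followup = np.where(susceptible, t, horizon)
        event = susceptible

    return pd.DataFrame(
        {
            "entry_age": np.zeros(n),
            "followup_age": followup,
            "event": event.astype(np.int64),
            "marker": z,
            "stratum": stratum,
        }
    )


def write_cohort(cohort: pd.DataFrame, path) -> None:
    """Write a cohort as CSV with the canonical header."""
    cohort.loc[:, list(COHORT_COLUMNS)].to_csv(path, index=False)


def read_cohort(path) -> pd.DataFrame:
    """Read a cohort CSV, checking the canonical columns are present."""
    cohort = pd.read_csv(path)
    missing = [c for c in COHORT_COLUMNS if c not in cohort.columns]
    if missing:
        raise ConfigurationError(f"cohort file {path} lacks columns {missing}")
    return cohort
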