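"""Nuisance quantities under the null hypothesis of no marker effect.

Everything is computed per entry-age stratum, marker-free (alpha = beta = 0):

* the marginal survival function — Fleming–Harrington form
  ``S(t) = exp(-A(t))`` with ``A`` the Nelson–Aalen cumulative hazard,
  evaluated *left-continuously* at event ages (the value just before the jump);
* the tail-defect parameter ``theta_hat = -log S(tmax+)``, where ``S(tmax+)``
  is the survival plateau just after the last observed failure age, so that
  ``exp(-theta_hat)`` is the estimated non-susceptible fraction;
* the baseline conditional cumulative hazard of the susceptible component,
  obtained by inverting the mixture survival at the null:
  ``Lambda0(t) = -log[(S(t) - e^{-theta}) / (1 - e^{-theta})]``.

Ties are handled Breslow-style: the ``d`` events at a common age share one risk
set.  Risk sets use ``Y(s) = 1(X >= s)``; an optional delayed-entry mode uses
``1(entry < s <= X)`` for real age-scale cohorts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import EstimationError

THETA_CONVENTIONS = ("plateau", "printed")


@dataclass
class StratumNullEstimates:
    """Null-hypothesis estimates for one stratum, tabulated at its event ages.

    ``surv_left``/``cumhaz0`` hold the left-continuous values S(a_l-),
    Lambda0(a_l-) at each distinct event age; ``surv_right``/``cumhaz0_right``
    the values just after the jump (needed to evaluate the step functions at
    arbitrary ages).  ``k_j`` counts event contributions (with multiplicity).
    """

    stratum: object
    event_times: np.ndarray
    n_events_at: np.ndarray
    n_at_risk: np.ndarray
    surv_left: np.ndarray
    surv_right: np.ndarray
    surv_plateau: float
    theta_hat: float = np.nan
    cumhaz0: np.ndarray | None = None
    cumhaz0_right: np.ndarray | None = None
    n_clipped: int = 0
    theta_flagged: bool = field(default=False)

    @property
    def k_j(self) -> int:
        return int(self.n_events_at.sum())

    @property
    def tail_defect_hat(self) -> float:
        """exp(-theta_hat); 0.0 when theta_hat is infinite (no plateau)."""
        return float(np.exp(-self.theta_hat))

    def to_frame(self) -> pd.DataFrame:
        """Dump the per-event-age estimates for debugging."""
        return pd.DataFrame(
            {
                "stratum": self.stratum,
                "event_time": self.event_times,
                "n_events": self.n_events_at,
                "n_at_risk": self.n_at_risk,
                "surv_left": self.surv_left,
                "cumhaz0": self.cumhaz0,
            }
        )


def _risk_counts(
    times: np.ndarray, event_ages: np.ndarray, entry: np.ndarray | None
) -> np.ndarray:
    """Number at risk at each event age: #{X >= a}  (minus #{entry >= a} if delayed)."""
    x_sorted = np.sort(times)
    at_risk = times.size - np.searchsorted(x_sorted, event_ages, side="left")
    if entry is not None:
        e_sorted = np.sort(entry)
        not_entered = entry.size - np.searchsorted(e_sorted, event_ages, side="left")
        at_risk = at_risk - not_entered
    return at_risk


def marginal_survival(
    followup: np.ndarray,
    event: np.ndarray,
    stratum: object = 0,
    entry: np.ndarray | None = None,
) -> StratumNullEstimates:
    """Nelson–Aalen / Fleming–Harrington marginal survival for one stratum.

    Returns the estimates with ``surv_left`` filled in; ``theta_hat`` and
    ``cumhaz0`` are left for :func:`tail_defect_estimate` and
    :func:`baseline_cumhaz`.
    """
    followup = np.asarray(followup, dtype=float)
    event = np.asarray(event).astype(bool)
    if not event.any():
        raise EstimationError(f"stratum {stratum!r}: no events, survival not estimable")
    event_ages, d = np.unique(followup[event], return_counts=True)
    r = _risk_counts(followup, event_ages, entry)
    if np.any(r <= 0):
        raise EstimationError(f"stratum {stratum!r}: empty risk set at an event age")
    jumps = d / r
    cumhaz_right = np.cumsum(jumps)
    cumhaz_left = cumhaz_right - jumps
    return StratumNullEstimates(
        stratum=stratum,
        event_times=event_ages,
        n_events_at=d,
        n_at_risk=r,
        surv_left=np.exp(-cumhaz_left),
        surv_right=np.exp(-cumhaz_right),
        surv_plateau=float(np.exp(-cumhaz_right[-1])),
    )


def tail_defect_estimate(
    estimates: StratumNullEstimates, convention: str = "plateau"
) -> float:
    """Estimate theta from the survival plateau after the last failure age.

    ``convention="plateau"`` (default): theta_hat = -log S(tmax+), so that
    exp(-theta_hat) equals the estimated non-susceptible fraction — the
    quantity the mixture survival model calls the tail defect.  The
    ``"printed"`` variant theta_hat = -log(1 - S(tmax+)) is retained for audit
    only; it swaps the roles of the susceptible and non-susceptible fractions.

    A plateau of exactly 0 (the last observation is an event) yields
    theta_hat = +inf with ``theta_flagged`` set; downstream the propensity
    weight degenerates to 0 and the pseudo-R2 is undefined.
    """
    if convention not in THETA_CONVENTIONS:
        raise EstimationError(f"unknown theta convention {convention!r}")
    p = estimates.surv_plateau
    if convention == "printed":
        p = 1.0 - p
    if p <= 0.0:
        estimates.theta_hat = np.inf
        estimates.theta_flagged = True
    else:
        estimates.theta_hat = float(-np.log(p))
        estimates.theta_flagged = False
    return estimates.theta_hat


def _invert_mixture(surv: np.ndarray, defect: float) -> tuple[np.ndarray, int]:
    """Lambda0 = -log[(S - p)/(1 - p)], clipping where S <= p to the last finite value."""
    ratio = (surv - defect) / (1.0 - defect)
    valid = ratio > 0.0
    lam = np.full(surv.shape, np.nan)
    lam[valid] = -np.log(ratio[valid])
    n_clipped = int((~valid).sum())
    if n_clipped:
        # forward-fill invalid entries with the largest finite preceding value
        last = 0.0
        for i in range(lam.size):
            if np.isnan(lam[i]):
                lam[i] = last
            else:
                last = lam[i]
    return lam, n_clipped


def baseline_cumhaz(estimates: StratumNullEstimates) -> np.ndarray:
    """Baseline conditional cumulative hazard at event ages (left-continuous).

    Requires ``theta_hat`` to be set.  theta_hat = 0 would make the mixture
    degenerate (everyone non-susceptible) and raises; theta_hat = +inf reduces
    the inversion to the plain Nelson–Aalen cumulative hazard (no plateau).
    """
    if np.isnan(estimates.theta_hat):
        raise EstimationError("theta_hat not set; run tail_defect_estimate first")
    if estimates.theta_hat == 0.0:
        raise EstimationError("theta_hat = 0: degenerate mixture, Lambda0 undefined")
    defect = estimates.tail_defect_hat
    lam_left, clipped_left = _invert_mixture(estimates.surv_left, defect)
    lam_right, _ = _invert_mixture(estimates.surv_right, defect)
    estimates.cumhaz0 = lam_left
    estimates.cumhaz0_right = lam_right
    # only left-continuous values feed the weights; the right limit at the last
    # failure age always sits on the plateau and is clipped by construction
    estimates.n_clipped = clipped_left
    return lam_left


def fit_stratum(
    followup: np.ndarray,
    event: np.ndarray,
    stratum: object = 0,
    entry: np.ndarray | None = None,
    theta_convention: str = "plateau",
) -> StratumNullEstimates:
    """marginal survival -> theta_hat -> baseline cumulative hazard, one stratum."""
    est = marginal_survival(followup, event, stratum=stratum, entry=entry)
    tail_defect_estimate(est, convention=theta_convention)
    baseline_cumhaz(est)
    return est


def fit_null(
    cohort: pd.DataFrame,
    delayed_entry: bool = False,
    theta_convention: str = "plateau",
) -> dict:
    """Null estimates for every stratum of a cohort that contains events.

    Strata without events are skipped (they contribute no score rows); if no
    stratum has an event the cohort is not analysable.
    """
    estimates: dict = {}
    for label, grp in cohort.groupby("stratum", sort=True):
        if not grp["event"].astype(bool).any():
            continue
        entry = grp["entry_age"].to_numpy(dtype=float) if delayed_entry else None
        estimates[label] = fit_stratum(
            grp["followup_age"].to_numpy(dtype=float),
            grp["event"].to_numpy(),
            stratum=label,
            entry=entry,
            theta_convention=theta_convention,
        )
    if not estimates:
        raise EstimationError("no stratum contains an event")
    return estimates
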