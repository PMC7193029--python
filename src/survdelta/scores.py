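"""Score components of the mixture partial likelihood and their robust shifts.

At each event age the log partial-likelihood of the two-component model has two
score contributions per failing subject, evaluated under the null:

* ``U1`` (propensity component), built with weight
  ``w1(s) = e^{-theta} theta / S(s-)``;
* ``U2`` (dynamic component), with weight
  ``w2(s) = [e^{-theta}(1 - e^{-L(s-)} - L(s-)) + e^{-L(s-)}] / S(s-)``,
  where ``L`` is the baseline conditional cumulative hazard.

Each contribution is ``U_k = w_k(a) * (z_i - zbar(a))`` with ``zbar`` the mean
marker over the risk set at the event age (the weight being constant across a
risk set at fixed age, it cancels inside the bracket; the literal weighted form
is computed and checked).  ``w2`` can legitimately go negative once the
cumulative hazard exceeds ~1 under a substantial tail defect; the formula is
applied literally.

Because the raw contributions are dependent across subjects, they are shifted
by their estimated compensator (the Lin–Wei robust-score construction): for
every subject, event or censored,

    Ushift_k(i) = sum over event ages a_l <= X_i of
                  w_k(a_l) * (d_l / r_l) * (z_i - zbar(a_l)),

and ``W_k = U_k - Ushift_k``.  The shifted scores are i.i.d. under the null;
only the rows at event times (``W*``) feed the pseudo-R2.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .exceptions import DegenerateCohortError, EstimationError
from .nullfit import StratumNullEstimates

#: columns of the per-subject score table
SCORE_COLUMNS = (
    "stratum",
    "event",
    "marker",
    "weight_w1",
    "weight_w2",
    "score_u1",
    "score_u2",
    "shift_u1",
    "shift_u2",
    "shifted_w1",
    "shifted_w2",
)


def _weights_from_values(
    theta_hat: float, surv: np.ndarray | float, cumhaz: np.ndarray | float
) -> tuple[np.ndarray, np.ndarray]:
    surv = np.asarray(surv, dtype=float)
    cumhaz = np.asarray(cumhaz, dtype=float)
    if np.any(surv <= 0.0):
        raise EstimationError("marginal survival is 0 at an evaluation age")
    defect = float(np.exp(-theta_hat))
    # e^{-theta} * theta -> 0 in the no-plateau limit theta -> inf
    w1_num = 0.0 if np.isinf(theta_hat) else defect * theta_hat
    w1 = np.broadcast_to(w1_num, surv.shape) / surv
    exp_l = np.exp(-cumhaz)
    w2 = (defect * (1.0 - exp_l - cumhaz) + exp_l) / surv
    return w1, w2


def weights(estimates: StratumNullEstimates, age: float) -> tuple[float, float]:
    """(w1, w2) at an arbitrary age, using left-continuous plug-in estimates."""
    if estimates.cumhaz0 is None:
        raise EstimationError("baseline cumulative hazard not computed")
    times = estimates.event_times
    m = int(np.searchsorted(times, age, side="left"))
    if m < times.size and times[m] == age:
        surv, cumhaz = estimates.surv_left[m], estimates.cumhaz0[m]
    elif m == 0:
        surv, cumhaz = 1.0, 0.0
    else:
        surv, cumhaz = estimates.surv_right[m - 1], estimates.cumhaz0_right[m - 1]
    w1, w2 = _weights_from_values(estimates.theta_hat, surv, cumhaz)
    return float(w1), float(w2)


def weights_at_event_times(
    estimates: StratumNullEstimates,
) -> tuple[np.ndarray, np.ndarray]:
    """(w1, w2) arrays at every distinct event age of the stratum."""
    if estimates.cumhaz0 is None:
        raise EstimationError("baseline cumulative hazard not computed")
    return _weights_from_values(
        estimates.theta_hat, estimates.surv_left, estimates.cumhaz0
    )


def _stratum_scores(
    grp: pd.DataFrame,
    est: StratumNullEstimates,
    delayed_entry: bool,
    check_cancellation: bool,
) -> pd.DataFrame:
    x = grp["followup_age"].to_numpy(dtype=float)
    delta = grp["event"].to_numpy().astype(bool)
    z = grp["marker"].to_numpy(dtype=float)
    entry = grp["entry_age"].to_numpy(dtype=float) if delayed_entry else None

    times = est.event_times
    d = est.n_events_at.astype(float)
    w1, w2 = weights_at_event_times(est)

    # risk-set size and marker mean at each event age via suffix sums
    order = np.argsort(x, kind="mergesort")
    x_sorted = x[order]
    z_suffix = np.concatenate([np.cumsum(z[order][::-1])[::-1], [0.0]])
    pos = np.searchsorted(x_sorted, times, side="left")
    r = (x.size - pos).astype(float)
    z_risk_sum = z_suffix[pos]
    if entry is not None:
        e_order = np.argsort(entry, kind="mergesort")
        e_sorted = entry[e_order]
        ze_suffix = np.concatenate([np.cumsum(z[e_order][::-1])[::-1], [0.0]])
        epos = np.searchsorted(e_sorted, times, side="left")
        r = r - (entry.size - epos)
        z_risk_sum = z_risk_sum - ze_suffix[epos]
    if np.any(r <= 0):
        raise EstimationError(f"stratum {est.stratum!r}: empty risk set")
    zbar = z_risk_sum / r

    if check_cancellation:
        # the weight is constant within a risk set at fixed age, so the literal
        # weighted mean sum(w z)/sum(w) must coincide with the plain mean
        for w in (w1, w2):
            nz = w != 0.0
            literal = (w[nz] * z_risk_sum[nz]) / (w[nz] * r[nz])
            if not np.allclose(literal, zbar[nz], rtol=0.0, atol=1e-10):
                raise AssertionError("weight cancellation identity violated")

    # raw scores: only event rows are non-zero
    u1 = np.zeros(x.size)
    u2 = np.zeros(x.size)
    own_w1 = np.full(x.size, np.nan)
    own_w2 = np.full(x.size, np.nan)
    if delta.any():
        li = np.searchsorted(times, x[delta])  # index of each subject's event age
        centered = z[delta] - zbar[li]
        u1[delta] = w1[li] * centered
        u2[delta] = w2[li] * centered
        own_w1[delta] = w1[li]
        own_w2[delta] = w2[li]

    # shifts: prefix sums over event ages of c_kl = w_k d_l / r_l and c_kl*zbar_l
    c1 = w1 * d / r
    c2 = w2 * d / r
    p1 = np.concatenate([[0.0], np.cumsum(c1)])
    p2 = np.concatenate([[0.0], np.cumsum(c2)])
    q1 = np.concatenate([[0.0], np.cumsum(c1 * zbar)])
    q2 = np.concatenate([[0.0], np.cumsum(c2 * zbar)])
    hi = np.searchsorted(times, x, side="right")
    if entry is not None:
        lo = np.searchsorted(times, entry, side="right")
    else:
        lo = np.zeros(x.size, dtype=np.int64)
    shift1 = z * (p1[hi] - p1[lo]) - (q1[hi] - q1[lo])
    shift2 = z * (p2[hi] - p2[lo]) - (q2[hi] - q2[lo])

    return pd.DataFrame(
        {
            "stratum": est.stratum,
            "event": delta.astype(np.int64),
            "marker": z,
            "weight_w1": own_w1,
            "weight_w2": own_w2,
            "score_u1": u1,
            "score_u2": u2,
            "shift_u1": shift1,
            "shift_u2": shift2,
            "shifted_w1": u1 - shift1,
            "shifted_w2": u2 - shift2,
        },
        index=grp.index,
    )


def score_table(
    cohort: pd.DataFrame,
    estimates: dict,
    delayed_entry: bool = False,
    check_cancellation: bool = True,
) -> pd.DataFrame:
    """Per-subject score table (raw, shift, shifted) across all strata.

    Strata absent from ``estimates`` (no events) contribute no rows.
    """
    pieces = []
    for label, grp in cohort.groupby("stratum", sort=True):
        if label not in estimates:
            continue
        pieces.append(
            _stratum_scores(grp, estimates[label], delayed_entry, check_cancellation)
        )
    if not pieces:
        raise EstimationError("no stratum with null estimates")
    return pd.concat(pieces).sort_index()


def separability_form(
    cohort: pd.DataFrame, estimates: dict, delayed_entry: bool = False
) -> pd.DataFrame:
    """Raw scores via the leave-one-out (separability) factorization.

    Each event contribution is rewritten as
    ``w_k * (sum_{R*} w_k / sum_R w_k) * (z_i - zbar_{R*})`` where ``R*`` is the
    risk set without the failing subject: a weighted contrast between the
    failing subject and those still at risk.  Algebraically identical to the
    risk-set-mean form; a singleton risk set gives 0 by convention.  Returned
    as a frame with ``score_u1``/``score_u2`` columns for cross-checking.
    """
    pieces = []
    for label, grp in cohort.groupby("stratum", sort=True):
        if label not in estimates:
            continue
        est = estimates[label]
        x = grp["followup_age"].to_numpy(dtype=float)
        delta = grp["event"].to_numpy().astype(bool)
        z = grp["marker"].to_numpy(dtype=float)
        entry = grp["entry_age"].to_numpy(dtype=float) if delayed_entry else None

        times = est.event_times
        w1, w2 = weights_at_event_times(est)
        order = np.argsort(x, kind="mergesort")
        x_sorted = x[order]
        z_suffix = np.concatenate([np.cumsum(z[order][::-1])[::-1], [0.0]])
        pos = np.searchsorted(x_sorted, times, side="left")
        r = (x.size - pos).astype(float)
        z_risk_sum = z_suffix[pos]
        if entry is not None:
            e_order = np.argsort(entry, kind="mergesort")
            ze_suffix = np.concatenate([np.cumsum(z[e_order][::-1])[::-1], [0.0]])
            epos = np.searchsorted(entry[e_order], times, side="left")
            r = r - (entry.size - epos)
            z_risk_sum = z_risk_sum - ze_suffix[epos]

        u1 = np.zeros(x.size)
        u2 = np.zeros(x.size)
        if delta.any():
            li = np.searchsorted(times, x[delta])
            r_i = r[li]
            loo = r_i - 1.0  # size of R* for each failing subject
            with np.errstate(divide="ignore", invalid="ignore"):
                zbar_loo = (z_risk_sum[li] - z[delta]) / loo
                contrast = np.where(loo > 0, (loo / r_i) * (z[delta] - zbar_loo), 0.0)
            u1[delta] = w1[li] * contrast
            u2[delta] = w2[li] * contrast
        pieces.append(
            pd.DataFrame(
                {"stratum": label, "score_u1": u1, "score_u2": u2}, index=grp.index
            )
        )
    if not pieces:
        raise EstimationError("no stratum with null estimates")
    return pd.concat(pieces).sort_index()


def event_restricted(table: pd.DataFrame, min_events: int = 3) -> pd.DataFrame:
    """Shifted-score rows at event times only (``W*``), tagged by stratum.

    Raises :class:`DegenerateCohortError` when fewer than ``min_events`` rows
    remain — the 2x2 generalized variance needs at least three points.
    """
    wstar = table.loc[table["event"] == 1, ["stratum", "shifted_w1", "shifted_w2"]]
    if len(wstar) < min_events:
        raise DegenerateCohortError(
            f"only {len(wstar)} event-time shifted scores; need >= {min_events}"
        )
    return wstar
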