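"""The pseudo-R2 criterion Delta built from event-time shifted scores.

Let ``W* = (W1*, W2*)`` be the two-dimensional shifted-score vector collected
at the K event times, grouped by stratum.  The criterion compares two
generalized variances (determinants of 2x2 cross-product matrices, the common
1/(K-1) factor omitted since it cancels):

* under the null (E[W*] = 0), uncentered sums pooled over strata;
* under the alternative, each stratum's sums centered by its own mean.

``Delta = (det_null - det_alt) / det_null`` is the proportion of the
generalized variance of the separability measures explained by the marker; it
lies in [0, 1] (finite-sample Monte-Carlo noise outside the range is clipped
and flagged) and grows with either the propensity or the dynamic effect.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import DegenerateCohortError
from .nullfit import fit_null
from .scores import event_restricted, score_table


@dataclass
class PseudoR2Result:
    delta: float
    det_null: float
    det_alt: float
    k_total: int = 0
    per_stratum_k: dict = field(default_factory=dict)
    clipped: bool = False

    def to_dict(self) -> dict:
        return {
            "delta": self.delta,
            "det_null": self.det_null,
            "det_alt": self.det_alt,
            "k_total": self.k_total,
            "per_stratum_k": {str(k): v for k, v in self.per_stratum_k.items()},
            "clipped": self.clipped,
        }


# determinants this small relative to the diagonal product are rounding noise
# from (near-)collinear score components, not a measurable generalized variance
_REL_DET_FLOOR = 1e-12


def gen_variance_null(wstar: pd.DataFrame) -> float:
    """det(Sigma): uncentered pooled cross-products of (W1*, W2*)."""
    w1 = wstar["shifted_w1"].to_numpy(dtype=float)
    w2 = wstar["shifted_w2"].to_numpy(dtype=float)
    s11, s22 = np.dot(w1, w1), np.dot(w2, w2)
    det = float(s11 * s22 - np.dot(w1, w2) ** 2)
    if det <= _REL_DET_FLOOR * s11 * s22:
        raise DegenerateCohortError(
            f"det(Sigma) = {det:g}: pseudo-R2 undefined (collinear or null scores)"
        )
    return det


def gen_variance_alt(wstar: pd.DataFrame) -> float:
    """det(Sigma*): cross-products centered within each stratum, then pooled.

    A stratum with a single event has no within variance and contributes 0.
    """
    s11 = s22 = s12 = 0.0
    for _, grp in wstar.groupby("stratum", sort=True):
        w1 = grp["shifted_w1"].to_numpy(dtype=float)
        w2 = grp["shifted_w2"].to_numpy(dtype=float)
        k = w1.size
        s11 += np.dot(w1, w1) - w1.sum() ** 2 / k
        s22 += np.dot(w2, w2) - w2.sum() ** 2 / k
        s12 += np.dot(w1, w2) - w1.sum() * w2.sum() / k
    return float(s11 * s22 - s12**2)


def delta(det_null: float, det_alt: float, **extra) -> PseudoR2Result:
    """Delta = clip((det_null - det_alt) / det_null, 0, 1)."""
    if det_null <= 0.0:
        raise DegenerateCohortError(f"det(Sigma) = {det_null:g} <= 0")
    raw = (det_null - det_alt) / det_null
    clipped = not 0.0 <= raw <= 1.0
    return PseudoR2Result(
        delta=float(min(max(raw, 0.0), 1.0)),
        det_null=det_null,
        det_alt=det_alt,
        clipped=clipped,
        **extra,
    )


def delta_from_cohort(
    cohort: pd.DataFrame,
    delayed_entry: bool = False,
    theta_convention: str = "plateau",
) -> PseudoR2Result:
    """One-call pipeline: null estimates -> scores -> shifted scores -> Delta.

    ``cohort`` must carry the canonical columns (entry_age, followup_age,
    event, marker, stratum).  Deterministic given the records.
    """
    estimates = fit_null(
        cohort, delayed_entry=delayed_entry, theta_convention=theta_convention
    )
    table = score_table(
        cohort, estimates, delayed_entry=delayed_entry, check_cancellation=False
    )
    wstar = event_restricted(table)
    det_null = gen_variance_null(wstar)
    det_alt = gen_variance_alt(wstar)
    per_k = wstar.groupby("stratum").size().to_dict()
    return delta(
        det_null, det_alt, k_total=int(len(wstar)), per_stratum_k=per_k
    )
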