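"""Partial-likelihood comparator pseudo-R2 indices (N, XO, OXS).

All three are monotone transforms of the likelihood-ratio statistic
``G = 2(l(beta_hat) - l(0))`` of a single-covariate, stratified Cox
proportional-hazards fit (Breslow ties):

* ``N``   — Nagelkerke-type, per subject: ``1 - exp(-G/n)`` (no max-rescaling);
* ``XO``  — Xu–O'Quigley explained randomness; its likelihood-ratio transform
  coincides numerically with ``1 - exp(-G/n)``, hence with ``N`` — the variant
  is a swappable strategy (see :data:`XO_STRATEGIES`);
* ``OXS`` — O'Quigley–Xu–Stare variant normalised per event: ``1 - exp(-G/k)``.

The fit is an own Newton–Raphson on the stratified partial likelihood; it is a
comparator baseline, deliberately plain (no step-halving refinements beyond a
monotone-likelihood guard).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .exceptions import EstimationError

#: swappable definitions of the XO index as a function of (G, n, k)
XO_STRATEGIES = {
    "per-subject": lambda G, n, k: 1.0 - math.exp(-G / n),
    "per-event": lambda G, n, k: 1.0 - math.exp(-G / k),
}

# |beta| beyond this is treated as a monotone likelihood (separation): the
# score keeps one sign and Newton walks off; genuine fits sit far below it
_MAX_ABS_BETA = 15.0


@dataclass
class ComparatorResult:
    beta_hat: float
    loglik_null: float
    loglik_fit: float
    n: int
    k: int
    converged: bool
    index_n: float = float("nan")
    index_xo: float = float("nan")
    index_oxs: float = float("nan")

    @property
    def G(self) -> float:
        """Likelihood-ratio statistic 2(l(beta_hat) - l(0)) >= 0."""
        return max(2.0 * (self.loglik_fit - self.loglik_null), 0.0)

    def to_dict(self) -> dict:
        return {
            "beta_hat": self.beta_hat,
            "G": self.G,
            "n": self.n,
            "k": self.k,
            "converged": self.converged,
            "N": self.index_n,
            "XO": self.index_xo,
            "OXS": self.index_oxs,
        }


def _stratum_arrays(grp: pd.DataFrame) -> tuple[np.ndarray, ...] | None:
    x = grp["followup_age"].to_numpy(dtype=float)
    delta = grp["event"].to_numpy().astype(bool)
    z = grp["marker"].to_numpy(dtype=float)
    if not delta.any():
        return None
    times, d = np.unique(x[delta], return_counts=True)
    order = np.argsort(x, kind="mergesort")
    # suffix index of subjects at risk at each event time
    pos = np.searchsorted(x[order], times, side="left")
    # sum of z among events at each distinct time
    sz = np.zeros(times.size)
    li = np.searchsorted(times, x[delta])
    np.add.at(sz, li, z[delta])
    return x[order], z[order], times, d.astype(float), pos, sz


def _loglik_score_info(parts: list, beta: float) -> tuple[float, float, float]:
    ll = sc = info = 0.0
    for x_s, z_s, times, d, pos, sz in parts:
        ez = np.exp(beta * z_s)
        s0_suffix = np.concatenate([np.cumsum(ez[::-1])[::-1], [0.0]])
        s1_suffix = np.concatenate([np.cumsum((ez * z_s)[::-1])[::-1], [0.0]])
        s2_suffix = np.concatenate([np.cumsum((ez * z_s * z_s)[::-1])[::-1], [0.0]])
        s0 = s0_suffix[pos]
        e1 = s1_suffix[pos] / s0
        e2 = s2_suffix[pos] / s0
        ll += float(beta * sz.sum() - np.dot(d, np.log(s0)))
        sc += float(sz.sum() - np.dot(d, e1))
        info += float(np.dot(d, e2 - e1**2))
    return ll, sc, info


def fit_ph(
    cohort: pd.DataFrame, tol: float = 1e-8, max_iter: int = 50
) -> ComparatorResult:
    """Newton–Raphson fit of the single-covariate stratified PH model.

    A flat likelihood (constant marker among every risk set) returns
    ``beta_hat = 0`` with ``G = 0``; a monotone likelihood (separation) is
    flagged via ``converged=False`` and the indices are left undefined.
    """
    parts = []
    for _, grp in cohort.groupby("stratum", sort=True):
        arrays = _stratum_arrays(grp)
        if arrays is not None:
            parts.append(arrays)
    if not parts:
        raise EstimationError("no stratum contains an event; PH fit undefined")
    n = int(len(cohort))
    k = int(cohort["event"].astype(bool).sum())

    ll0, sc, info = _loglik_score_info(parts, 0.0)
    if info <= 0.0:  # marker constant within every risk set
        return ComparatorResult(0.0, ll0, ll0, n, k, converged=True)
    beta = 0.0
    ll = ll0
    converged = False
    for _ in range(max_iter):
        step = sc / info
        beta_new = beta + step
        if abs(beta_new) > _MAX_ABS_BETA:
            break  # monotone likelihood / separation
        ll_new, sc, info = _loglik_score_info(parts, beta_new)
        if info <= 0.0:
            break
        beta = beta_new
        ll = ll_new
        if abs(sc) < tol:
            converged = abs(beta) <= _MAX_ABS_BETA
            break
    return ComparatorResult(beta, ll0, ll, n, k, converged=converged)


def indices(fit: ComparatorResult, xo_strategy: str = "per-subject") -> ComparatorResult:
    """Fill in the N, XO, OXS indices from a converged fit (clipped to [0, 1])."""
    if not fit.converged:
        return fit
    if fit.k == 0:
        raise EstimationError("no events: comparator indices undefined")
    G = fit.G
    clip = lambda v: float(min(max(v, 0.0), 1.0))  # noqa: E731
    fit.index_n = clip(1.0 - math.exp(-G / fit.n))
    fit.index_xo = clip(XO_STRATEGIES[xo_strategy](G, fit.n, fit.k))
    fit.index_oxs = clip(1.0 - math.exp(-G / fit.k))
    return fit


def indices_from_cohort(
    cohort: pd.DataFrame, xo_strategy: str = "per-subject"
) -> ComparatorResult:
    """Fit the stratified PH model and compute all three comparator indices."""
    return indices(fit_ph(cohort), xo_strategy=xo_strategy)
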