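"""Monte-Carlo simulation-study driver.

Runs the Delta pipeline (and, on request, the comparator indices) over a grid
of hazard-ratio values, tail defects, sample sizes and design variants, with a
configurable replication count, and reports replication means and standard
deviations per cell.  Replications on which the pseudo-R2 is undefined (fewer
than three events, no survival plateau, non-positive generalized variance) are
dropped and counted; cells with more than 5% such failures are flagged.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .comparators import indices_from_cohort
from .delta import delta_from_cohort
from .exceptions import ConfigurationError, DegenerateCohortError
from .simulate import SimulationConfig, simulate_cohort

#: design variants of the simulation scheme
DESIGNS = {
    "normal": {},
    "censored": {"censor_fraction": 0.20},
    "student": {"covariate_law": "student-t"},
    "gompertz": {"survival_family": "gompertz-improper"},
    "strata": {"n_strata": 2},
}

_CELL_SEED_STRIDE = 1_000_003
_SEED_MODULUS = 2**31


@dataclass(frozen=True)
class StudyGrid:
    """Cartesian grid of simulation cells.

    ``hr_propensity``/``hr_dynamic`` are hazard-ratio values e^alpha, e^beta.
    """

    hr_propensity: tuple = (1.0, 1.25, 1.5)
    hr_dynamic: tuple = (1.0, 2.0, 2.5)
    tail_defects: tuple = (0.3, 0.5, 0.7)
    n_subjects: tuple = (500,)
    designs: tuple = ("normal",)
    reps: int = 300
    seed: int = 0

    def __post_init__(self) -> None:
        if self.reps < 1:
            raise ConfigurationError(f"reps must be >= 1, got {self.reps}")
        if any(h <= 0 for h in tuple(self.hr_propensity) + tuple(self.hr_dynamic)):
            raise ConfigurationError("hazard ratios must be positive")
        unknown = [d for d in self.designs if d not in DESIGNS]
        if unknown:
            raise ConfigurationError(f"unknown designs {unknown}; choose from {list(DESIGNS)}")

    def cells(self):
        index = 0
        for design in self.designs:
            for tail in self.tail_defects:
                for n in self.n_subjects:
                    for hr_a in self.hr_propensity:
                        for hr_b in self.hr_dynamic:
                            yield index, design, tail, n, hr_a, hr_b
                            index += 1


@dataclass
class CellResult:
    design: str
    tail_defect: float
    n_subjects: int
    hr_propensity: float
    hr_dynamic: float
    reps_done: int
    n_failed: int
    values: dict = field(default_factory=dict)  # index name -> np.ndarray


def run_cell(
    config: SimulationConfig,
    reps: int,
    with_comparators: bool = False,
) -> tuple[dict, int]:
    """Replicate one simulation cell; per-replication seed = config.seed + rep.

    Returns (dict of index name -> array of per-replication values, n_failed).
    """
    deltas, ns, xos, oxss = [], [], [], []
    n_failed = 0
    for rep in range(reps):
        cohort = simulate_cohort(
            replace(config, seed=(config.seed + rep) % _SEED_MODULUS)
        )
        try:
            result = delta_from_cohort(cohort)
        except DegenerateCohortError:
            n_failed += 1
            continue
        deltas.append(result.delta)
        if with_comparators:
            comp = indices_from_cohort(cohort)
            if not comp.converged:
                n_failed += 1
                deltas.pop()
                continue
            ns.append(comp.index_n)
            xos.append(comp.index_xo)
            oxss.append(comp.index_oxs)
    values = {"delta": np.asarray(deltas)}
    if with_comparators:
        values.update(
            {"N": np.asarray(ns), "XO": np.asarray(xos), "OXS": np.asarray(oxss)}
        )
    return values, n_failed


def run_study(grid: StudyGrid, with_comparators: bool = False) -> pd.DataFrame:
    """Run every cell of the grid; one row per cell and index.

    Columns: design, tail_defect, n, hr_propensity, hr_dynamic, index, mean,
    sd, reps_used, n_failed, flagged.  Deterministic given ``grid.seed``
    (per-cell seeds are derived by a fixed stride).
    """
    rows = []
    for index, design, tail, n, hr_a, hr_b in grid.cells():
        config = SimulationConfig(
            alpha=float(np.log(hr_a)),
            beta=float(np.log(hr_b)),
            tail_defect=tail,
            n_subjects=n,
            seed=(grid.seed + _CELL_SEED_STRIDE * (index + 1)) % _SEED_MODULUS,
            **DESIGNS[design],
        )
        values, n_failed = run_cell(config, grid.reps, with_comparators)
        flagged = n_failed > 0.05 * grid.reps
        for name, arr in values.items():
            rows.append(
                {
                    "design": design,
                    "tail_defect": tail,
                    "n": n,
                    "hr_propensity": hr_a,
                    "hr_dynamic": hr_b,
                    "index": name,
                    "mean": float(arr.mean()) if arr.size else np.nan,
                    "sd": float(arr.std(ddof=1)) if arr.size > 1 else np.nan,
                    "reps_used": int(arr.size),
                    "n_failed": n_failed,
                    "flagged": flagged,
                }
            )
    return pd.DataFrame(rows)


def render_table(results: pd.DataFrame, decimals: int = 2) -> str:
    """Aligned-text panels: one per (design, tail defect, n), rows = index
    mean/SD, columns = (e^alpha, e^beta) pairs."""
    if results.empty:
        return "design tail_defect n (no cells)\n"
    lines = []
    for (design, tail, n), panel in results.groupby(
        ["design", "tail_defect", "n"], sort=True
    ):
        lines.append(f"design={design}  tail defect={tail:g}  n={n}")
        cols = sorted(
            {(a, b) for a, b in zip(panel["hr_propensity"], panel["hr_dynamic"])}
        )
        header = ["index", "stat"] + [f"a={a:g},b={b:g}" for a, b in cols]
        body = []
        for idx_name, sub in panel.groupby("index", sort=True):
            by_cell = {
                (row.hr_propensity, row.hr_dynamic): row for row in sub.itertuples()
            }
            for stat in ("mean", "sd"):
                cells = []
                for c in cols:
                    row = by_cell.get(c)
                    v = getattr(row, stat) if row is not None else np.nan
                    cells.append("" if np.isnan(v) else f"{v:.{decimals}f}")
                body.append([idx_name if stat == "mean" else "", stat.upper()] + cells)
        widths = [
            max(len(r[i]) for r in [header] + body) for i in range(len(header))
        ]
        for r in [header] + body:
            lines.append("  ".join(s.ljust(w) for s, w in zip(r, widths)).rstrip())
        lines.append("")
    return "\n".join(lines) + "\n"
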