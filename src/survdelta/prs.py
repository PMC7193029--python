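"""Polygenic risk scores as weighted allele-dosage sums.

``PRS_i = sum_k dosage_ik * log_or_k`` over the variants of a published weight
table (variant id, effect allele, per-allele log odds-ratio).  Dosages are
expected effect-allele counts in [0, 2] (hard calls or imputed expectations),
pre-oriented to the effect allele — no strand or allele flipping is attempted
here, and genotype QC/imputation are upstream concerns.

Missingness (a weight variant absent from the dosage matrix, or NaN entries)
is handled by an explicit policy: ``"error"`` (default), ``"mean-impute"``
(per-variant mean of the observed dosages), or ``"skip"`` (drop the missing
contribution, no renormalization of the remaining weights).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .exceptions import ConfigurationError

MISSING_POLICIES = ("error", "mean-impute", "skip")

WEIGHT_COLUMNS = ("variant_id", "effect_allele", "log_or")


def read_weight_table(path) -> pd.DataFrame:
    """Read a 3-column TSV weight table (variant_id, effect_allele, log_or)."""
    table = pd.read_csv(path, sep="\t")
    missing = [c for c in WEIGHT_COLUMNS if c not in table.columns]
    if missing:
        raise ConfigurationError(f"weight table {path} lacks columns {missing}")
    return validate_weights(table)


def validate_weights(table: pd.DataFrame) -> pd.DataFrame:
    if table["variant_id"].duplicated().any():
        dup = table.loc[table["variant_id"].duplicated(), "variant_id"].iloc[0]
        raise ConfigurationError(f"duplicate variant_id in weight table: {dup!r}")
    if not np.isfinite(table["log_or"].to_numpy(dtype=float)).all():
        raise ConfigurationError("non-finite log_or in weight table")
    return table


def read_dosage_matrix(path) -> pd.DataFrame:
    """Read a subjects x variants dosage CSV (first column = subject id)."""
    matrix = pd.read_csv(path, index_col=0)
    return validate_dosages(matrix)


def validate_dosages(matrix: pd.DataFrame) -> pd.DataFrame:
    values = matrix.to_numpy(dtype=float)
    observed = values[~np.isnan(values)]
    if observed.size and (observed.min() < 0.0 or observed.max() > 2.0):
        raise ConfigurationError("dosages must lie in [0, 2]")
    return matrix

def compute_prs(
    dosages: pd.DataFrame,
    weights: pd.DataFrame,
    missing_policy: str = "error",
) -> pd.Series:
    """Per-subject weighted dosage sum; returns a Series named ``"prs"``.

    ``dosages``: subjects x variants frame (NaN = missing call).
    ``weights``: frame with :data:`WEIGHT_COLUMNS`.
    """
    if missing_policy not in MISSING_POLICIES:
        raise ConfigurationError(
            f"unknown missing_policy {missing_policy!r}; choose from {MISSING_POLICIES}"
        )
    weights = validate_weights(weights)
    validate_dosages(dosages)
    absent = [v for v in weights["variant_id"] if v not in dosages.columns]
    if absent and missing_policy != "skip":
        raise ConfigurationError(
            f"variants missing from dosage matrix: {absent} (policy={missing_policy!r})"
        )
    used = weights.loc[~weights["variant_id"].isin(absent)]
    mat = dosages.loc[:, used["variant_id"].tolist()].to_numpy(dtype=float)
    if np.isnan(mat).any():
        if missing_policy == "error":
            raise ConfigurationError(
                "missing dosage entries present (policy='error'); choose "
                "'mean-impute' or 'skip'"
            )
        if missing_policy == "mean-impute":
            col_mean = np.nanmean(mat, axis=0)
            if np.isnan(col_mean).any():
                raise ConfigurationError(
                    "cannot mean-impute a variant with no observed dosages"
                )
            mat = np.where(np.isnan(mat), col_mean, mat)
        else:  # skip: missing contributions dropped, weights not renormalized
            mat = np.nan_to_num(mat, nan=0.0)
    scores = mat @ used["log_or"].to_numpy(dtype=float)
    return pd.Series(scores, index=dosages.index, name="prs")
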