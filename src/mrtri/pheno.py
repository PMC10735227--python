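"""Phenotype preparation: rank-based inverse normal transformation and
regression design assembly.

Metabolite concentrations are standardized and normalized with the
rank-based inverse normal transformation (rank-INT): the value of rank
``r`` among ``n`` non-missing observations maps to the standard-normal
quantile at ``(r − c) / (n − 2c + 1)``. The Blom offset ``c = 3/8`` is the
default; ties receive average ranks so the transform is deterministic.
Designs are complete-case per time point, with sex coded 0/1 and age
centred at its sample mean.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import ndtri
from scipy.stats import rankdata

from .datatypes import CohortTable, ValidationError

logger = logging.getLogger("mrtri")

__all__ = ["rank_inverse_normal", "build_design", "Design"]

BLOM_OFFSET = 3.0 / 8.0


def rank_inverse_normal(values, offset: float = BLOM_OFFSET) -> np.ndarray:
    """Map values to normal quantiles by rank; missing entries preserved.

    Monotone in the input, hence invariant to any strictly increasing
    transformation of it. Requires ≥3 non-missing, non-constant values.
    """
    x = np.asarray(values, dtype=float)
    obs = ~np.isnan(x)
    n = int(obs.sum())
    if n < 3:
        raise ValidationError("rank-INT needs at least 3 non-missing values")
    xo = x[obs]
    if np.all(xo == xo[0]):
        raise ValidationError("rank-INT undefined for a constant vector")
    ranks = rankdata(xo, method="average")
    quantiles = (ranks - offset) / (n - 2.0 * offset + 1.0)
    out = np.full_like(x, np.nan)
    out[obs] = ndtri(quantiles)
    return out


@dataclass
class Design:
    """Complete-case regression design for one metabolite × time point."""

    outcome: np.ndarray
    exposure: np.ndarray
    covariates: pd.DataFrame
    n: int
    n_dropped: int
    timepoint: str
    metabolite: str


def build_design(
    cohort: CohortTable,
    scores: np.ndarray,
    metabolite: str,
    timepoint: str,
    min_n: int = 10,
    outcome_values: np.ndarray | None = None,
) -> Design:
    """Assemble outcome, score and sex/age covariates for one regression.

    Rows with missing outcome, score or covariates are dropped
    (complete-case); a single-sex cohort drops the sex column with a
    warning to keep the design full rank. ``outcome_values`` substitutes
    an already-transformed outcome vector for the stored column.
    """
    if timepoint not in cohort.timepoints:
        raise ValidationError(f"unknown time point {timepoint!r}; have {cohort.timepoints}")
    t = cohort.table
    if outcome_values is not None:
        y = np.asarray(outcome_values, dtype=float)
        if y.shape[0] != len(t):
            raise ValidationError("outcome_values length does not match cohort size")
    else:
        y = t[cohort.metabolite_column(metabolite, timepoint)].to_numpy(float)
    age = t[f"age_{timepoint}"].to_numpy(float)
    sex = t["sex"].to_numpy(float)
    s = np.asarray(scores, dtype=float)
    if s.shape[0] != len(t):
        raise ValidationError("score vector length does not match cohort size")

    keep = ~(np.isnan(y) | np.isnan(s) | np.isnan(age) | np.isnan(sex))
    n = int(keep.sum())
    n_dropped = int(len(t) - n)
    if n < min_n:
        raise ValidationError(
            f"only {n} complete rows for {metabolite!r} at {timepoint!r}; unfit for regression"
        )
    if n_dropped:
        logger.info("%s @ %s: dropped %d incomplete rows (%d remain)", metabolite, timepoint, n_dropped, n)

    cov = pd.DataFrame({"sex": sex[keep], "age": age[keep] - age[keep].mean()})
    if cov["sex"].nunique() < 2:
        logger.warning("single-sex cohort at %s; dropping sex covariate", timepoint)
        cov = cov.drop(columns=["sex"])
    return Design(
        outcome=y[keep],
        exposure=s[keep],
        covariates=cov,
        n=n,
        n_dropped=n_dropped,
        timepoint=timepoint,
        metabolite=metabolite,
    )
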