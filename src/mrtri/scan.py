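"""Metabolome-wide scan of a genetic liability score.

Each metabolite at each time point is regressed on the raw (log-odds
scale) genetic risk score with sex and age as covariates, using OLS with
heteroskedasticity-consistent (HC1 "sandwich") standard errors and a
normal reference for Wald p-values. Estimates are rescaled by ln 2 ≈ 0.693
so coefficients read as the SD difference in metabolite per doubling of
genetic liability, and Benjamini–Hochberg FDR adjustment is applied across
metabolites within each time point × sensitivity family.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.special import ndtr
from statsmodels.stats.multitest import multipletests

from .datatypes import CohortTable, DosageMatrix, GRSWeights, ValidationError
from .grs import exclude_region, score_grs
from .pheno import Design, build_design, rank_inverse_normal

logger = logging.getLogger("mrtri")

__all__ = [
    "LN2",
    "robust_linreg",
    "scale_per_doubling",
    "bh_adjust",
    "LiabilityScan",
    "LiabilityScanResults",
    "run_scan",
    "SCAN_COLUMNS",
]

LN2 = math.log(2.0)

SCAN_COLUMNS = [
    "metabolite",
    "timepoint",
    "n",
    "beta_per_doubling",
    "se",
    "ci_low",
    "ci_high",
    "p",
    "p_fdr",
    "n_snps",
    "sensitivity",
]


def _collinear_columns(X: pd.DataFrame) -> list[str]:
    """Columns whose removal restores full rank (reported on error)."""
    bad = []
    full_rank = np.linalg.matrix_rank(X.to_numpy())
    for col in X.columns:
        if np.linalg.matrix_rank(X.drop(columns=[col]).to_numpy()) == full_rank:
            bad.append(col)
    return bad


def robust_linreg(
    outcome,
    exposure,
    covariates: pd.DataFrame | None = None,
    hc: str = "HC1",
) -> tuple[float, float, float]:
    """OLS of outcome on exposure (+ covariates) with sandwich SEs.

    Returns ``(beta, robust_se, p)`` for the exposure term; the p-value
    uses the normal approximation. The default HC1 flavour rescales the
    heteroskedasticity-consistent covariance by n/(n−k).
    """
    y = np.asarray(outcome, dtype=float)
    X = pd.DataFrame({"const": np.ones_like(y), "exposure": np.asarray(exposure, dtype=float)})
    if covariates is not None and len(covariates.columns):
        X = pd.concat([X, covariates.reset_index(drop=True)], axis=1)
    if y.shape[0] <= X.shape[1] + 2:
        raise ValidationError("too few observations for the requested design")
    rank = np.linalg.matrix_rank(X.to_numpy())
    if rank < X.shape[1]:
        raise ValidationError(f"rank-deficient design; collinear columns: {_collinear_columns(X)}")
    fit = sm.OLS(y, X).fit(cov_type=hc)
    beta = float(fit.params["exposure"])
    se = float(fit.bse["exposure"])
    if se == 0.0:
        return beta, 0.0, 0.0 if beta != 0 else 1.0
    p = float(2.0 * ndtr(-abs(beta / se)))
    return beta, se, max(p, np.finfo(float).tiny)


def scale_per_doubling(
    beta: float,
    se: float,
    ci_low: float | None = None,
    ci_high: float | None = None,
) -> tuple[float, ...]:
    """Rescale an estimate on the per-unit-log-odds scale by ln 2.

    The result reads as the effect per doubling of the odds of disease
    (per doubling of genetic liability). CI bounds, when given, are
    rescaled identically; Wald p-values are unchanged by this rescaling.
    """
    out = [beta * LN2, se * LN2]
    if ci_low is not None:
        out.append(ci_low * LN2)
    if ci_high is not None:
        out.append(ci_high * LN2)
    return tuple(out)


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if np.any(np.isnan(p)) or np.any((p <= 0) | (p > 1)):
        raise ValidationError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


@dataclass
class LiabilityScanResults:
    """Scan results: one row per metabolite × time point (× sensitivity)."""

    frame: pd.DataFrame
    alpha: float = 0.05

    @property
    def n_flagged(self) -> int:
        return int((self.frame["p_fdr"] < self.alpha).sum())

    def flagged(self) -> pd.DataFrame:
        return self.frame[self.frame["p_fdr"] < self.alpha]

    def summary(self) -> str:
        f = self.frame
        lines = [
            "Genetic liability → metabolome scan",
            "=" * 51,
            f"metabolites: {f['metabolite'].nunique()}   time points: {f['timepoint'].nunique()}"
            f"   rows: {len(f)}",
            f"FDR-flagged (BH < {self.alpha:g}): {self.n_flagged}",
            "",
            "beta = SD difference in metabolite per doubling of liability",
            "",
        ]
        show = f.sort_values("p_fdr").head(10)
        lines.append(
            show[["metabolite", "timepoint", "n", "beta_per_doubling", "se", "p", "p_fdr"]]
            .to_string(index=False, float_format=lambda v: f"{v:.4g}")
        )
        return "\n".join(lines)


class LiabilityScan:
    """Model: metabolites at repeated time points vs a liability score.

    Parameters
    ----------
    cohort : CohortTable
    scores : array of per-individual GRS values on the raw log-odds scale
        (the sum of weight × dosage), aligned with the cohort rows.
    metabolites, timepoints : subsets to scan (defaults: all).
    transform : apply rank-based inverse normal transformation to each
        metabolite within time point before regression (default True).
    n_snps : number of variants behind the score (bookkeeping column).
    sensitivity : label recorded in the output (e.g. "none",
        "FADS-excluded").
    """

    def __init__(
        self,
        cohort: CohortTable,
        scores,
        metabolites: list[str] | None = None,
        timepoints: list[str] | None = None,
        transform: bool = True,
        hc: str = "HC1",
        n_snps: int | None = None,
        sensitivity: str = "none",
    ) -> None:
        self.cohort = cohort
        self.scores = np.asarray(scores, dtype=float)
        self.metabolites = metabolites or cohort.metabolites
        self.timepoints = timepoints or cohort.timepoints
        self.transform = transform
        self.hc = hc
        self.n_snps = n_snps if n_snps is not None else -1
        self.sensitivity = sensitivity

    def fit(self, alpha: float = 0.05) -> LiabilityScanResults:
        rows = []
        for tp in self.timepoints:
            tp_rows = []
            for met in self.metabolites:
                col = self.cohort.metabolite_column(met, tp)
                values = self.cohort.table[col].to_numpy(float)
                if self.transform:
                    values = rank_inverse_normal(values)
                design = build_design(self.cohort, self.scores, met, tp, outcome_values=values)
                beta, se, p = robust_linreg(design.outcome, design.exposure, design.covariates, hc=self.hc)
                ci_low, ci_high = beta - 1.96 * se, beta + 1.96 * se
                beta_d, se_d, lo_d, hi_d = scale_per_doubling(beta, se, ci_low, ci_high)
                tp_rows.append(
                    {
                        "metabolite": met,
                        "timepoint": tp,
                        "n": design.n,
                        "beta_per_doubling": beta_d,
                        "se": se_d,
                        "ci_low": lo_d,
                        "ci_high": hi_d,
                        "p": p,
                        "n_snps": self.n_snps,
                        "sensitivity": self.sensitivity,
                    }
                )
            sub = pd.DataFrame(tp_rows)
            sub["p_fdr"] = bh_adjust(sub["p"].to_numpy())
            rows.append(sub)
        frame = pd.concat(rows, ignore_index=True)[SCAN_COLUMNS]
        logger.info(
            "scan (%s): %d rows, %d FDR-flagged at %g",
            self.sensitivity,
            len(frame),
            int((frame["p_fdr"] < alpha).sum()),
            alpha,
        )
        return LiabilityScanResults(frame, alpha=alpha)


def run_scan(
    cohort: CohortTable,
    scores=None,
    timepoints: list[str] | None = None,
    metabolites: list[str] | None = None,
    dosages: DosageMatrix | None = None,
    weights: GRSWeights | None = None,
    region_map: dict | None = None,
    exclude_tags: tuple[str, ...] = (),
    transform: bool = True,
    hc: str = "HC1",
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Full scan, optionally with a gene-region-exclusion sensitivity rerun.

    Scores may be supplied directly or computed from ``dosages`` +
    ``weights`` on the raw log-odds scale. When ``exclude_tags`` is
    non-empty (and dosages/weights are available), a second pass rescoring
    without the tagged variants is appended, with its own FDR family.
    """
    n_snps = None
    if scores is None:
        if dosages is None or weights is None:
            raise ValidationError("run_scan needs either scores or dosages + weights")
        scores = score_grs(dosages, weights, per_snp_average=False)
        n_snps = sum(v in set(dosages.variant_ids) for v in weights.entries["variant_id"])
    elif weights is not None:
        n_snps = len(weights)

    frames = [
        LiabilityScan(
            cohort, scores, metabolites, timepoints, transform, hc, n_snps, sensitivity="none"
        )
        .fit(alpha)
        .frame
    ]
    if exclude_tags:
        if dosages is None or weights is None:
            raise ValidationError("sensitivity rerun needs dosages and weights to rescore")
        w2 = exclude_region(weights, exclude_tags, region_map)
        if len(w2) == 0:
            raise ValidationError("region exclusion removed every weight variant")
        s2 = score_grs(dosages, w2, per_snp_average=False)
        n2 = sum(v in set(dosages.variant_ids) for v in w2.entries["variant_id"])
        label = "excl-" + "+".join(sorted(exclude_tags))
        frames.append(
            LiabilityScan(cohort, s2, metabolites, timepoints, transform, hc, n2, sensitivity=label)
            .fit(alpha)
            .frame
        )
    return pd.concat(frames, ignore_index=True)
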