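"""Core data containers shared across the pipeline.

GWAS summary statistics, dosage matrices, cohort phenotype tables, LD
matrices, external GRS weights and harmonized exposure/outcome instrument
sets are all thin, validated wrappers around pandas/numpy objects. Effect
sizes are in log-odds units for disease traits and SD units for metabolite
traits; positions are 1-based and strand is assumed forward.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ValidationError",
    "FormatError",
    "SummaryStats",
    "LDMatrix",
    "DosageMatrix",
    "CohortTable",
    "GRSWeights",
    "HarmonizedSet",
    "MREstimate",
    "SUMMARY_COLUMNS",
    "VALID_ALLELES",
]


class ValidationError(ValueError):
    """An object violated an invariant of its domain type."""


class FormatError(ValueError):
    """A file could not be interpreted in the expected tabular dialect."""


VALID_ALLELES = frozenset("ACGT")

#: canonical column order of a summary-statistics table
SUMMARY_COLUMNS = [
    "variant_id",
    "chrom",
    "pos",
    "effect_allele",
    "other_allele",
    "eaf",
    "beta",
    "se",
    "pvalue",
    "region",
]


def _require(cond: bool, message: str, exc=ValidationError) -> None:
    if not cond:
        raise exc(message)


@dataclass
class SummaryStats:
    """Per-variant association results for one trait.

    ``table`` holds one row per variant with the columns in
    :data:`SUMMARY_COLUMNS`; ``eaf`` and ``region`` may be missing (NaN /
    empty). ``beta`` is the effect of one copy of ``effect_allele``.
    """

    trait: str
    table: pd.DataFrame
    units: str = ""

    def __post_init__(self) -> None:
        t = self.table
        missing = [c for c in SUMMARY_COLUMNS if c not in t.columns and c not in ("chrom", "pos", "eaf", "region")]
        _require(not missing, f"summary table missing columns: {missing}", FormatError)
        t = t.copy()
        for col, default in (("chrom", ""), ("pos", 0), ("eaf", np.nan), ("region", "")):
            if col not in t.columns:
                t[col] = default
        t["effect_allele"] = t["effect_allele"].astype(str).str.upper()
        t["other_allele"] = t["other_allele"].astype(str).str.upper()
        t["region"] = t["region"].fillna("").astype(str)
        _require(len(t) > 0, f"summary statistics for {self.trait!r} are empty")
        dup = t["variant_id"][t["variant_id"].duplicated()].tolist()
        _require(not dup, f"duplicate variant ids in {self.trait!r}: {sorted(set(dup))}")
        bad_alleles = t.index[
            ~t["effect_allele"].isin(VALID_ALLELES)
            | ~t["other_allele"].isin(VALID_ALLELES)
            | (t["effect_allele"] == t["other_allele"])
        ].tolist()
        _require(not bad_alleles, f"invalid allele pairs at rows {bad_alleles}")
        se = t["se"].to_numpy(float)
        _require(bool(np.all(np.isfinite(se) & (se > 0))), "all SEs must be finite and > 0")
        p = t["pvalue"].to_numpy(float)
        _require(bool(np.all((p > 0) & (p <= 1))), "p-values must lie in (0, 1]")
        _require(bool(np.all(np.isfinite(t["beta"].to_numpy(float)))), "betas must be finite")
        self.table = t.reset_index(drop=True)[SUMMARY_COLUMNS]

    def __len__(self) -> int:
        return len(self.table)

    @property
    def variant_ids(self) -> list[str]:
        return self.table["variant_id"].tolist()

    def subset(self, variant_ids: Iterable[str]) -> "SummaryStats":
        keep = set(variant_ids)
        sub = self.table[self.table["variant_id"].isin(keep)]
        return SummaryStats(self.trait, sub, self.units)


@dataclass
class LDMatrix:
    """Pairwise r² between variants: symmetric, unit diagonal, values in [0, 1]."""

    variant_ids: list[str]
    r2: np.ndarray

    def __post_init__(self) -> None:
        self.variant_ids = list(self.variant_ids)
        self.r2 = np.asarray(self.r2, dtype=float)
        n = len(self.variant_ids)
        _require(self.r2.shape == (n, n), "LD matrix shape does not match variant id list")
        _require(bool(np.allclose(self.r2, self.r2.T, atol=1e-12)), "LD matrix must be symmetric")
        _require(bool(np.allclose(np.diag(self.r2), 1.0, atol=1e-12)), "LD matrix diagonal must be 1")
        _require(bool(np.all((self.r2 >= -1e-12) & (self.r2 <= 1 + 1e-12))), "r² values must lie in [0, 1]")
        self._index = {v: i for i, v in enumerate(self.variant_ids)}

    def r2_between(self, a: str, b: str) -> float:
        return float(self.r2[self._index[a], self._index[b]])

    def __contains__(self, variant_id: str) -> bool:
        return variant_id in self._index

    def submatrix(self, variant_ids: Sequence[str]) -> "LDMatrix":
        idx = [self._index[v] for v in variant_ids]
        return LDMatrix(list(variant_ids), self.r2[np.ix_(idx, idx)])


@dataclass
class DosageMatrix:
    """Individual × variant effect-allele dosages in [0, 2], NaN = missing.

    ``effect_alleles[j]`` is the allele counted by column ``j``; scoring
    flips columns whose orientation disagrees with the weights.
    """

    individual_ids: list[str]
    variant_ids: list[str]
    dosages: np.ndarray
    effect_alleles: list[str] | None = None

    def __post_init__(self) -> None:
        self.individual_ids = [str(i) for i in self.individual_ids]
        self.variant_ids = [str(v) for v in self.variant_ids]
        self.dosages = np.asarray(self.dosages, dtype=float)
        n, j = len(self.individual_ids), len(self.variant_ids)
        _require(self.dosages.shape == (n, j), "dosage matrix shape does not match id lists")
        vals = self.dosages
        bad = np.argwhere(~np.isnan(vals) & ((vals < 0) | (vals > 2)))
        if bad.size:
            r, c = bad[0]
            raise ValidationError(
                f"dosage out of [0, 2] at individual {self.individual_ids[r]!r}, "
                f"variant {self.variant_ids[c]!r}: {vals[r, c]}"
            )
        if self.effect_alleles is not None:
            _require(len(self.effect_alleles) == j, "effect_alleles length mismatch")

    @property
    def shape(self) -> tuple[int, int]:
        return self.dosages.shape


@dataclass
class CohortTable:
    """Wide per-individual phenotype table over repeated time points.

    Columns: ``individual_id``, ``sex`` (0/1), ``age_<tp>`` for each time
    point label, and ``<metabolite>_<tp>`` for each metabolite × time point.
    """

    table: pd.DataFrame
    timepoints: list[str]
    metabolites: list[str]

    def __post_init__(self) -> None:
        t = self.table
        _require("individual_id" in t.columns and "sex" in t.columns, "cohort table needs individual_id and sex", FormatError)
        _require(not t["individual_id"].duplicated().any(), "one row per individual required")
        for tp in self.timepoints:
            _require(f"age_{tp}" in t.columns, f"missing age column for time point {tp!r}", FormatError)
            ages = t[f"age_{tp}"].to_numpy(float)
            _require(bool(np.all(np.isnan(ages) | (ages >= 0))), "ages must be non-negative")
        self.table = t.reset_index(drop=True)

    def metabolite_column(self, metabolite: str, timepoint: str) -> str:
        col = f"{metabolite}_{timepoint}"
        _require(col in self.table.columns, f"no column for {metabolite!r} at {timepoint!r}", KeyError)
        return col


@dataclass
class GRSWeights:
    """Externally weighted instrument set defining genetic liability.

    ``entries`` columns: variant_id, effect_allele, weight (log-odds per
    effect allele); ``trait`` names the source GWAS (e.g. overall vs
    site-specific disease).
    """

    entries: pd.DataFrame
    trait: str = "disease"

    def __post_init__(self) -> None:
        e = self.entries
        for col in ("variant_id", "effect_allele", "weight"):
            _require(col in e.columns, f"weights table missing column {col!r}", FormatError)
        e = e.copy()
        e["effect_allele"] = e["effect_allele"].astype(str).str.upper()
        _require(not e["variant_id"].duplicated().any(), "duplicate variant ids in weights")
        _require(bool(np.all(np.isfinite(e["weight"].to_numpy(float)))), "weights must be finite")
        self.entries = e.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.entries)

    @classmethod
    def from_summary_stats(cls, stats: SummaryStats, variant_ids: Iterable[str] | None = None) -> "GRSWeights":
        t = stats.table
        if variant_ids is not None:
            t = t[t["variant_id"].isin(set(variant_ids))]
        entries = t[["variant_id", "effect_allele", "beta"]].rename(columns={"beta": "weight"})
        return cls(entries, trait=stats.trait)


@dataclass
class HarmonizedSet:
    """Exposure/outcome instrument table after allele alignment.

    One row per retained instrument with exposure and outcome betas
    expressed for the same effect allele. Input to every MR estimator.
    """

    exposure: str
    outcome: str
    table: pd.DataFrame
    drops: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        t = self.table
        needed = ["variant_id", "beta_exp", "se_exp", "beta_out", "se_out"]
        for col in needed:
            _require(col in t.columns, f"harmonized table missing column {col!r}", FormatError)
        _require(len(t) >= 1, "harmonized set must contain at least one instrument")
        for col in ("se_exp", "se_out"):
            _require(bool(np.all(t[col].to_numpy(float) > 0)), "harmonized SEs must be > 0")
        self.table = t.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.table)

    @property
    def beta_exp(self) -> np.ndarray:
        return self.table["beta_exp"].to_numpy(float)

    @property
    def se_exp(self) -> np.ndarray:
        return self.table["se_exp"].to_numpy(float)

    @property
    def beta_out(self) -> np.ndarray:
        return self.table["beta_out"].to_numpy(float)

    @property
    def se_out(self) -> np.ndarray:
        return self.table["se_out"].to_numpy(float)

    @classmethod
    def from_arrays(
        cls,
        beta_exp: Sequence[float],
        se_exp: Sequence[float],
        beta_out: Sequence[float],
        se_out: Sequence[float],
        exposure: str = "exposure",
        outcome: str = "outcome",
        variant_ids: Sequence[str] | None = None,
    ) -> "HarmonizedSet":
        n = len(beta_exp)
        ids = list(variant_ids) if variant_ids is not None else [f"rs{i + 1}" for i in range(n)]
        table = pd.DataFrame(
            {
                "variant_id": ids,
                "beta_exp": np.asarray(beta_exp, float),
                "se_exp": np.asarray(se_exp, float),
                "beta_out": np.asarray(beta_out, float),
                "se_out": np.asarray(se_out, float),
            }
        )
        return cls(exposure, outcome, table)


#: recognised effect-size scales for MR estimates
SCALES = ("per-unit-log-odds", "per-doubling", "per-sd", "log-odds", "OR")


@dataclass
class MREstimate:
    """One method's causal-effect estimate with its uncertainty.

    The 95% CI is ``beta ± 1.96·se`` on the linear scale; on the OR scale
    the bounds are the exponentials of the linear-scale bounds and ``se``
    stays on the log scale. ``q``/``q_df`` (Cochran heterogeneity) are set
    for IVW only.
    """

    method: str
    beta: float
    se: float
    p: float
    n_snps: int
    ci_low: float = np.nan
    ci_high: float = np.nan
    q: float | None = None
    q_df: int | None = None
    scale: str = "per-sd"
    exposure: str = ""
    outcome: str = ""
    note: str = ""

    def __post_init__(self) -> None:
        _require(self.scale in SCALES, f"unknown scale {self.scale!r}")
        if np.isnan(self.ci_low) and np.isfinite(self.se):
            self.ci_low = self.beta - 1.96 * self.se
            self.ci_high = self.beta + 1.96 * self.se
        if self.q is not None:
            _require(self.q >= 0, "Cochran's Q must be non-negative")

    def rescaled(self, factor: float, scale: str) -> "MREstimate":
        """Multiply beta, se and CI bounds by ``factor`` (linear rescaling)."""
        return replace(
            self,
            beta=self.beta * factor,
            se=self.se * factor,
            ci_low=self.ci_low * factor,
            ci_high=self.ci_high * factor,
            scale=scale,
        )

    def to_row(self) -> dict:
        return {
            "exposure": self.exposure,
            "outcome": self.outcome,
            "method": self.method,
            "n_snps": self.n_snps,
            "beta": self.beta,
            "se": self.se,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "p": self.p,
            "q": np.nan if self.q is None else self.q,
            "q_df": np.nan if self.q_df is None else self.q_df,
            "scale": self.scale,
            "note": self.note,
        }
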