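"""Synthetic genotype panels, cohorts and two-sample summary statistics.

These generators produce data with exactly the statistical structure the
analysis assumes, so every downstream stage (clumping, scoring, the
liability scan, harmonization, the MR estimators, triangulation) can be
tested against known truth without access to restricted cohort or
consortium data.

Generative model
----------------
* Genotypes are Hardy–Weinberg draws: two haplotypes per individual, each
  allele Bernoulli(MAF). Within an LD block the haplotype alleles share a
  latent Gaussian factor (a Gaussian copula with equicorrelation
  √r²_target), so the realized dosage correlation approximates the target;
  variants in different blocks, and within blocks whose target r² is zero,
  are independent by construction and their LD entries are exact zeros.
* Disease liability is the weighted allele count S = Σ w_j·g_j in log-odds
  units (continuous; no binary case status is generated). A metabolite
  with per-doubling effect θ is θ·(S/ln 2) plus sex/age effects and
  Gaussian noise, so θ is exactly the estimand the per-doubling scan
  recovers.
* Two-sample instruments have true exposure effects γ_j with
  |γ_j|/se ~ Uniform(strength range), keeping every instrument
  genome-wide significant and strong (F ≈ strength²). Outcome effects are
  θ·γ_j + α_j + noise, with α_j = 0 for valid instruments and drawn
  Normal(0, σ_p) (balanced) or Normal(+σ_p, σ_p/2) (directional) for
  horizontally pleiotropic ones.

All draws flow from one seeded generator per call: identical seed and
parameters give byte-identical outputs.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import ndtr, ndtri

from .datatypes import (
    CohortTable,
    DosageMatrix,
    GRSWeights,
    LDMatrix,
    SummaryStats,
    ValidationError,
)

logger = logging.getLogger("mrtri")

__all__ = [
    "PanelTruth",
    "CohortTruth",
    "TwoSampleTruth",
    "gen_variant_panel",
    "gen_cohort",
    "gen_two_sample",
    "gen_triangulation_scenario",
]

LN2 = math.log(2.0)
_Z_GENOME_WIDE = 5.6  # |z| floor enforcing p < 5e-8 with margin
#: non-palindromic allele pairs a variant may carry
_ALLELE_PAIRS = [
    ("A", "G"), ("A", "C"), ("T", "G"), ("T", "C"),
    ("G", "A"), ("C", "A"), ("G", "T"), ("C", "T"),
]


@dataclass
class PanelTruth:
    """Ground truth behind a generated disease-liability variant panel."""

    variant_ids: list[str]
    mafs: np.ndarray
    weights: np.ndarray
    blocks: list[list[int]]  # partition of variant indices
    block_r2: list[float]  # target within-block r² per block
    effect_alleles: list[str]
    region_tags: dict[str, str] = field(default_factory=dict)
    seed: int | None = None

    def __post_init__(self) -> None:
        self.mafs = np.asarray(self.mafs, float)
        self.weights = np.asarray(self.weights, float)
        if not np.all((self.mafs > 0) & (self.mafs <= 0.5)):
            raise ValidationError("minor-allele frequencies must lie in (0, 0.5]")
        if not np.all(np.isfinite(self.weights)):
            raise ValidationError("liability weights must be finite")
        seen = sorted(i for b in self.blocks for i in b)
        if seen != list(range(len(self.variant_ids))):
            raise ValidationError("blocks must partition the variant set")
        if not all(0 <= r <= 1 for r in self.block_r2):
            raise ValidationError("within-block r² must lie in [0, 1]")

    def params(self) -> dict:
        return {
            "variant_ids": self.variant_ids,
            "mafs": self.mafs,
            "weights": self.weights,
            "blocks": self.blocks,
            "block_r2": self.block_r2,
            "region_tags": self.region_tags,
            "seed": self.seed,
        }


@dataclass
class CohortTruth:
    """Generative parameters of a synthetic repeated-measures cohort.

    ``theta`` is the per-metabolite effect in SD units per doubling of
    liability (0 = null metabolite). ``noise_sd=None`` calibrates the
    residual SD per metabolite so the marginal variance is ≈1
    (standardization); an explicit value (including 0) is used as given.
    """

    theta: np.ndarray
    noise_sd: float | None = None
    sex_effect: float = 0.1
    age_effect: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        self.theta = np.atleast_1d(np.asarray(self.theta, float))

    @classmethod
    def sparse(
        cls,
        n_metabolites: int,
        n_causal: int,
        theta: float,
        **kwargs,
    ) -> "CohortTruth":
        """First ``n_causal`` metabolites causal at ``theta``, rest null."""
        vec = np.zeros(n_metabolites)
        vec[:n_causal] = theta
        return cls(theta=vec, **kwargs)

    @property
    def causal_indices(self) -> np.ndarray:
        return np.flatnonzero(self.theta != 0)


@dataclass
class TwoSampleTruth:
    """Generative parameters of a paired exposure/outcome instrument set."""

    theta: float
    prop_invalid: float = 0.0
    mode: str = "none"  # none | balanced | directional
    pleiotropy_sd: float = 0.3
    seed: int = 0
    # realized draws, populated by gen_two_sample
    alphas: np.ndarray | None = None
    invalid_ids: list[str] | None = None

    def __post_init__(self) -> None:
        if self.mode not in ("none", "balanced", "directional"):
            raise ValidationError(f"unknown pleiotropy mode {self.mode!r}")
        if not 0 <= self.prop_invalid <= 1:
            raise ValidationError("prop_invalid must lie in [0, 1]")
        if self.mode == "none" and self.prop_invalid != 0:
            raise ValidationError("mode='none' requires prop_invalid = 0")


def _copula_dosages(
    rng: np.random.Generator,
    mafs: np.ndarray,
    blocks: list[list[int]],
    block_r2: list[float],
    n: int,
) -> np.ndarray:
    """Draw n×J dosages: 2 haplotypes, block-equicorrelated latent scores."""
    J = len(mafs)
    thresholds = ndtri(mafs)  # allele present iff latent < threshold
    dosages = np.zeros((n, J))
    for hap in range(2):
        latent = rng.standard_normal((n, J))
        for block, r2 in zip(blocks, block_r2):
            if len(block) > 1 and r2 > 0:
                rho = math.sqrt(r2)  # latent equicorrelation targeting dosage r²
                shared = rng.standard_normal(n)
                latent[:, block] = (
                    math.sqrt(rho) * shared[:, None]
                    + math.sqrt(1 - rho) * latent[:, block]
                )
        dosages += (latent < thresholds[None, :]).astype(float)
    return dosages


def _assign_alleles(rng: np.random.Generator, n: int) -> tuple[list[str], list[str]]:
    pick = rng.integers(0, len(_ALLELE_PAIRS), size=n)
    return [_ALLELE_PAIRS[i][0] for i in pick], [_ALLELE_PAIRS[i][1] for i in pick]


def gen_variant_panel(
    n_variants: int,
    maf_range: tuple[float, float] = (0.05, 0.5),
    weight_sd: float = 0.08,
    block_spec: list[tuple[int, float]] | None = None,
    seed: int | None = None,
    n_ref: int = 2000,
    ensure_significant: bool = True,
    strength_range: tuple[float, float] = (6.0, 12.0),
    region_tags: dict[str, str] | None = None,
    trait: str = "disease",
    id_prefix: str = "rs",
) -> tuple[SummaryStats, LDMatrix, PanelTruth]:
    """Generate a disease GWAS panel with block LD structure.

    ``block_spec`` lists (block size, target within-block r²); sizes must
    sum to ``n_variants`` (default: all singletons). The returned LD
    matrix holds the *realized* r² of a reference sample of ``n_ref``
    individuals within correlated blocks, and exact zeros between
    independent variants (cross-block and within target-r²-0 blocks), so
    clumping behaviour on generated panels is deterministic. Observed
    betas are the liability weights plus sampling noise; when
    ``ensure_significant`` every p-value is below genome-wide
    significance.
    """
    if n_variants < 1:
        raise ValidationError("n_variants must be ≥ 1")
    lo, hi = maf_range
    if not (0 < lo <= hi <= 0.5):
        raise ValidationError("maf_range must be within (0, 0.5]")
    if block_spec is None:
        block_spec = [(1, 0.0)] * n_variants
    sizes = [s for s, _ in block_spec]
    if sum(sizes) != n_variants:
        raise ValidationError(
            f"block sizes {sizes} do not sum to n_variants={n_variants}"
        )
    rng = np.random.default_rng(seed)

    variant_ids = [f"{id_prefix}{i + 1}" for i in range(n_variants)]
    mafs = rng.uniform(lo, hi, size=n_variants)
    # half-normal risk-raising log-odds weights with a small floor so no
    # variant is an empty instrument
    weights = np.abs(rng.normal(0.0, weight_sd, size=n_variants)) + 0.25 * weight_sd

    blocks, block_r2 = [], []
    start = 0
    for size, r2 in block_spec:
        if not 0 <= r2 <= 1:
            raise ValidationError(f"block r² {r2} outside [0, 1]")
        blocks.append(list(range(start, start + size)))
        block_r2.append(float(r2))
        start += size

    # observed association statistics
    z_target = rng.uniform(*strength_range, size=n_variants)
    se = weights / z_target
    beta = weights + 0.3 * se * rng.standard_normal(n_variants)
    if ensure_significant:
        beta = np.sign(beta) * np.maximum(np.abs(beta), _Z_GENOME_WIDE * se)
    pvals = np.maximum(2.0 * ndtr(-np.abs(beta) / se), np.finfo(float).tiny)

    effect_alleles, other_alleles = _assign_alleles(rng, n_variants)
    tags = dict(region_tags or {})
    table = pd.DataFrame(
        {
            "variant_id": variant_ids,
            "chrom": [str(b % 22 + 1) for b, blk in enumerate(blocks) for _ in blk],
            "pos": np.arange(1, n_variants + 1) * 50_000,
            "effect_allele": effect_alleles,
            "other_allele": other_alleles,
            "eaf": mafs,
            "beta": beta,
            "se": se,
            "pvalue": pvals,
            "region": [tags.get(v, "") for v in variant_ids],
        }
    )
    stats = SummaryStats(trait, table, units="log-odds")

    # realized LD from a reference draw; structural zeros stay exact
    ref = _copula_dosages(rng, mafs, blocks, block_r2, n_ref)
    r2 = np.eye(n_variants)
    for block, target in zip(blocks, block_r2):
        if len(block) > 1 and target > 0:
            corr = np.corrcoef(ref[:, block], rowvar=False)
            r2[np.ix_(block, block)] = np.clip(corr**2, 0.0, 1.0)
    np.fill_diagonal(r2, 1.0)
    ld = LDMatrix(variant_ids, r2)

    truth = PanelTruth(
        variant_ids=variant_ids,
        mafs=mafs,
        weights=weights,
        blocks=blocks,
        block_r2=block_r2,
        effect_alleles=effect_alleles,
        region_tags=tags,
        seed=seed,
    )
    return stats, ld, truth


def gen_cohort(
    panel: PanelTruth,
    n_individuals: int,
    timepoints: tuple[float, ...] = (8.0, 16.0, 18.0, 25.0),
    truth: CohortTruth | None = None,
    n_metabolites: int | None = None,
) -> tuple[DosageMatrix, CohortTable]:
    """Generate genotypes and repeated metabolite measures for a cohort.

    Metabolite k at each time point is
    ``θ_k·(S/ln 2) + b_sex·(sex−mean) + b_age·(age−mean) + ε`` with S the
    log-odds liability score, so the per-doubling scan's estimand for
    metabolite k is exactly θ_k.
    """
    if n_individuals < 10:
        raise ValidationError("n_individuals must be ≥ 10")
    if not timepoints:
        raise ValidationError("at least one time point required")
    if truth is None:
        if n_metabolites is None:
            raise ValidationError("supply a CohortTruth or n_metabolites")
        truth = CohortTruth(theta=np.zeros(n_metabolites))
    n_met = truth.theta.size
    rng = np.random.default_rng(truth.seed)

    g = _copula_dosages(rng, panel.mafs, panel.blocks, panel.block_r2, n_individuals)
    individual_ids = [f"id{i + 1}" for i in range(n_individuals)]
    dosages = DosageMatrix(individual_ids, panel.variant_ids, g, list(panel.effect_alleles))

    S = g @ panel.weights  # log-odds liability
    D = S / LN2  # doublings of liability
    sex = rng.integers(0, 2, size=n_individuals).astype(float)

    data = {"individual_id": individual_ids, "sex": sex}
    tp_labels = [f"{tp:g}" for tp in timepoints]
    met_names = [f"m{k + 1:03d}" for k in range(n_met)]
    for tp, label in zip(timepoints, tp_labels):
        age = tp + rng.uniform(-0.5, 0.5, size=n_individuals)
        data[f"age_{label}"] = age
        age_c = age - age.mean()
        sex_c = sex - sex.mean()
        for k, met in enumerate(met_names):
            signal = truth.theta[k] * D + truth.sex_effect * sex_c + truth.age_effect * age_c
            if truth.noise_sd is None:
                noise_sd = math.sqrt(max(1.0 - signal.var(), 0.04))
            else:
                noise_sd = truth.noise_sd
            data[f"{met}_{label}"] = signal + noise_sd * rng.standard_normal(n_individuals)

    cohort = CohortTable(pd.DataFrame(data), tp_labels, met_names)
    return dosages, cohort


def gen_two_sample(
    n_instruments: int,
    truth: TwoSampleTruth,
    se_exposure: float = 0.05,
    se_outcome: float = 0.05,
    strength_range: tuple[float, float] = (10.0, 20.0),
    scramble_alleles: bool = False,
    exposure_trait: str = "exposure",
    outcome_trait: str = "outcome",
    id_prefix: str = "rs",
    signed_gamma: bool = False,
) -> tuple[SummaryStats, SummaryStats, TwoSampleTruth]:
    """Generate paired exposure/outcome summary statistics.

    Outcome betas are ``θ·γ_j + α_j + noise`` with α_j drawn per the
    truth's pleiotropy mode for the invalid fraction of instruments.
    Effect alleles are oriented to the exposure-raising allele (γ_j > 0),
    the usual instrument convention; ``signed_gamma=True`` randomizes the
    signs instead. ``scramble_alleles`` randomly swaps effect/other
    alleles in the outcome table (negating betas, complementing
    frequencies) to exercise harmonization; the information content is
    unchanged.
    """
    if n_instruments < 3:
        raise ValidationError("need at least 3 instruments")
    if se_exposure <= 0 or se_outcome <= 0:
        raise ValidationError("SEs must be > 0")
    if truth.mode == "directional" and truth.prop_invalid >= 0.5:
        warnings.warn(
            "≥50% directionally invalid instruments: the weighted-median "
            "consistency assumption is violated by design",
            stacklevel=2,
        )
    rng = np.random.default_rng(truth.seed)
    n = n_instruments

    strength = rng.uniform(*strength_range, size=n)
    sign = rng.choice([-1.0, 1.0], size=n) if signed_gamma else np.ones(n)
    gamma = sign * strength * se_exposure
    beta_exp = gamma + se_exposure * rng.standard_normal(n)

    n_invalid = int(round(truth.prop_invalid * n))
    alphas = np.zeros(n)
    invalid = rng.choice(n, size=n_invalid, replace=False) if n_invalid else np.array([], dtype=int)
    if truth.mode == "balanced" and n_invalid:
        alphas[invalid] = rng.normal(0.0, truth.pleiotropy_sd, size=n_invalid)
    elif truth.mode == "directional" and n_invalid:
        alphas[invalid] = rng.normal(truth.pleiotropy_sd, truth.pleiotropy_sd / 2.0, size=n_invalid)
    beta_out = truth.theta * gamma + alphas + se_outcome * rng.standard_normal(n)

    ids = [f"{id_prefix}{i + 1}" for i in range(n)]
    eaf = rng.uniform(0.1, 0.9, size=n)
    ea, oa = _assign_alleles(rng, n)

    def _stats(trait, beta, se_val, units):
        se_arr = np.full(n, se_val)
        p = np.maximum(2.0 * ndtr(-np.abs(beta) / se_arr), np.finfo(float).tiny)
        return SummaryStats(
            trait,
            pd.DataFrame(
                {
                    "variant_id": ids,
                    "chrom": "1",
                    "pos": np.arange(1, n + 1) * 10_000,
                    "effect_allele": ea,
                    "other_allele": oa,
                    "eaf": eaf,
                    "beta": beta,
                    "se": se_arr,
                    "pvalue": p,
                    "region": "",
                }
            ),
            units=units,
        )

    exposure = _stats(exposure_trait, beta_exp, se_exposure, "sd")
    outcome = _stats(outcome_trait, beta_out, se_outcome, "sd")
    if scramble_alleles:
        t = outcome.table.copy()
        flip = rng.random(n) < 0.5
        t.loc[flip, ["effect_allele", "other_allele"]] = t.loc[
            flip, ["other_allele", "effect_allele"]
        ].to_numpy()
        t.loc[flip, "beta"] = -t.loc[flip, "beta"]
        t.loc[flip, "eaf"] = 1.0 - t.loc[flip, "eaf"]
        outcome = SummaryStats(outcome.trait, t, outcome.units)

    realized = TwoSampleTruth(
        theta=truth.theta,
        prop_invalid=truth.prop_invalid,
        mode=truth.mode,
        pleiotropy_sd=truth.pleiotropy_sd,
        seed=truth.seed,
        alphas=alphas,
        invalid_ids=[ids[i] for i in sorted(invalid)],
    )
    return exposure, outcome, realized


def gen_triangulation_scenario(
    seed: int,
    n_metabolites: int = 20,
    n_causal: int = 5,
    n_individuals: int = 3000,
    panel_size: int = 65,
    n_forward_instruments: int = 30,
    theta_scan: float = 0.15,
    theta_reverse: float = 0.15,
    theta_forward: float = 0.15,
    timepoints: tuple[float, ...] = (18.0,),
    se_metabolite_gwas: float = 0.02,
    se_disease_gwas: float = 0.05,
) -> dict:
    """Full synthetic study: cohort, reverse-MR and forward-MR datasets.

    The first ``n_causal`` metabolites are causal in every stream's sense
    (liability raises them in the cohort and in the reverse-MR outcome
    GWAS, and they raise disease risk in the forward-MR outcome GWAS);
    the rest are null everywhere. Returns a dict of all inputs plus the
    generating truth, keyed by pipeline stage.
    """
    rng = np.random.default_rng(seed)
    sub = lambda: int(rng.integers(0, 2**31 - 1))

    panel_stats, panel_ld, panel = gen_variant_panel(
        panel_size, seed=sub(), trait="disease-liability"
    )
    cohort_truth = CohortTruth.sparse(
        n_metabolites, n_causal, theta_scan, seed=sub()
    )
    dosages, cohort = gen_cohort(panel, n_individuals, timepoints, cohort_truth)
    met_names = cohort.metabolites

    # reverse MR: liability GWAS is the exposure; one outcome GWAS per
    # metabolite over the same panel variants
    reverse_outcomes = []
    theta_rev = np.zeros(n_metabolites)
    theta_rev[:n_causal] = theta_reverse
    for k, met in enumerate(met_names):
        noise = se_metabolite_gwas * rng.standard_normal(panel_size)
        beta_out = theta_rev[k] * panel.weights + noise
        t = panel_stats.table.copy()
        t["beta"] = beta_out
        t["se"] = se_metabolite_gwas
        t["pvalue"] = np.maximum(
            2.0 * ndtr(-np.abs(beta_out) / se_metabolite_gwas), np.finfo(float).tiny
        )
        reverse_outcomes.append(SummaryStats(met, t, units="sd"))

    # forward MR: per-metabolite instrument sets, one pooled disease GWAS
    theta_fwd = np.zeros(n_metabolites)
    theta_fwd[:n_causal] = theta_forward
    forward_exposures, crc_tables = [], []
    for k, met in enumerate(met_names):
        exp, out, _ = gen_two_sample(
            n_forward_instruments,
            TwoSampleTruth(theta=theta_fwd[k], seed=sub()),
            se_exposure=0.05,
            se_outcome=se_disease_gwas,
            exposure_trait=met,
            outcome_trait="disease",
            id_prefix=f"fw{k + 1}_rs",
        )
        forward_exposures.append(exp)
        crc_tables.append(out.table)
    crc_outcome = SummaryStats("disease", pd.concat(crc_tables, ignore_index=True), "log-odds")
    fwd_ids = crc_outcome.variant_ids
    forward_ld = LDMatrix(fwd_ids, np.eye(len(fwd_ids)))

    weights = GRSWeights.from_summary_stats(panel_stats)
    return {
        "seed": seed,
        "panel_stats": panel_stats,
        "panel_ld": panel_ld,
        "panel_truth": panel,
        "weights": weights,
        "dosages": dosages,
        "cohort": cohort,
        "cohort_truth": cohort_truth,
        "reverse_outcomes": reverse_outcomes,
        "forward_exposures": forward_exposures,
        "disease_outcome": crc_outcome,
        "forward_ld": forward_ld,
        "causal_metabolites": met_names[:n_causal],
    }
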