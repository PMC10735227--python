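"""Two-sample Mendelian randomization machinery.

Instruments are genome-wide-significant, LD-independent variants for the
exposure; exposure and outcome association tables are harmonized to a
common effect allele; per-variant Wald ratios are combined with three
estimators making different pleiotropy assumptions:

* multiplicative random-effects IVW — efficient, biased by any net
  (directional) horizontal pleiotropy;
* weighted median — consistent while ≥50% of the instrument weight comes
  from valid variants;
* weighted mode — consistent while the most common pleiotropy value is
  zero (ZEMPA), implemented as the maximum of an inverse-variance-weighted
  Gaussian kernel density over the Wald ratios.

Reverse-direction runs (disease liability → metabolites) are rescaled by
ln 2 to read per doubling of liability; forward runs (metabolite →
disease) are exponentiated to odds ratios per SD of metabolite.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import replace

import numpy as np
import pandas as pd
from scipy.special import ndtr

from .datatypes import (
    HarmonizedSet,
    LDMatrix,
    MREstimate,
    SummaryStats,
    ValidationError,
)
from .grs import ld_clump
from .scan import LN2, bh_adjust

logger = logging.getLogger("mrtri")

__all__ = [
    "select_instruments",
    "harmonize",
    "wald_ratio",
    "ivw_random_effects",
    "weighted_median",
    "weighted_mode",
    "instrument_strength",
    "to_odds_ratio",
    "TwoSampleMR",
    "TwoSampleMRResults",
    "run_mr",
    "UninstrumentableExposure",
]

GENOME_WIDE_P = 5e-8
CLUMP_R2 = 0.001
#: effect-allele-frequency window inside which a palindromic variant is ambiguous
PALINDROME_WINDOW = (0.42, 0.58)
MODE_GRID_POINTS = 512

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}


class UninstrumentableExposure(ValidationError):
    """No variant satisfies the instrument-selection thresholds."""


def _normal_p(z: float) -> float:
    return float(max(2.0 * ndtr(-abs(z)), np.finfo(float).tiny))


def select_instruments(
    exposure: SummaryStats,
    ld: LDMatrix,
    p_threshold: float = GENOME_WIDE_P,
    r2_threshold: float = CLUMP_R2,
) -> list[str]:
    """p-filter then LD-clump; error if nothing survives."""
    sig = exposure.table[exposure.table["pvalue"] < p_threshold]
    if sig.empty:
        raise UninstrumentableExposure(
            f"no variant of {exposure.trait!r} reaches p<{p_threshold:g}"
        )
    retained = ld_clump(SummaryStats(exposure.trait, sig, exposure.units), ld, r2_threshold)
    if not retained:
        raise UninstrumentableExposure(f"clumping removed every instrument of {exposure.trait!r}")
    return retained


def _is_palindromic(ea: str, oa: str) -> bool:
    return _COMPLEMENT[ea] == oa


def harmonize(
    exposure: SummaryStats,
    outcome: SummaryStats,
    palindrome_policy: str = "frequency",
    ambiguity_window: tuple[float, float] = PALINDROME_WINDOW,
) -> HarmonizedSet:
    """Align outcome associations to the exposure's effect alleles.

    Swapped allele labels flip the outcome beta sign and complement its
    EAF; strand flips of unambiguous variants are resolved by allele
    complementing. Palindromic (A/T, C/G) variants are dropped when either
    EAF is missing or the exposure EAF falls in the ambiguity window,
    otherwise aligned so minor/major status agrees across datasets
    (``palindrome_policy="frequency"``) or dropped outright
    (``palindrome_policy="drop"``). Instruments absent from the outcome
    and incompatible allele pairs are dropped; every drop is logged with
    its reason.
    """
    if palindrome_policy not in ("frequency", "drop"):
        raise ValidationError(f"unknown palindrome policy {palindrome_policy!r}")
    lo, hi = ambiguity_window
    out_by_id = outcome.table.set_index("variant_id")
    rows, drops = [], []
    for rec in exposure.table.itertuples(index=False):
        vid = rec.variant_id
        if vid not in out_by_id.index:
            drops.append((vid, "absent from outcome"))
            continue
        o = out_by_id.loc[vid]
        ea, oa = rec.effect_allele, rec.other_allele
        o_ea, o_oa = o["effect_allele"], o["other_allele"]
        beta_out, eaf_out = float(o["beta"]), float(o["eaf"])
        palindromic = _is_palindromic(ea, oa)

        if palindromic:
            if {o_ea, o_oa} != {ea, oa}:
                drops.append((vid, "incompatible alleles"))
                continue
            if palindrome_policy == "drop":
                drops.append((vid, "palindromic"))
                continue
            eaf_exp = float(rec.eaf)
            if o_ea != ea:  # label swap first, then frequency check
                beta_out, eaf_out = -beta_out, 1.0 - eaf_out
            if np.isnan(eaf_exp) or np.isnan(eaf_out) or (lo < eaf_exp < hi):
                drops.append((vid, "palindromic, ambiguous frequency"))
                continue
            if (eaf_exp < 0.5) != (eaf_out < 0.5):
                # same labels but opposite minor allele: strand flip hiding
                # an effective allele swap
                beta_out, eaf_out = -beta_out, 1.0 - eaf_out
        else:
            if (o_ea, o_oa) == (ea, oa):
                pass
            elif (o_ea, o_oa) == (oa, ea):
                beta_out, eaf_out = -beta_out, 1.0 - eaf_out
            elif (_COMPLEMENT[o_ea], _COMPLEMENT[o_oa]) == (ea, oa):
                pass  # strand flip, same orientation
            elif (_COMPLEMENT[o_ea], _COMPLEMENT[o_oa]) == (oa, ea):
                beta_out, eaf_out = -beta_out, 1.0 - eaf_out
            else:
                drops.append((vid, "incompatible alleles"))
                continue

        rows.append(
            {
                "variant_id": vid,
                "effect_allele": ea,
                "other_allele": oa,
                "beta_exp": float(rec.beta),
                "se_exp": float(rec.se),
                "eaf_exp": float(rec.eaf),
                "beta_out": beta_out,
                "se_out": float(o["se"]),
                "eaf_out": eaf_out,
            }
        )
    for vid, reason in drops:
        logger.info("harmonize %s→%s: dropped %s (%s)", exposure.trait, outcome.trait, vid, reason)
    if not rows:
        raise ValidationError(
            f"no instrument survived harmonization of {exposure.trait!r} vs {outcome.trait!r}"
        )
    drop_frame = pd.DataFrame(drops, columns=["variant_id", "reason"])
    return HarmonizedSet(exposure.trait, outcome.trait, pd.DataFrame(rows), drops=drop_frame)


def wald_ratio(bx: float, sx: float, by: float, sy: float, second_order: bool = False) -> tuple[float, float]:
    """Per-variant causal estimate by/bx with delta-method SE.

    First-order SE is sy/|bx|; the second-order correction adds the
    exposure-uncertainty term.
    """
    if bx == 0:
        raise ValidationError("Wald ratio undefined for bx = 0")
    ratio = by / bx
    if second_order:
        se = np.sqrt(sy**2 / bx**2 + by**2 * sx**2 / bx**4)
    else:
        se = sy / abs(bx)
    return float(ratio), float(se)


def _ratios(hs: HarmonizedSet, second_order: bool = False) -> tuple[np.ndarray, np.ndarray]:
    pairs = [
        wald_ratio(bx, sx, by, sy, second_order)
        for bx, sx, by, sy in zip(hs.beta_exp, hs.se_exp, hs.beta_out, hs.se_out)
    ]
    r = np.array([p[0] for p in pairs])
    s = np.array([p[1] for p in pairs])
    return r, s


def ivw_random_effects(hs: HarmonizedSet, second_order: bool = False) -> MREstimate:
    """Multiplicative random-effects inverse-variance-weighted estimate.

    The point estimate is the precision-weighted mean of the Wald ratios
    (equivalently, WLS of outcome betas on exposure betas through the
    origin with weights 1/se_out²). The fixed-effect SE is inflated by
    √(Q/(L−1)) when Cochran's Q exceeds its degrees of freedom. With a
    single instrument the estimate falls back to that Wald ratio.
    """
    L = len(hs)
    ratios, ses = _ratios(hs, second_order)
    if L < 2:
        est = MREstimate(
            method="IVW-RE",
            beta=float(ratios[0]),
            se=float(ses[0]),
            p=_normal_p(ratios[0] / ses[0]),
            n_snps=1,
            exposure=hs.exposure,
            outcome=hs.outcome,
            note="single instrument: Wald ratio fallback",
        )
        return est
    w = ses**-2
    beta = float(np.sum(w * ratios) / np.sum(w))
    se_fixed = float(np.sum(w) ** -0.5)
    q = float(np.sum(w * (ratios - beta) ** 2))
    df = L - 1
    se = se_fixed * max(1.0, np.sqrt(q / df))
    return MREstimate(
        method="IVW-RE",
        beta=beta,
        se=se,
        p=_normal_p(beta / se),
        n_snps=L,
        q=q,
        q_df=df,
        exposure=hs.exposure,
        outcome=hs.outcome,
    )


def _weighted_median_point(ratios: np.ndarray, weights: np.ndarray) -> float:
    order = np.argsort(ratios, kind="mergesort")
    r, w = ratios[order], weights[order]
    w = w / w.sum()
    s = np.cumsum(w) - 0.5 * w  # cumulative midpoint of each instrument
    if 0.5 <= s[0]:
        return float(r[0])
    if 0.5 >= s[-1]:
        return float(r[-1])
    k = int(np.searchsorted(s, 0.5, side="right")) - 1
    if s[k + 1] == s[k]:
        return float(r[k])
    return float(r[k] + (r[k + 1] - r[k]) * (0.5 - s[k]) / (s[k + 1] - s[k]))


def _parametric_boot(hs: HarmonizedSet, point_fn, n_boot: int, seed) -> float:
    """Bootstrap SE: redraw both betas from their SEs, re-estimate."""
    rng = np.random.default_rng(seed)
    bx, sx = hs.beta_exp, hs.se_exp
    by, sy = hs.beta_out, hs.se_out
    estimates = np.empty(n_boot)
    for b in range(n_boot):
        bxb = rng.normal(bx, sx)
        byb = rng.normal(by, sy)
        bxb[bxb == 0] = np.finfo(float).tiny
        ratios = byb / bxb
        weights = (sy / np.abs(bxb)) ** -2
        estimates[b] = point_fn(ratios, weights)
    return float(estimates.std(ddof=1))


def weighted_median(hs: HarmonizedSet, n_boot: int = 1000, seed=None) -> MREstimate:
    """Weighted-median estimator with parametric-bootstrap SE.

    Instruments are ordered by Wald ratio; the estimate interpolates the
    inverse-variance-weighted 50th percentile. ``n_boot=0`` skips the
    bootstrap (SE and p reported as NaN), useful in simulation loops that
    only need point estimates.
    """
    if len(hs) < 3:
        raise ValidationError("weighted median needs at least 3 instruments")
    ratios, ses = _ratios(hs)
    beta = _weighted_median_point(ratios, ses**-2)
    se = _parametric_boot(hs, _weighted_median_point, n_boot, seed) if n_boot else np.nan
    p = _normal_p(beta / se) if np.isfinite(se) and se > 0 else np.nan
    return MREstimate(
        method="weighted-median",
        beta=beta,
        se=se,
        p=p,
        n_snps=len(hs),
        exposure=hs.exposure,
        outcome=hs.outcome,
    )


def _weighted_mode_point(ratios: np.ndarray, weights: np.ndarray, phi: float = 1.0) -> float:
    if np.all(ratios == ratios[0]):
        return float(ratios[0])
    med = np.median(ratios)
    mad = np.median(np.abs(ratios - med))
    h = phi * 1.4826 * mad
    if h == 0:
        # degenerate MAD (a majority of identical ratios): fall back to a
        # Silverman-scaled weighted SD so the kernel stays narrow enough
        # to resolve the majority cluster
        wm = np.average(ratios, weights=weights)
        sd = np.sqrt(np.average((ratios - wm) ** 2, weights=weights))
        h = phi * 0.9 * sd * ratios.size ** (-1 / 5)
    if h == 0:
        raise ValidationError("degenerate ratio spread: zero bandwidth")
    grid = np.linspace(ratios.min() - 3 * h, ratios.max() + 3 * h, MODE_GRID_POINTS)
    density = np.sum(
        weights[:, None] * np.exp(-0.5 * ((grid[None, :] - ratios[:, None]) / h) ** 2),
        axis=0,
    )
    return float(grid[int(np.argmax(density))])


def weighted_mode(
    hs: HarmonizedSet,
    phi: float = 1.0,
    n_boot: int = 1000,
    seed=None,
) -> MREstimate:
    """Weighted-mode estimator (ZEMPA) with parametric-bootstrap SE.

    The estimate is the maximizer of a Gaussian-kernel density over the
    Wald ratios with inverse-variance weights; the bandwidth is
    ``phi × 1.4826 × MAD`` of the ratios (weighted-SD fallback when the
    MAD is zero), evaluated on a fixed 512-point grid spanning the ratio
    range ± 3 bandwidths.
    """
    if len(hs) < 3:
        raise ValidationError("weighted mode needs at least 3 instruments")
    ratios, ses = _ratios(hs)
    beta = _weighted_mode_point(ratios, ses**-2, phi)
    if np.all(ratios == ratios[0]):
        return MREstimate(
            method="weighted-mode",
            beta=beta,
            se=0.0,
            p=0.0 if beta != 0 else 1.0,
            n_snps=len(hs),
            exposure=hs.exposure,
            outcome=hs.outcome,
            note="all ratios identical",
        )
    se = (
        _parametric_boot(hs, lambda r, w: _weighted_mode_point(r, w, phi), n_boot, seed)
        if n_boot
        else np.nan
    )
    p = _normal_p(beta / se) if np.isfinite(se) and se > 0 else np.nan
    return MREstimate(
        method="weighted-mode",
        beta=beta,
        se=se,
        p=p,
        n_snps=len(hs),
        exposure=hs.exposure,
        outcome=hs.outcome,
    )


def instrument_strength(hs: HarmonizedSet) -> dict:
    """Per-variant F-statistics (beta/se)² with min/median summaries.

    A minimum below the conventional threshold of 10 raises the
    weak-instrument flag.
    """
    f = (hs.beta_exp / hs.se_exp) ** 2
    out = {
        "f_stats": f,
        "f_min": float(f.min()),
        "f_median": float(np.median(f)),
        "weak": bool(f.min() < 10),
    }
    if out["weak"]:
        logger.warning(
            "%s: minimum instrument F = %.1f < 10 (weak-instrument warning)",
            hs.exposure,
            out["f_min"],
        )
    return out


def to_odds_ratio(estimate: MREstimate) -> MREstimate:
    """Exponentiate a log-odds-scale estimate to the OR scale.

    CI bounds are the exponentials of the linear-scale bounds; the SE is
    retained on the log scale. Refuses to exponentiate twice.
    """
    if estimate.scale == "OR":
        raise ValidationError("estimate already on OR scale")
    return replace(
        estimate,
        beta=float(np.exp(estimate.beta)),
        ci_low=float(np.exp(estimate.ci_low)),
        ci_high=float(np.exp(estimate.ci_high)),
        scale="OR",
    )


_METHOD_FNS = {
    "ivw": ivw_random_effects,
    "median": weighted_median,
    "mode": weighted_mode,
}


class TwoSampleMRResults:
    """Estimates from all requested methods for one exposure–outcome pair."""

    def __init__(self, estimates: list[MREstimate], strength: dict, harmonized: HarmonizedSet):
        self.estimates = estimates
        self.strength = strength
        self.harmonized = harmonized

    def __getitem__(self, method: str) -> MREstimate:
        for e in self.estimates:
            if e.method == method or e.method.lower().startswith(method.lower()):
                return e
        raise KeyError(method)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([e.to_row() for e in self.estimates])

    def summary(self) -> str:
        hs = self.harmonized
        lines = [
            f"Two-sample MR: {hs.exposure} → {hs.outcome}",
            "=" * 55,
            f"instruments: {len(hs)}   F min/median: "
            f"{self.strength['f_min']:.1f}/{self.strength['f_median']:.1f}"
            + ("   [weak-instrument warning]" if self.strength["weak"] else ""),
            "",
        ]
        frame = self.to_frame()
        lines.append(
            frame[["method", "n_snps", "beta", "se", "ci_low", "ci_high", "p", "scale"]]
            .to_string(index=False, float_format=lambda v: f"{v:.4g}")
        )
        ivw = next((e for e in self.estimates if e.method == "IVW-RE"), None)
        if ivw is not None and ivw.q is not None:
            lines.append(f"\nCochran's Q = {ivw.q:.3g} on {ivw.q_df} df")
        return "\n".join(lines)


class TwoSampleMR:
    """Model: causal effect of an exposure on an outcome from summary data.

    Built from a :class:`HarmonizedSet` (or via :meth:`from_summary_stats`,
    which selects instruments and harmonizes). ``fit`` runs the requested
    estimators and returns a :class:`TwoSampleMRResults`.
    """

    def __init__(self, harmonized: HarmonizedSet):
        self.harmonized = harmonized

    @classmethod
    def from_summary_stats(
        cls,
        exposure: SummaryStats,
        outcome: SummaryStats,
        ld: LDMatrix,
        p_threshold: float = GENOME_WIDE_P,
        r2_threshold: float = CLUMP_R2,
        palindrome_policy: str = "frequency",
    ) -> "TwoSampleMR":
        instruments = select_instruments(exposure, ld, p_threshold, r2_threshold)
        hs = harmonize(exposure.subset(instruments), outcome, palindrome_policy)
        return cls(hs)

    def fit(
        self,
        methods: tuple[str, ...] = ("ivw", "median", "mode"),
        n_boot: int = 1000,
        seed=None,
        phi: float = 1.0,
        second_order: bool = False,
    ) -> TwoSampleMRResults:
        estimates = []
        rng = np.random.default_rng(seed)
        for method in methods:
            if method not in _METHOD_FNS:
                raise ValidationError(f"unknown MR method {method!r}; choose from {sorted(_METHOD_FNS)}")
            sub = int(rng.integers(0, 2**31 - 1))
            if method == "ivw":
                estimates.append(ivw_random_effects(self.harmonized, second_order))
            elif method == "median":
                estimates.append(weighted_median(self.harmonized, n_boot=n_boot, seed=sub))
            else:
                estimates.append(weighted_mode(self.harmonized, phi=phi, n_boot=n_boot, seed=sub))
        return TwoSampleMRResults(estimates, instrument_strength(self.harmonized), self.harmonized)


def run_mr(
    direction: str,
    exposures: SummaryStats | list[SummaryStats],
    outcomes: SummaryStats | list[SummaryStats],
    ld: LDMatrix,
    methods: tuple[str, ...] = ("ivw", "median", "mode"),
    p_threshold: float = GENOME_WIDE_P,
    r2_threshold: float = CLUMP_R2,
    n_boot: int = 1000,
    seed=None,
    phi: float = 1.0,
    exclude_tags: tuple[str, ...] = (),
    region_map: dict | None = None,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Batch two-sample MR over exposure–outcome pairs, with FDR control.

    ``direction="reverse"`` (liability → metabolites) rescales every
    estimate by ln 2 (per doubling of liability); ``direction="forward"``
    (metabolites → disease) exponentiates to odds ratios. BH FDR is
    applied across outcomes (reverse) or exposures (forward) within each
    method family; the adjusted p is computed from the pre-transformation
    p-values, which both rescalings leave unchanged. When
    ``exclude_tags`` is given, instruments whose region tag matches (via
    ``region_map`` or the summary tables' region column) are removed and
    the whole analysis is repeated as a sensitivity family.
    """
    if direction not in ("reverse", "forward"):
        raise ValidationError(f"direction must be 'reverse' or 'forward': {direction!r}")
    exposures = [exposures] if isinstance(exposures, SummaryStats) else list(exposures)
    outcomes = [outcomes] if isinstance(outcomes, SummaryStats) else list(outcomes)
    rng = np.random.default_rng(seed)

    def _tag(stats: SummaryStats, vid: str) -> str:
        if region_map and vid in region_map:
            return region_map[vid]
        row = stats.table.loc[stats.table["variant_id"] == vid, "region"]
        return row.iloc[0] if len(row) else ""

    def _one_family(sensitivity: str, tags: tuple[str, ...]) -> list[dict]:
        rows = []
        for exp in exposures:
            try:
                instruments = select_instruments(exp, ld, p_threshold, r2_threshold)
            except UninstrumentableExposure as err:
                logger.warning("skipping %s: %s", exp.trait, err)
                continue
            if tags:
                instruments = [v for v in instruments if _tag(exp, v) not in set(tags)]
                if not instruments:
                    logger.warning("skipping %s: region exclusion removed all instruments", exp.trait)
                    continue
            exp_sub = exp.subset(instruments)
            for out in outcomes:
                try:
                    hs = harmonize(exp_sub, out)
                except ValidationError as err:
                    logger.warning("skipping %s→%s: %s", exp.trait, out.trait, err)
                    continue
                res = TwoSampleMR(hs).fit(
                    methods, n_boot=n_boot, seed=int(rng.integers(0, 2**31 - 1)), phi=phi
                )
                for est in res.estimates:
                    if direction == "reverse":
                        est = est.rescaled(LN2, "per-doubling")
                    row = est.to_row()
                    row["p_raw"] = est.p
                    row["f_min"] = res.strength["f_min"]
                    row["f_median"] = res.strength["f_median"]
                    row["weak_instruments"] = res.strength["weak"]
                    row["sensitivity"] = sensitivity
                    row["direction"] = direction
                    rows.append(row)
        return rows

    all_rows = _one_family("none", ())
    if exclude_tags:
        all_rows += _one_family("excl-" + "+".join(sorted(exclude_tags)), tuple(exclude_tags))
    if not all_rows:
        raise ValidationError("no exposure–outcome pair produced an estimate")
    frame = pd.DataFrame(all_rows)

    # FDR within each (sensitivity × method) family, across traits
    frame["p_fdr"] = np.nan
    for (sens, method), idx in frame.groupby(["sensitivity", "method"]).groups.items():
        p = frame.loc[idx, "p_raw"].to_numpy(float)
        ok = np.isfinite(p)
        adj = np.full(p.shape, np.nan)
        if ok.any():
            adj[ok] = bh_adjust(p[ok])
        frame.loc[idx, "p_fdr"] = adj
    frame["flagged"] = frame["p_fdr"] < alpha

    if direction == "forward":
        frame["beta"] = np.exp(frame["beta"])
        frame["ci_low"] = np.exp(frame["ci_low"])
        frame["ci_high"] = np.exp(frame["ci_high"])
        frame["scale"] = "OR"
    return frame.drop(columns=["p_raw"])
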