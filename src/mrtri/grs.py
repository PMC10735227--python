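"""Genetic risk score construction.

LD clumping follows the greedy keep-the-smallest-p rule: candidates are
ordered by ascending p-value (ties broken lexicographically by variant id,
for determinism) and accepted only if their r² with every previously
accepted variant stays at or below the threshold. Scoring uses external
per-allele log-odds weights; by default the weighted allele count is
averaged over the SNPs actually observed for each individual, matching the
usual "sum of weighted dosages divided by the number of SNPs used"
construction. Setting ``per_snp_average=False`` leaves the score on the
summed log-odds-of-disease scale, the scale on which a ×ln2 rescaling
yields effects per doubling of liability.
"""

from __future__ import annotations

import logging

from typing import Iterable, Mapping

import numpy as np

from .datatypes import DosageMatrix, GRSWeights, LDMatrix, SummaryStats, ValidationError

logger = logging.getLogger("mrtri")

__all__ = ["ld_clump", "score_grs", "zscore", "exclude_region"]


def ld_clump(candidates: SummaryStats, ld: LDMatrix, r2_threshold: float) -> list[str]:
    """Greedy LD clumping; returns retained variant ids in acceptance order.

    No two retained variants have r² above ``r2_threshold``. Raises if a
    candidate is absent from the LD matrix.
    """
    if not 0 <= r2_threshold < 1:
        raise ValidationError(f"r2_threshold must lie in [0, 1): {r2_threshold}")
    missing = [v for v in candidates.variant_ids if v not in ld]
    if missing:
        raise ValidationError(f"candidates absent from LD matrix: {missing}")

    order = candidates.table.sort_values(["pvalue", "variant_id"], kind="mergesort")
    idx = {v: i for i, v in enumerate(ld.variant_ids)}
    accepted: list[str] = []
    accepted_idx: list[int] = []
    for vid in order["variant_id"]:
        j = idx[vid]
        if all(ld.r2[j, k] <= r2_threshold for k in accepted_idx):
            accepted.append(vid)
            accepted_idx.append(j)
    logger.info(
        "clumping at r²>%g removed %d of %d candidates",
        r2_threshold,
        len(candidates) - len(accepted),
        len(candidates),
    )
    return accepted


def score_grs(
    dosages: DosageMatrix,
    weights: GRSWeights,
    per_snp_average: bool = True,
    strict_denominator: bool = False,
) -> np.ndarray:
    """Score each individual with external per-allele weights.

    ``score_i = Σ_j w_j·g_ij / m_i`` over the weight variants with a
    non-missing dosage for individual ``i`` (``m_i`` = that count). With
    ``strict_denominator=True`` the denominator is the full overlapping
    SNP count regardless of missingness; with ``per_snp_average=False``
    no division is performed and the score is the weighted allele count in
    log-odds units. Dosage columns whose counted allele differs from the
    weight's effect allele are flipped (g → 2−g) before scoring.
    Individuals with no observed dosage get NaN.
    """
    entries = weights.entries
    col_of = {v: j for j, v in enumerate(dosages.variant_ids)}
    overlap = entries[entries["variant_id"].isin(col_of)].reset_index(drop=True)
    if overlap.empty:
        raise ValidationError(
            f"no overlap between weights ({weights.trait!r}) and dosage matrix variants"
        )
    if len(overlap) < len(entries):
        logger.info(
            "%d of %d weight variants absent from dosages; scoring with %d",
            len(entries) - len(overlap),
            len(entries),
            len(overlap),
        )
    cols = [col_of[v] for v in overlap["variant_id"]]
    g = dosages.dosages[:, cols].copy()
    if dosages.effect_alleles is not None:
        counted = np.array([dosages.effect_alleles[c] for c in cols])
        flip = counted != overlap["effect_allele"].to_numpy()
        if flip.any():
            g[:, flip] = 2.0 - g[:, flip]
            logger.info("flipped orientation of %d dosage columns to match weights", int(flip.sum()))
    w = overlap["weight"].to_numpy(float)

    observed = ~np.isnan(g)
    weighted = np.where(observed, g, 0.0) @ w
    if per_snp_average:
        denom = (
            np.full(g.shape[0], float(len(overlap))) if strict_denominator else observed.sum(axis=1).astype(float)
        )
    else:
        denom = np.ones(g.shape[0])
    m = observed.sum(axis=1)
    scores = np.where(m > 0, weighted / np.where(denom > 0, denom, np.nan), np.nan)
    return scores


def zscore(values: Iterable[float]) -> np.ndarray:
    """Standardize to mean 0, sample SD 1 (ddof=1) over non-missing entries."""
    x = np.asarray(list(values) if not isinstance(values, np.ndarray) else values, dtype=float)
    obs = x[~np.isnan(x)]
    if obs.size < 2:
        raise ValidationError("zscore needs at least 2 non-missing values")
    sd = obs.std(ddof=1)
    if sd == 0:
        raise ValidationError("zscore undefined for a constant vector")
    return (x - obs.mean()) / sd


def exclude_region(
    obj: SummaryStats | GRSWeights,
    tags: Iterable[str],
    region_map: Mapping[str, str] | None = None,
):
    """Drop variants whose gene-region tag is in ``tags``.

    Tags come from the object's own ``region`` column (SummaryStats) or
    from ``region_map`` (variant id → tag), which takes precedence. An
    empty result is allowed but logged as a warning.
    """
    tagset = set(tags)
    if isinstance(obj, SummaryStats):
        t = obj.table
        regions = t["variant_id"].map(region_map).fillna("") if region_map else t["region"]
        keep = ~regions.isin(tagset)
        removed = int((~keep).sum())
        if keep.any():
            out = SummaryStats(obj.trait, t[keep], obj.units)
        else:
            # empty result is legal here (with a warning); bypass the
            # non-empty table invariant enforced by the constructor
            logger.warning("exclude_region removed every variant of %r", obj.trait)
            out = object.__new__(SummaryStats)
            out.trait, out.units, out.table = obj.trait, obj.units, t.iloc[0:0].copy()
    elif isinstance(obj, GRSWeights):
        e = obj.entries
        if region_map is None:
            raise ValidationError("GRSWeights carry no region tags; supply region_map")
        regions = e["variant_id"].map(region_map).fillna("")
        keep = ~regions.isin(tagset)
        removed = int((~keep).sum())
        if not keep.any():
            logger.warning("exclude_region removed every variant of %r", obj.trait)
        out = GRSWeights(e[keep], obj.trait) if keep.any() else GRSWeights(e.iloc[0:0], obj.trait)
    else:
        raise TypeError(f"cannot exclude regions from {type(obj).__name__}")
    logger.info("excluded %d variants tagged %s", removed, sorted(tagset))
    return out
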