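"""Tab-separated readers and writers for the pipeline's tabular formats.

GWAS summary statistics have no single standard layout, so the reader
takes a *dialect* — a mapping from canonical field names to the column
headers actually present. Readers validate and reject bad rows rather
than silently coercing them; rejected-row counts are logged. Writers
round-trip numeric values at 12 significant digits.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .datatypes import (
    SUMMARY_COLUMNS,
    DosageMatrix,
    FormatError,
    LDMatrix,
    SummaryStats,
    ValidationError,
)

logger = logging.getLogger("mrtri")

__all__ = [
    "read_summary_stats",
    "write_summary_stats",
    "read_dosages",
    "write_dosages",
    "read_ld_matrix",
    "write_ld_matrix",
    "write_results",
    "read_results",
    "write_truth_sidecar",
    "read_truth_sidecar",
    "load_config",
]

#: canonical name -> default header
DEFAULT_DIALECT = {
    "variant_id": "variant_id",
    "chrom": "chrom",
    "pos": "pos",
    "effect_allele": "effect_allele",
    "other_allele": "other_allele",
    "eaf": "eaf",
    "beta": "beta",
    "se": "se",
    "pvalue": "pvalue",
    "region": "region",
}

MANDATORY_FIELDS = ("variant_id", "effect_allele", "other_allele", "beta", "se", "pvalue")
MISSING_MARKERS = ("", "NA")


def read_summary_stats(
    path: str | Path,
    trait: str | None = None,
    dialect: Mapping[str, str] | None = None,
    units: str = "",
) -> SummaryStats:
    """Read a summary-statistics table, validating each row.

    Rows whose mandatory fields fail to parse (non-numeric beta/se/p,
    se ≤ 0, p outside (0, 1], malformed alleles) raise a
    :class:`ValidationError` naming the offenders; a missing mandatory
    column raises :class:`FormatError` naming the column.
    """
    path = Path(path)
    mapping = dict(DEFAULT_DIALECT)
    if dialect:
        mapping.update(dialect)
    raw = pd.read_csv(path, sep="\t", dtype=str, na_values=list(MISSING_MARKERS), keep_default_na=False)
    for field in MANDATORY_FIELDS:
        if mapping[field] not in raw.columns:
            raise FormatError(f"{path.name}: missing mandatory column {mapping[field]!r} (field {field!r})")
    out = pd.DataFrame()
    out["variant_id"] = raw[mapping["variant_id"]].astype(str)
    for field in ("chrom", "region"):
        col = mapping[field]
        out[field] = raw[col].fillna("") if col in raw.columns else ""
    for field, required in (("pos", False), ("eaf", False), ("beta", True), ("se", True), ("pvalue", True)):
        col = mapping[field]
        if col in raw.columns:
            out[field] = pd.to_numeric(raw[col], errors="coerce")
        else:
            out[field] = np.nan
        if required and out[field].isna().any():
            bad = out.loc[out[field].isna(), "variant_id"].tolist()
            raise ValidationError(f"{path.name}: unparseable {field!r} for variants {bad}")
    out["pos"] = out["pos"].fillna(0).astype(int)
    out["effect_allele"] = raw[mapping["effect_allele"]].astype(str).str.upper()
    out["other_allele"] = raw[mapping["other_allele"]].astype(str).str.upper()

    bad_se = out.loc[out["se"] <= 0, "variant_id"].tolist()
    if bad_se:
        raise ValidationError(f"{path.name}: non-positive se for variants {bad_se}")
    bad_p = out.loc[(out["pvalue"] <= 0) | (out["pvalue"] > 1), "variant_id"].tolist()
    if bad_p:
        raise ValidationError(f"{path.name}: p-values outside (0, 1] for variants {bad_p}")
    dup = out["variant_id"][out["variant_id"].duplicated()].tolist()
    if dup:
        raise ValidationError(f"{path.name}: duplicate variant ids {sorted(set(dup))}")

    stats = SummaryStats(trait or path.stem, out[SUMMARY_COLUMNS], units=units)
    logger.info("read %d variants for trait %r from %s", len(stats), stats.trait, path)
    return stats


def write_summary_stats(path: str | Path, stats: SummaryStats) -> Path:
    path = Path(path)
    stats.table.to_csv(path, sep="\t", index=False, float_format="%.12g")
    return path


def read_dosages(path: str | Path) -> DosageMatrix:
    """Read a rectangular dosage matrix (rows = individuals, cols = variants).

    The first column holds individual ids; an optional comment line
    ``#effect_alleles`` ahead of the header records per-variant counted
    alleles. "NA" and empty cells are missing. Values outside [0, 2]
    raise with the offending coordinates.
    """
    path = Path(path)
    effect_alleles = None
    with open(path) as fh:
        first = fh.readline()
        if first.startswith("#effect_alleles"):
            effect_alleles = first.strip().split("\t")[1:]
            skip = 1
        else:
            skip = 0
    raw = pd.read_csv(
        path, sep="\t", skiprows=skip, na_values=list(MISSING_MARKERS), keep_default_na=False
    )
    individual_ids = raw.iloc[:, 0].astype(str).tolist()
    variant_ids = list(raw.columns[1:])
    values = raw.iloc[:, 1:].apply(pd.to_numeric, errors="coerce").to_numpy(float)
    unparsed = raw.iloc[:, 1:].notna().to_numpy() & np.isnan(values)
    if unparsed.any():
        r, c = np.argwhere(unparsed)[0]
        raise ValidationError(
            f"{path.name}: unparseable dosage at individual {individual_ids[r]!r}, variant {variant_ids[c]!r}"
        )
    return DosageMatrix(individual_ids, variant_ids, values, effect_alleles)


def write_dosages(path: str | Path, dosages: DosageMatrix) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        if dosages.effect_alleles is not None:
            fh.write("#effect_alleles\t" + "\t".join(dosages.effect_alleles) + "\n")
        fh.write("individual_id\t" + "\t".join(dosages.variant_ids) + "\n")
        for i, ind in enumerate(dosages.individual_ids):
            row = ["%.12g" % v if np.isfinite(v) else "NA" for v in dosages.dosages[i]]
            fh.write(ind + "\t" + "\t".join(row) + "\n")
    return path


def read_ld_matrix(path: str | Path) -> LDMatrix:
    raw = pd.read_csv(path, sep="\t", index_col=0)
    ids = [str(c) for c in raw.columns]
    return LDMatrix(ids, raw.to_numpy(float))


def write_ld_matrix(path: str | Path, ld: LDMatrix) -> Path:
    path = Path(path)
    pd.DataFrame(ld.r2, index=ld.variant_ids, columns=ld.variant_ids).to_csv(
        path, sep="\t", float_format="%.12g"
    )
    return path


def write_results(path: str | Path, rows: pd.DataFrame | Sequence) -> Path:
    """Write a results table (scan rows, MR estimates or triangulation rows).

    Accepts a DataFrame or a sequence of objects exposing ``to_row()``.
    Refuses to write an empty table.
    """
    path = Path(path)
    if isinstance(rows, pd.DataFrame):
        frame = rows
    else:
        rows = list(rows)
        if rows and hasattr(rows[0], "to_row"):
            frame = pd.DataFrame([r.to_row() for r in rows])
        else:
            frame = pd.DataFrame(rows)
    if frame.empty:
        raise ValidationError(f"refusing to write empty results table to {path}")
    frame.to_csv(path, sep="\t", index=False, float_format="%.12g")
    logger.info("wrote %d result rows to %s", len(frame), path)
    return path


def read_results(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", na_values=list(MISSING_MARKERS), keep_default_na=False)


def write_truth_sidecar(path: str | Path, params: Mapping) -> Path:
    """Record all generative parameters of a synthetic dataset (YAML)."""
    path = Path(path)

    def _plain(obj):
        if isinstance(obj, Mapping):
            return {str(k): _plain(v) for k, v in obj.items()}
        if isinstance(obj, np.ndarray):
            return [_plain(v) for v in obj.tolist()]
        if isinstance(obj, (list, tuple)):
            return [_plain(v) for v in obj]
        if isinstance(obj, (np.integer,)):
            return int(obj)
        if isinstance(obj, (np.floating,)):
            return float(obj)
        return obj

    with open(path, "w") as fh:
        yaml.safe_dump(_plain(params), fh, sort_keys=False)
    return path


def read_truth_sidecar(path: str | Path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)


def load_config(path: str | Path) -> dict:
    """Load a YAML run configuration (paths, thresholds, seeds)."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise FormatError(f"{path}: configuration must be a mapping")
    return cfg
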