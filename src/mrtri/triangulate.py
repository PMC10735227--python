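"""Triangulation of the three evidence streams.

Each metabolite is classified from the directions of its FDR-flagged
results in (1) the cohort liability scan, (2) reverse MR of liability on
the metabolite, and (3) forward MR of the metabolite on disease risk.
Consistent flagged evidence in all three streams marks a metabolite as a
causal candidate; liability-side evidence without forward support marks a
liability marker (a trait predictive of, but not necessarily causal for,
the disease); conflicting flagged signs are reported as inconsistent.
The classification is an explicit operationalization of the informal
"consistent evidence across approaches" reading and is labelled as such
in the report.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datatypes import ValidationError

logger = logging.getLogger("mrtri")

__all__ = ["TriangulationRow", "classify_consistency", "summarize", "CLASSES"]

CLASSES = (
    "consistent-causal-candidate",
    "liability-marker-only",
    "forward-only",
    "inconsistent",
    "insufficient",
)


@dataclass
class TriangulationRow:
    """Directional-consistency call for one metabolite."""

    metabolite: str
    scan_direction: int | None  # +1 / -1 / None (not flagged)
    reverse_direction: int | None
    forward_side: int | None  # +1 (OR>1) / -1 (OR<1) / None
    consistency_class: str
    note: str = ""

    def to_row(self) -> dict:
        fmt = {1: "+", -1: "-", None: ""}
        return {
            "metabolite": self.metabolite,
            "scan_direction": fmt[self.scan_direction],
            "reverse_direction": fmt[self.reverse_direction],
            "forward_or_side": {1: ">1", -1: "<1", None: ""}[self.forward_side],
            "class": self.consistency_class,
            "note": self.note,
        }


def _classify(scan: int | None, reverse: int | None, forward: int | None) -> str:
    """Pure classification rule; precedence documented in the module docstring."""
    flagged = [d for d in (scan, reverse, forward) if d is not None]
    if not flagged:
        return "insufficient"
    if len(set(flagged)) > 1:
        return "inconsistent"
    if scan is not None and reverse is not None and forward is not None:
        return "consistent-causal-candidate"
    if forward is not None:
        return "forward-only"
    return "liability-marker-only"


def _sign(x: float) -> int:
    return 1 if x > 0 else -1


def classify_consistency(
    scan: pd.DataFrame,
    reverse: pd.DataFrame,
    forward: pd.DataFrame,
    alpha: float = 0.05,
    primary_method: str = "IVW-RE",
) -> list[TriangulationRow]:
    """Assign each metabolite a directional-consistency class.

    ``scan`` is a liability-scan results table (one row per metabolite ×
    time point); the scan direction is taken from the metabolite's
    smallest-FDR time point when that row is flagged. ``reverse`` and
    ``forward`` are ``run_mr`` tables; directions come from the flagged
    primary-method (IVW) rows, with a concordance note when the other
    methods disagree in sign. The forward OR side compares the odds ratio
    with 1 (log scale: with 0). Metabolites missing from a stream are
    classified from the available streams with a completeness note.
    """
    mets: list[str] = []
    for frame, col in ((scan, "metabolite"), (reverse, "outcome"), (forward, "exposure")):
        for m in frame[col].unique():
            if m not in mets:
                mets.append(m)

    sens_col = "sensitivity"
    scan_main = scan[scan[sens_col] == "none"] if sens_col in scan.columns else scan
    rev_main = reverse[reverse[sens_col] == "none"] if sens_col in reverse.columns else reverse
    fwd_main = forward[forward[sens_col] == "none"] if sens_col in forward.columns else forward

    rows = []
    for met in mets:
        notes = []

        sub = scan_main[scan_main["metabolite"] == met]
        if sub.empty:
            scan_dir = None
            notes.append("missing:scan")
        else:
            best = sub.loc[sub["p_fdr"].idxmin()]
            scan_dir = _sign(best["beta_per_doubling"]) if best["p_fdr"] < alpha else None

        def _mr_direction(frame: pd.DataFrame, trait_col: str, stream: str):
            sub = frame[(frame[trait_col] == met) & (frame["method"] == primary_method)]
            if sub.empty:
                notes.append(f"missing:{stream}")
                return None
            row = sub.iloc[0]
            null_value = 1.0 if row["scale"] == "OR" else 0.0
            direction = _sign(row["beta"] - null_value) if row["p_fdr"] < alpha else None
            others = frame[(frame[trait_col] == met) & (frame["method"] != primary_method)]
            if direction is not None and len(others):
                signs = {_sign(b - null_value) for b in others["beta"]}
                if signs - {direction}:
                    notes.append(f"{stream}: sensitivity-method sign discordance")
            return direction

        rev_dir = _mr_direction(rev_main, "outcome", "reverse")
        fwd_side = _mr_direction(fwd_main, "exposure", "forward")

        rows.append(
            TriangulationRow(
                metabolite=met,
                scan_direction=scan_dir,
                reverse_direction=rev_dir,
                forward_side=fwd_side,
                consistency_class=_classify(scan_dir, rev_dir, fwd_side),
                note="; ".join(notes),
            )
        )
    return rows


def summarize(rows: list[TriangulationRow]) -> dict:
    """Counts per class plus the causal-candidate list and a text report."""
    if not rows:
        raise ValidationError("nothing to summarize")
    counts = {c: 0 for c in CLASSES}
    for r in rows:
        counts[r.consistency_class] += 1
    candidates = [r.metabolite for r in rows if r.consistency_class == "consistent-causal-candidate"]
    lines = [
        "Triangulation of liability-scan, reverse-MR and forward-MR evidence",
        "(explicit operationalization of cross-stream directional consistency)",
        "=" * 68,
        f"metabolites classified: {len(rows)}",
    ]
    for cls in CLASSES:
        if counts[cls]:
            lines.append(f"  {cls:<30s} {counts[cls]}")
    if candidates:
        lines.append("")
        lines.append("consistent causal candidates: " + ", ".join(candidates))
    report = "\n".join(lines)
    return {"counts": counts, "candidates": candidates, "n": len(rows), "report": report}


def to_frame(rows: list[TriangulationRow]) -> pd.DataFrame:
    return pd.DataFrame([r.to_row() for r in rows])
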