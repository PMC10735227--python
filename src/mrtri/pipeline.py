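"""End-to-end assembly of the three evidence streams.

Convenience layer used by the CLI, tests and reproduction script: runs
the liability scan, reverse MR and forward MR on a generated (or loaded)
scenario and triangulates the results.
"""

from __future__ import annotations

import logging

import pandas as pd

from .mr import run_mr
from .scan import run_scan
from .triangulate import classify_consistency, summarize, to_frame

logger = logging.getLogger("mrtri")

__all__ = ["triangulate_scenario"]


def triangulate_scenario(
    scenario: dict,
    n_boot: int = 500,
    seed: int | None = None,
    alpha: float = 0.05,
    methods: tuple[str, ...] = ("ivw", "median", "mode"),
) -> dict:
    """Run scan + reverse MR + forward MR on a synthetic scenario.

    Returns the three result tables, the triangulation rows and the
    summary report.
    """
    scan_frame = run_scan(
        scenario["cohort"],
        dosages=scenario["dosages"],
        weights=scenario["weights"],
        alpha=alpha,
    )
    reverse_frame = run_mr(
        "reverse",
        scenario["panel_stats"],
        scenario["reverse_outcomes"],
        scenario["panel_ld"],
        methods=methods,
        n_boot=n_boot,
        seed=seed,
        alpha=alpha,
    )
    forward_frame = run_mr(
        "forward",
        scenario["forward_exposures"],
        scenario["disease_outcome"],
        scenario["forward_ld"],
        methods=methods,
        n_boot=n_boot,
        seed=None if seed is None else seed + 1,
        alpha=alpha,
    )
    rows = classify_consistency(scan_frame, reverse_frame, forward_frame, alpha=alpha)
    report = summarize(rows)
    return {
        "scan": scan_frame,
        "reverse": reverse_frame,
        "forward": forward_frame,
        "triangulation": to_frame(rows),
        "rows": rows,
        "summary": report,
    }
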