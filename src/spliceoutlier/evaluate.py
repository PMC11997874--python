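"""Scoring of detection output against simulated ground truth.

Gene-level metrics follow the standard benchmark definitions: a gene is
*identified* when at least one of its junctions drew at least one tumor
outlier call surviving the expression-floor and fold-change filters, and
*identified + significant* when at least one of its junctions reached
BH-adjusted Fisher p <= the threshold. Sensitivity is TP over truth-positive
genes, specificity TN over truth-negative genes, and FDR the fraction of
called genes lacking a true event.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .core import EventResult

LEVEL_IDENTIFIED = "identified"
LEVEL_SIGNIFICANT = "identified_and_significant"

RULE_OUTLIER = "outlier"  # >=1 tumor outlier call on some junction
RULE_TESTED = "tested"  # any tested junction marks its gene


@dataclass(frozen=True)
class EvalReport:
    level: str
    true_positive: int
    total_identified: int
    sensitivity: float
    specificity: float
    fdr: float


def gene_level_calls(
    results: Sequence[EventResult],
    level: str = LEVEL_IDENTIFIED,
    fdr_threshold: float = 0.05,
    identified_rule: str = RULE_OUTLIER,
) -> set[str]:
    """Collapse junction-level results to the set of called genes."""
    called: set[str] = set()
    for r in results:
        if r.gene is None:
            continue
        if level == LEVEL_IDENTIFIED:
            if identified_rule == RULE_TESTED or r.tumor_outliers >= 1:
                called.add(r.gene)
        elif level == LEVEL_SIGNIFICANT:
            if r.fdr <= fdr_threshold:
                called.add(r.gene)
        else:
            raise ValueError(f"unknown level {level!r}")
    return called


def score(
    calls: Iterable[str],
    truth_positive: Iterable[str],
    all_genes: Iterable[str],
    level: str = LEVEL_IDENTIFIED,
) -> EvalReport:
    """Confusion counts and Table-style metrics over the simulated gene set."""
    universe = set(all_genes)
    positives = set(truth_positive) & universe
    negatives = universe - positives
    called = set(calls) & universe

    tp = len(called & positives)
    fp = len(called & negatives)
    tn = len(negatives - called)
    total = len(called)

    sensitivity = tp / len(positives) if positives else float("nan")
    specificity = tn / len(negatives) if negatives else float("nan")
    fdr = fp / total if total else 0.0
    return EvalReport(
        level=level,
        true_positive=tp,
        total_identified=total,
        sensitivity=sensitivity,
        specificity=specificity,
        fdr=fdr,
    )


def report_frame(reports: Sequence[EvalReport]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "level": r.level,
                "true_positive": r.true_positive,
                "total_identified": r.total_identified,
                "sensitivity": r.sensitivity,
                "specificity": r.specificity,
                "fdr": r.fdr,
            }
            for r in reports
        ]
    )
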