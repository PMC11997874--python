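"""High-level composition: normalization -> annotation -> detection -> summary.

`run_detect` wires the individual modules into the full cohort analysis, and
`run_benchmark` repeats simulate -> detect -> score over replicate seeds for
the synthetic-cohort evaluation.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional, Sequence

import pandas as pd

from . import annotate, evaluate, normalize, outliers
from .core import (
    EventResult,
    GeneModel,
    JunctionCountMatrix,
    NormalizedJunctionMatrix,
    OutlierCallMatrix,
)
from .burden import compute_burden
from .simulate import SimConfig, SimulatedData, simulate_cohort


@dataclass
class DetectOutput:
    results: list[EventResult]
    calls: OutlierCallMatrix
    normalized: NormalizedJunctionMatrix
    gene_map: pd.Series
    event_types: pd.Series
    burden: pd.DataFrame


def run_detect(
    counts: JunctionCountMatrix,
    gene_expression: pd.DataFrame,
    phenotype: pd.Series,
    model: Optional[GeneModel] = None,
    norm_config: Optional[normalize.NormalizationConfig] = None,
    outlier_config: Optional[outliers.OutlierConfig] = None,
) -> DetectOutput:
    """Run the full junction-outlier analysis on one cohort.

    Junction counts are converted to reads per million, divided by the
    upper-quartile-normalized expression of their host gene (mapped through
    the annotation model when given), filtered, outlier-called against the
    normal panel, and tested per junction and direction with pooled BH
    correction. Returns every intermediate a downstream consumer needs.
    """
    norm_config = norm_config or normalize.NormalizationConfig()
    outlier_config = outlier_config or outliers.OutlierConfig()

    lib_frac = normalize.to_library_fraction(counts, norm_config)
    expr_norm = normalize.upper_quartile_normalize(gene_expression, norm_config)

    junctions = counts.junctions
    if model is not None:
        gene_map = annotate.map_junctions_to_genes(junctions, model)
        event_types = annotate.classify_events(junctions, gene_map, model)
    else:
        gene_map = pd.Series(
            [None] * len(junctions), index=lib_frac.index, dtype=object, name="gene"
        )
        event_types = pd.Series(
            [annotate.EVENT_UNMAPPED] * len(junctions), index=lib_frac.index, name="event_type"
        )

    norm_matrix = normalize.normalize_by_gene(lib_frac, expr_norm, gene_map)
    results, calls = outliers.detect_events(
        norm_matrix,
        phenotype,
        outlier_config,
        gene_map=gene_map,
        event_types=event_types,
        return_calls=True,
    )
    burden = compute_burden(results, calls, outlier_config.fdr_threshold, phenotype)
    return DetectOutput(
        results=results,
        calls=calls,
        normalized=norm_matrix,
        gene_map=gene_map,
        event_types=event_types,
        burden=burden,
    )


def evaluate_simulated(
    data: SimulatedData,
    output: DetectOutput,
    fdr_threshold: float = 0.05,
) -> dict[str, evaluate.EvalReport]:
    """Score one simulated cohort at both gene-call levels."""
    all_genes = sorted(data.model.genes)
    reports = {}
    for level in (evaluate.LEVEL_IDENTIFIED, evaluate.LEVEL_SIGNIFICANT):
        calls = evaluate.gene_level_calls(output.results, level, fdr_threshold)
        reports[level] = evaluate.score(calls, data.truth.alt_genes, all_genes, level)
    return reports


def run_simulate_evaluate(
    sim_config: SimConfig,
    outlier_config: Optional[outliers.OutlierConfig] = None,
) -> tuple[SimulatedData, DetectOutput, dict[str, evaluate.EvalReport]]:
    """simulate -> detect -> score, all driven by the config seed."""
    outlier_config = outlier_config or outliers.OutlierConfig(fold_change_cutoff=2.0)
    data = simulate_cohort(sim_config)
    output = run_detect(
        data.counts,
        data.gene_expression,
        data.phenotype,
        model=data.model,
        outlier_config=outlier_config,
    )
    reports = evaluate_simulated(data, output, outlier_config.fdr_threshold)
    return data, output, reports


def run_benchmark(
    sim_config: Optional[SimConfig] = None,
    outlier_config: Optional[outliers.OutlierConfig] = None,
    n_replicates: int = 10,
    base_seed: int = 1,
) -> pd.DataFrame:
    """Replicate the synthetic benchmark across seeds.

    Returns one row per replicate with sensitivity/specificity/FDR at both
    the identified and the identified+significant levels; replicate seeds are
    ``1000 * base_seed + i``.
    """
    sim_config = sim_config or SimConfig()
    rows = []
    for i in range(n_replicates):
        cfg = replace(sim_config, seed=1000 * base_seed + i)
        _, _, reports = run_simulate_evaluate(cfg, outlier_config)
        ident = reports[evaluate.LEVEL_IDENTIFIED]
        sig = reports[evaluate.LEVEL_SIGNIFICANT]
        rows.append(
            {
                "seed": cfg.seed,
                "tp_identified": ident.true_positive,
                "total_identified": ident.total_identified,
                "sens_identified": ident.sensitivity,
                "spec_identified": ident.specificity,
                "fdr_identified": ident.fdr,
                "tp_significant": sig.true_positive,
                "total_significant": sig.total_identified,
                "sens_significant": sig.sensitivity,
                "spec_significant": sig.specificity,
                "fdr_significant": sig.fdr,
            }
        )
    return pd.DataFrame(rows)
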