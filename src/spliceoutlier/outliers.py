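"""Outlier calling against the normal panel and per-junction Fisher testing.

Each tumor sample's normalized junction expression is compared with the
distribution of the normal samples. The outlier statistic is Ghosh-style
robust fences — quantile(1 - tail) + k*IQR above, quantile(tail) - k*IQR
below — modified by two absolute requirements: the cell must clear a minimum
normalized-expression floor, and it must differ from the normal median by at
least a fold-change cutoff. Normal samples are labeled with leave-one-out
fences so a normal value is never compared against a distribution containing
itself.

Per junction and direction, a one-sided Fisher's exact test asks whether
outliers are enriched among tumors, and Benjamini-Hochberg correction is
applied jointly across every tested (junction, direction) pair.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .core import (
    CALL_NONE,
    CALL_OVER,
    CALL_UNDER,
    CALL_UNDEFINED,
    EventResult,
    JunctionKey,
    NormalizedJunctionMatrix,
    OutlierCallMatrix,
    index_to_junctions,
)
from .io import NORMAL, TUMOR, validate_phenotype

#: guard for fold-change ratios when the reference median is zero
EPSILON = 1e-12


@dataclass
class OutlierConfig:
    """Detection parameters.

    min_norm_expr
        Absolute floor on normalized junction expression: an over-outlier
        cell (or the normal median, for under-outliers) must reach this
        value. Default 0.00001 on the pipeline's normalized-RPM scale.
    fold_change_cutoff
        Minimum ratio between the cell and the normal median (default 10;
        simulation benchmarks with mild expression separation use 2).
    fdr_threshold
        BH-adjusted significance cutoff for events (default 0.05).
    tail_quantile, iqr_multiplier
        Fence construction: upper fence = Q(1 - tail) + k*IQR, lower fence =
        Q(tail) - k*IQR over the normal panel (defaults 0.25 and 1.5, i.e.
        Tukey fences).
    exclude_sex_chromosomes
        Drop chrX/chrY junctions before testing (default on: tumor biology
        rather than sex should drive the signal).
    """

    min_norm_expr: float = 0.00001
    fold_change_cutoff: float = 10.0
    fdr_threshold: float = 0.05
    tail_quantile: float = 0.25
    iqr_multiplier: float = 1.5
    exclude_sex_chromosomes: bool = True
    sex_chromosome_names: frozenset[str] = frozenset({"chrX", "chrY", "X", "Y"})

    def __post_init__(self) -> None:
        if self.min_norm_expr < 0:
            raise ValueError("min_norm_expr must be >= 0")
        if self.fold_change_cutoff < 1:
            raise ValueError("fold_change_cutoff must be >= 1")
        if not 0 < self.fdr_threshold < 1:
            raise ValueError("fdr_threshold must be in (0, 1)")
        if not 0 < self.tail_quantile < 0.5:
            raise ValueError("tail_quantile must be in (0, 0.5)")
        if self.iqr_multiplier < 0:
            raise ValueError("iqr_multiplier must be >= 0")


def filter_sex_chromosomes(
    matrix: NormalizedJunctionMatrix, config: Optional[OutlierConfig] = None
) -> NormalizedJunctionMatrix:
    """Remove junctions on the sex chromosomes (no other rows are altered)."""
    config = config or OutlierConfig()
    if not config.exclude_sex_chromosomes:
        return matrix
    chroms = matrix.values.index.get_level_values("chromosome")
    keep = ~chroms.isin(config.sex_chromosome_names)
    return NormalizedJunctionMatrix(
        values=matrix.values.loc[keep],
        gene=matrix.gene.loc[keep],
        no_gene=matrix.no_gene.loc[keep],
    )


def _fences(
    normals: np.ndarray, config: OutlierConfig
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Median and robust fences along axis 1, NaN-aware.

    ``normals`` is junctions x normal-samples; rows that are all-NaN yield
    NaN statistics.
    """
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        lo_q = np.nanquantile(normals, config.tail_quantile, axis=1)
        hi_q = np.nanquantile(normals, 1.0 - config.tail_quantile, axis=1)
        median = np.nanmedian(normals, axis=1)
    iqr = hi_q - lo_q
    return median, lo_q - config.iqr_multiplier * iqr, hi_q + config.iqr_multiplier * iqr


def _label_cells(
    values: np.ndarray,
    median: np.ndarray,
    lower: np.ndarray,
    upper: np.ndarray,
    config: OutlierConfig,
) -> np.ndarray:
    """Apply the outlier rules to a junctions x samples block.

    The fence comparisons are strict, so constant junctions never produce
    outliers; reference arrays broadcast along axis 0.
    """
    median = median[:, None]
    lower = lower[:, None]
    upper = upper[:, None]
    defined = ~np.isnan(values) & ~np.isnan(median)
    with np.errstate(invalid="ignore"):
        over = (
            defined
            & (values > upper)
            & (values >= config.min_norm_expr)
            & (values >= config.fold_change_cutoff * np.maximum(median, EPSILON))
        )
        under = (
            defined
            & (values < lower)
            & (median >= config.min_norm_expr)
            & (median >= config.fold_change_cutoff * np.maximum(values, EPSILON))
        )
    labels = np.full(values.shape, CALL_NONE, dtype=object)
    labels[~defined] = CALL_UNDEFINED
    labels[over] = CALL_OVER
    labels[under] = CALL_UNDER
    return labels


def call_outliers(
    matrix: NormalizedJunctionMatrix,
    phenotype: pd.Series,
    config: Optional[OutlierConfig] = None,
) -> OutlierCallMatrix:
    """Label every (junction, sample) cell as over / under / none / undefined.

    Tumor cells are compared against fences from all defined normal values of
    the junction; each normal cell is compared against fences recomputed from
    the *other* normals. Junctions with fewer than two defined normal values
    are marked all-undefined.
    """
    config = config or OutlierConfig()
    pheno = validate_phenotype(phenotype, matrix.samples)
    values = matrix.values.to_numpy(dtype=float)
    samples = matrix.samples
    is_normal = (pheno == NORMAL).to_numpy()
    normal_block = values[:, is_normal]

    enough = (~np.isnan(normal_block)).sum(axis=1) >= 2
    median, lower, upper = _fences(normal_block, config)
    median[~enough] = np.nan
    lower[~enough] = np.nan
    upper[~enough] = np.nan

    labels = np.full(values.shape, CALL_UNDEFINED, dtype=object)
    tumor_cols = np.flatnonzero(~is_normal)
    labels[:, tumor_cols] = _label_cells(values[:, tumor_cols], median, lower, upper, config)

    normal_cols = np.flatnonzero(is_normal)
    for pos, col in enumerate(normal_cols):
        rest = np.delete(normal_block, pos, axis=1)
        med_i, lo_i, up_i = _fences(rest, config)
        med_i[~enough] = np.nan
        lo_i[~enough] = np.nan
        up_i[~enough] = np.nan
        labels[:, [col]] = _label_cells(values[:, [col]], med_i, lo_i, up_i, config)

    reference = pd.DataFrame(
        {"median": median, "lower_fence": lower, "upper_fence": upper},
        index=matrix.values.index,
    )
    calls = pd.DataFrame(labels, index=matrix.values.index, columns=samples)
    return OutlierCallMatrix(calls=calls, reference=reference)


def fisher_test_junction(
    tumor_outliers: int, tumor_n: int, normal_outliers: int, normal_n: int
) -> float:
    """One-sided Fisher's exact p for outlier enrichment in tumors.

    Computed as the hypergeometric upper tail of the 2x2 table
    [[tumor_outliers, tumor_n - tumor_outliers],
     [normal_outliers, normal_n - normal_outliers]].
    """
    if tumor_n == 0 or normal_n == 0:
        raise ValueError("fisher test undefined with an empty group")
    if tumor_outliers > tumor_n or normal_outliers > normal_n:
        raise ValueError("outlier counts exceed group sizes")
    return float(
        stats.hypergeom.sf(
            tumor_outliers - 1,
            tumor_n + normal_n,
            tumor_outliers + normal_outliers,
            tumor_n,
        )
    )


def _fisher_many(
    tumor_outliers: np.ndarray,
    tumor_n: np.ndarray,
    normal_outliers: np.ndarray,
    normal_n: np.ndarray,
) -> np.ndarray:
    return stats.hypergeom.sf(
        tumor_outliers - 1,
        tumor_n + normal_n,
        tumor_outliers + normal_outliers,
        tumor_n,
    )


def bh_fdr(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, order-preserving."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def detect_events(
    matrix: NormalizedJunctionMatrix,
    phenotype: pd.Series,
    config: Optional[OutlierConfig] = None,
    gene_map: Optional[pd.Series] = None,
    event_types: Optional[pd.Series] = None,
    return_calls: bool = False,
):
    """Full junction-level detection: filter, call outliers, test, adjust.

    Returns the list of EventResult (one per tested junction and direction);
    with ``return_calls=True`` also returns the OutlierCallMatrix so
    downstream burden summaries can reuse the per-sample labels.
    """
    config = config or OutlierConfig()
    matrix = filter_sex_chromosomes(matrix, config)
    calls = call_outliers(matrix, phenotype, config)
    pheno = validate_phenotype(phenotype, matrix.samples)
    labels = calls.calls.to_numpy(dtype=object)
    is_normal = (pheno == NORMAL).to_numpy()

    defined = labels != CALL_UNDEFINED
    tumor_defined = defined[:, ~is_normal]
    normal_defined = defined[:, is_normal]
    tumor_n = tumor_defined.sum(axis=1)
    normal_n = normal_defined.sum(axis=1)
    testable = (tumor_n > 0) & (normal_n > 0)

    junctions = index_to_junctions(matrix.values.index)
    sample_arr = np.asarray(matrix.samples, dtype=object)
    records: list[dict] = []
    for direction in (CALL_OVER, CALL_UNDER):
        hits = labels == direction
        t_hits = hits[:, ~is_normal].sum(axis=1)
        n_hits = hits[:, is_normal].sum(axis=1)
        idx = np.flatnonzero(testable)
        if idx.size:
            pvals = _fisher_many(t_hits[idx], tumor_n[idx], n_hits[idx], normal_n[idx])
        else:
            pvals = np.array([])
        for k, row in enumerate(idx):
            records.append(
                {
                    "row": int(row),
                    "direction": direction,
                    "tumor_outliers": int(t_hits[row]),
                    "normal_outliers": int(n_hits[row]),
                    "tumor_n": int(tumor_n[row]),
                    "normal_n": int(normal_n[row]),
                    "p_value": float(pvals[k]),
                    "outlier_samples": tuple(sample_arr[hits[row]]),
                }
            )

    fdrs = bh_fdr([r["p_value"] for r in records])
    results: list[EventResult] = []
    for rec, fdr in zip(records, fdrs):
        junction = junctions[rec["row"]]
        gene = None
        if gene_map is not None:
            g = gene_map.get(tuple(junction))
            gene = None if g is None or pd.isna(g) else str(g)
        etype = "unmapped"
        if event_types is not None:
            et = event_types.get(tuple(junction))
            if et is not None and not pd.isna(et):
                etype = str(et)
        results.append(
            EventResult(
                junction=junction,
                gene=gene,
                event_type=etype,
                direction=rec["direction"],
                tumor_outliers=rec["tumor_outliers"],
                normal_outliers=rec["normal_outliers"],
                tumor_n=rec["tumor_n"],
                normal_n=rec["normal_n"],
                p_value=rec["p_value"],
                fdr=float(fdr),
                outlier_samples=rec["outlier_samples"],
            )
        )
    if return_calls:
        return results, calls
    return results
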