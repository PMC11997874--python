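"""Library-size and gene-expression normalization of junction counts.

The pipeline scale is reads-per-million by default: junction counts are
divided by the sample's total uniquely mapped reads and multiplied by 1e6,
then divided by the host gene's upper-quartile-normalized expression. On this
scale a typical expressed junction sits near 1 and the 0.00001 outlier floor
acts as a minimum-expression filter. A plain proportion scale (no 1e6 factor)
is available for users who prefer raw library fractions; the outlier floor in
OutlierConfig is interpreted on whichever scale is chosen.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .core import JunctionCountMatrix, NormalizedJunctionMatrix

PROPORTION = "proportion"
PER_MILLION = "per_million"


@dataclass
class NormalizationConfig:
    """Knobs of the two normalization steps.

    uq_target
        Value the per-sample upper quartile of expressed genes is scaled to.
        1000 matches the convention of the classic UNC quartile-normalization
        utility for RSEM expected counts.
    rpm_scale
        "per_million" (reads per million, default) or "proportion"
        (count / library size).
    uq_nonzero_only
        Compute the 75th percentile over genes with value > 0 only (default),
        or over all genes.
    """

    uq_target: float = 1000.0
    rpm_scale: str = PER_MILLION
    uq_nonzero_only: bool = True

    def __post_init__(self) -> None:
        if self.uq_target <= 0:
            raise ValueError("uq_target must be > 0")
        if self.rpm_scale not in (PROPORTION, PER_MILLION):
            raise ValueError(f"unknown rpm_scale {self.rpm_scale!r}")


def to_library_fraction(
    counts: JunctionCountMatrix, config: Optional[NormalizationConfig] = None
) -> pd.DataFrame:
    """Divide each junction count by its sample's library size.

    Returns reads-per-million under the default scale, or the plain
    proportion when ``rpm_scale="proportion"``.
    """
    config = config or NormalizationConfig()
    scale = 1e6 if config.rpm_scale == PER_MILLION else 1.0
    return counts.counts.div(counts.library_sizes, axis=1) * scale


def upper_quartile_normalize(
    expr: pd.DataFrame, config: Optional[NormalizationConfig] = None
) -> pd.DataFrame:
    """Rescale each sample so its upper quartile of expressed genes is uq_target.

    The 75th percentile uses the exclusive (type-6, ``h = (n+1)p``)
    interpolation rule over the genes with value > 0 in that sample.
    """
    config = config or NormalizationConfig()
    out = {}
    for sample in expr.columns:
        values = expr[sample].to_numpy(dtype=float)
        pool = values[values > 0] if config.uq_nonzero_only else values
        if pool.size == 0 or not np.any(pool > 0):
            raise ValueError(f"sample {sample!r} has all-zero expression; cannot normalize")
        q75 = float(np.percentile(pool, 75, method="weibull"))
        out[sample] = values / q75 * config.uq_target
    return pd.DataFrame(out, index=expr.index, columns=expr.columns)


def normalize_by_gene(
    lib_frac: pd.DataFrame,
    expr_norm: pd.DataFrame,
    junction_to_gene: pd.Series,
) -> NormalizedJunctionMatrix:
    """Divide junction expression by the normalized expression of its host gene.

    Cells whose host gene has zero normalized expression become NaN
    ("undefined", excluded from outlier calling). Junctions with no gene
    mapping — or mapped to a gene absent from the expression matrix — are
    carried through un-normalized (divisor 1) and flagged ``no_gene`` so
    novel-junction discovery still works.
    """
    gene = junction_to_gene.reindex(lib_frac.index)
    mapped = gene.notna() & gene.isin(expr_norm.index)
    divisor = pd.DataFrame(1.0, index=lib_frac.index, columns=lib_frac.columns)
    if mapped.any():
        divisor.loc[mapped] = expr_norm.loc[gene[mapped]].to_numpy(dtype=float)
    div = divisor.to_numpy(dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        values = lib_frac.to_numpy(dtype=float) / div
    values[div == 0] = np.nan
    return NormalizedJunctionMatrix(
        values=pd.DataFrame(values, index=lib_frac.index, columns=lib_frac.columns),
        gene=gene.where(mapped),
        no_gene=~mapped,
    )
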