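"""Per-sample splice burden and waterfall-plot data for significant events.

The splice burden counts, for every sample (normals included, expected near
zero), the significant events in which that sample is itself the outlier —
split by direction and by event type, so cohorts can be ranked by how much
aberrant splicing each sample underwent.
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .core import (
    CALL_OVER,
    CALL_UNDER,
    EventResult,
    JunctionKey,
    NormalizedJunctionMatrix,
    OutlierCallMatrix,
)


def compute_burden(
    results: Sequence[EventResult],
    calls: OutlierCallMatrix,
    fdr_threshold: float,
    phenotype: Optional[pd.Series] = None,
) -> pd.DataFrame:
    """Tabulate per-sample counts of significant events (fdr <= threshold).

    Returns a DataFrame indexed by sample with columns over_count,
    under_count, total, one column per observed event type, and (when a
    phenotype is given) the sample group.
    """
    samples = calls.samples
    event_types = sorted({r.event_type for r in results})
    over = pd.Series(0, index=samples, dtype=int)
    under = pd.Series(0, index=samples, dtype=int)
    by_type = {t: pd.Series(0, index=samples, dtype=int) for t in event_types}

    for r in results:
        if r.fdr > fdr_threshold:
            continue
        key = tuple(r.junction)
        if key not in calls.calls.index:
            raise ValueError(
                f"result junction {r.junction} absent from the outlier-call matrix; "
                "results and calls must come from the same run"
            )
        row = calls.calls.loc[key]
        hit = row == r.direction
        target = over if r.direction == CALL_OVER else under
        target[hit[hit].index] += 1
        by_type[r.event_type][hit[hit].index] += 1

    burden = pd.DataFrame({"over_count": over, "under_count": under})
    burden["total"] = burden["over_count"] + burden["under_count"]
    for t in event_types:
        burden[f"type:{t}"] = by_type[t]
    if phenotype is not None:
        burden.insert(0, "group", phenotype.reindex(burden.index))
    burden.index.name = "sample"
    return burden


def waterfall_data(
    junction: JunctionKey,
    matrix: NormalizedJunctionMatrix,
    phenotype: pd.Series,
) -> tuple[pd.DataFrame, int]:
    """Per-sample normalized expression of one junction, sorted descending.

    Undefined cells are omitted; the omission count is returned alongside.
    Ties preserve input sample order (stable sort), so the output is
    deterministic and directly plottable as a tumor/normal-colored bar chart.
    """
    key = tuple(junction)
    if key not in matrix.values.index:
        raise KeyError(f"junction {junction} not present in the normalized matrix")
    row = matrix.values.loc[key]
    omitted = int(row.isna().sum())
    data = pd.DataFrame(
        {
            "sample": row.index,
            "group": phenotype.reindex(row.index).to_numpy(),
            "value": row.to_numpy(dtype=float),
        }
    ).dropna(subset=["value"])
    data = data.sort_values("value", ascending=False, kind="stable").reset_index(drop=True)
    return data, omitted


def plot_waterfall(
    junction: JunctionKey,
    matrix: NormalizedJunctionMatrix,
    phenotype: pd.Series,
    path: Optional[str] = None,
):
    """Render the waterfall bar chart for one junction (headless backend)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    data, _ = waterfall_data(junction, matrix, phenotype)
    colors = np.where(data["group"] == "tumor", "firebrick", "steelblue")
    fig, ax = plt.subplots(figsize=(max(4, 0.12 * len(data)), 3.2))
    ax.bar(np.arange(len(data)), data["value"], color=colors, width=0.9)
    ax.set_ylabel("normalized junction expression")
    ax.set_xticks([])
    ax.set_title(
        f"{junction.chromosome}:{junction.intron_start}-{junction.intron_end} ({junction.strand})"
    )
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
        return None
    return fig
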