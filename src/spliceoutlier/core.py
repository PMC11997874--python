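"""Core domain types shared across the pipeline.

The in-memory containers are thin wrappers around pandas objects: junction
matrices carry a 4-level MultiIndex (chromosome, intron_start, intron_end,
strand) so that identical junctions observed in different samples collapse to
one row, and per-sample columns stay aligned between the raw-count, normalized
and outlier-call views of the cohort.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, NamedTuple, Optional

import numpy as np
import pandas as pd

#: strand token for junctions whose strand STAR could not determine
STRAND_UNDETERMINED = "."

JUNCTION_INDEX_NAMES = ("chromosome", "intron_start", "intron_end", "strand")


class JunctionKey(NamedTuple):
    """Genomic identity of one splice junction.

    Coordinates are 1-based inclusive over the *intron*: ``intron_start`` is
    the first intronic base and ``intron_end`` the last, which is the native
    convention of STAR's ``SJ.out.tab``.
    """

    chromosome: str
    intron_start: int
    intron_end: int
    strand: str  # "+", "-" or STRAND_UNDETERMINED

    def validate(self) -> "JunctionKey":
        if not self.chromosome:
            raise ValueError("junction chromosome must be non-empty")
        if self.intron_start > self.intron_end:
            raise ValueError(
                f"junction intron_start {self.intron_start} > intron_end {self.intron_end}"
            )
        if self.strand not in ("+", "-", STRAND_UNDETERMINED):
            raise ValueError(f"invalid strand {self.strand!r}")
        return self


def junction_index(junctions: Iterable[JunctionKey]) -> pd.MultiIndex:
    """Build the canonical junction MultiIndex from JunctionKeys."""
    keys = list(junctions)
    if not keys:
        return pd.MultiIndex.from_arrays([[], [], [], []], names=JUNCTION_INDEX_NAMES)
    return pd.MultiIndex.from_tuples(keys, names=JUNCTION_INDEX_NAMES)


def index_to_junctions(index: pd.Index) -> list[JunctionKey]:
    return [JunctionKey(*tup) for tup in index]


def sort_junctions(junctions: Iterable[JunctionKey]) -> list[JunctionKey]:
    """Deterministic cohort order: (chromosome, start, end, strand)."""
    return sorted(junctions, key=lambda j: (j.chromosome, j.intron_start, j.intron_end, j.strand))


@dataclass
class JunctionCountMatrix:
    """Raw junction read counts (junctions x samples) plus library sizes.

    ``counts`` is integer-valued with the junction MultiIndex as row index;
    a junction absent from one sample's file carries count 0 there.
    ``library_sizes`` holds each sample's total uniquely mapped reads.
    """

    counts: pd.DataFrame
    library_sizes: pd.Series

    def __post_init__(self) -> None:
        self.counts.index.names = list(JUNCTION_INDEX_NAMES)
        self.library_sizes = self.library_sizes.reindex(self.counts.columns)
        self.validate()

    def validate(self) -> None:
        if self.library_sizes.isna().any():
            missing = self.library_sizes.index[self.library_sizes.isna()].tolist()
            raise ValueError(f"missing library sizes for samples {missing}")
        if (self.library_sizes <= 0).any():
            bad = self.library_sizes.index[self.library_sizes <= 0].tolist()
            raise ValueError(f"non-positive library sizes for samples {bad}")
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("negative junction counts")

    @property
    def samples(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def junctions(self) -> list[JunctionKey]:
        return index_to_junctions(self.counts.index)


@dataclass
class NormalizedJunctionMatrix:
    """Junction expression after library-size and gene-expression normalization.

    ``values`` uses NaN as the "undefined" sentinel (host gene with zero
    normalized expression in that sample); ``gene`` maps each junction row to
    its host gene identifier (NaN when unmapped, in which case the row was
    carried through un-normalized and ``no_gene`` is set).
    """

    values: pd.DataFrame
    gene: pd.Series
    no_gene: pd.Series

    def __post_init__(self) -> None:
        self.values.index.names = list(JUNCTION_INDEX_NAMES)
        self.gene = self.gene.reindex(self.values.index)
        self.no_gene = self.no_gene.reindex(self.values.index).fillna(True).astype(bool)
        arr = self.values.to_numpy(dtype=float)
        if np.isinf(arr).any() or (np.nan_to_num(arr) < 0).any():
            raise ValueError("normalized junction values must be finite and >= 0")

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)

    @property
    def junctions(self) -> list[JunctionKey]:
        return index_to_junctions(self.values.index)


# outlier-call cell labels
CALL_OVER = "over"
CALL_UNDER = "under"
CALL_NONE = "none"
CALL_UNDEFINED = "undefined"


@dataclass
class OutlierCallMatrix:
    """Per-cell outlier labels plus the normal-reference summary per junction.

    ``calls`` holds one of {over, under, none, undefined} per (junction,
    sample); ``reference`` has columns median / lower_fence / upper_fence
    computed from the full normal panel (NaN where the junction had fewer than
    two defined normal values).
    """

    calls: pd.DataFrame
    reference: pd.DataFrame

    @property
    def samples(self) -> list[str]:
        return list(self.calls.columns)


@dataclass(frozen=True)
class EventResult:
    """Per-(junction, direction) statistical record."""

    junction: JunctionKey
    gene: Optional[str]
    event_type: str
    direction: str  # CALL_OVER or CALL_UNDER
    tumor_outliers: int
    normal_outliers: int
    tumor_n: int
    normal_n: int
    p_value: float
    fdr: float
    outlier_samples: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.tumor_outliers > self.tumor_n or self.normal_outliers > self.normal_n:
            raise ValueError("outlier counts exceed group sizes")


@dataclass(frozen=True)
class Transcript:
    transcript_id: str
    gene_id: str
    chromosome: str
    strand: str
    exons: tuple[tuple[int, int], ...]  # 1-based inclusive, sorted, non-overlapping

    def __post_init__(self) -> None:
        prev_end = -np.inf
        for start, end in self.exons:
            if start > end:
                raise ValueError(f"exon start {start} > end {end} in {self.transcript_id}")
            if start <= prev_end:
                raise ValueError(f"overlapping/unsorted exons in {self.transcript_id}")
            prev_end = end

    @property
    def introns(self) -> tuple[tuple[int, int], ...]:
        """Gaps between consecutive exons as (intron_start, intron_end)."""
        return tuple(
            (self.exons[i][1] + 1, self.exons[i + 1][0] - 1) for i in range(len(self.exons) - 1)
        )

    def intron_keys(self) -> tuple[JunctionKey, ...]:
        return tuple(
            JunctionKey(self.chromosome, s, e, self.strand) for s, e in self.introns
        )


@dataclass
class Gene:
    gene_id: str
    name: str
    chromosome: str
    strand: str
    transcripts: dict[str, Transcript] = field(default_factory=dict)

    @property
    def span(self) -> tuple[int, int]:
        starts = [t.exons[0][0] for t in self.transcripts.values()]
        ends = [t.exons[-1][1] for t in self.transcripts.values()]
        return min(starts), max(ends)

    @property
    def introns(self) -> frozenset[tuple[int, int]]:
        """Annotated introns of any transcript (shared introns stored once)."""
        out: set[tuple[int, int]] = set()
        for t in self.transcripts.values():
            out.update(t.introns)
        return frozenset(out)

    @property
    def intron_starts(self) -> frozenset[int]:
        return frozenset(s for s, _ in self.introns)

    @property
    def intron_ends(self) -> frozenset[int]:
        return frozenset(e for _, e in self.introns)

    @property
    def exons(self) -> frozenset[tuple[int, int]]:
        out: set[tuple[int, int]] = set()
        for t in self.transcripts.values():
            out.update(t.exons)
        return frozenset(out)


@dataclass
class GeneModel:
    """Exon models grouped by gene, with derived annotated splice sites."""

    genes: dict[str, Gene] = field(default_factory=dict)

    def add_transcript(self, transcript: Transcript, gene_name: Optional[str] = None) -> None:
        gene = self.genes.get(transcript.gene_id)
        if gene is None:
            gene = Gene(
                gene_id=transcript.gene_id,
                name=gene_name or transcript.gene_id,
                chromosome=transcript.chromosome,
                strand=transcript.strand,
            )
            self.genes[transcript.gene_id] = gene
        gene.transcripts[transcript.transcript_id] = transcript

    def transcripts(self) -> Iterable[Transcript]:
        for gene in self.genes.values():
            yield from gene.transcripts.values()

    def annotated_introns(self) -> frozenset[JunctionKey]:
        out: set[JunctionKey] = set()
        for t in self.transcripts():
            out.update(t.intron_keys())
        return frozenset(out)
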