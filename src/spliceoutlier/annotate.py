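"""Gene mapping and splicing event classification for junctions.

A junction is assigned to the gene whose span contains its intron interval
(strand-aware unless the junction strand is undetermined), then classified
against that gene's exon models into one of: annotated, skipping, deletion,
insertion. The rules are boundary-based, matching the junction-centric data
model — no read-level exon counts are available:

* annotated — the junction equals an annotated intron of some transcript;
* skipping  — both boundaries coincide with annotated splice sites of one
  transcript and the intron fully contains at least one exon of it;
* deletion  — at least one boundary falls strictly inside an annotated exon
  (part of the exon body is spliced out);
* insertion — the remaining novel junctions, whose boundaries lie in
  annotated intronic sequence (intronic sequence is retained as novel exonic
  material relative to the annotated form).

The checks are applied in that order and the first match wins, so every
mapped junction gets exactly one label.
"""

from __future__ import annotations

import bisect
import logging
from typing import Iterable, Optional

import pandas as pd

from .core import Gene, GeneModel, JunctionKey, STRAND_UNDETERMINED

logger = logging.getLogger(__name__)

EVENT_ANNOTATED = "annotated"
EVENT_SKIPPING = "skipping"
EVENT_DELETION = "deletion"
EVENT_INSERTION = "insertion"
EVENT_UNMAPPED = "unmapped"


class _GeneIndex:
    """Per-chromosome interval lookup over gene spans."""

    def __init__(self, model: GeneModel):
        by_chrom: dict[str, list[tuple[int, int, str]]] = {}
        for gene in model.genes.values():
            start, end = gene.span
            by_chrom.setdefault(gene.chromosome, []).append((start, end, gene.gene_id))
        self._by_chrom = {c: sorted(v) for c, v in by_chrom.items()}
        self._starts = {c: [iv[0] for iv in v] for c, v in self._by_chrom.items()}

    def containing(self, junction: JunctionKey) -> list[str]:
        intervals = self._by_chrom.get(junction.chromosome, [])
        starts = self._starts.get(junction.chromosome, [])
        hi = bisect.bisect_right(starts, junction.intron_start)
        return [
            gene_id
            for start, end, gene_id in intervals[:hi]
            if end >= junction.intron_end
        ]


def _strand_compatible(junction: JunctionKey, gene: Gene) -> bool:
    return junction.strand == STRAND_UNDETERMINED or junction.strand == gene.strand


def _shares_splice_site(junction: JunctionKey, gene: Gene) -> bool:
    return (
        junction.intron_start in gene.intron_starts
        or junction.intron_end in gene.intron_ends
    )


def map_junction_to_gene(
    junction: JunctionKey,
    model: GeneModel,
    index: Optional[_GeneIndex] = None,
    tie_break: bool = True,
) -> Optional[str]:
    """Return the host gene of a junction, or None if no gene contains it.

    When several overlapping genes contain the intron interval, the gene
    sharing an annotated splice site with the junction wins, then the one
    with the smaller span, then the lexicographically smaller identifier.
    With ``tie_break=False`` an ambiguous junction maps to None.
    """
    index = index or _GeneIndex(model)
    candidates = [
        model.genes[g]
        for g in index.containing(junction)
        if _strand_compatible(junction, model.genes[g])
    ]
    if not candidates:
        return None
    if len(candidates) == 1:
        return candidates[0].gene_id
    if not tie_break:
        logger.warning("junction %s maps to %d genes; unresolved", junction, len(candidates))
        return None
    sharing = [g for g in candidates if _shares_splice_site(junction, g)]
    pool = sharing or candidates
    pool = sorted(pool, key=lambda g: (g.span[1] - g.span[0], g.gene_id))
    return pool[0].gene_id


def map_junctions_to_genes(
    junctions: Iterable[JunctionKey], model: GeneModel, tie_break: bool = True
) -> pd.Series:
    """Vectorized wrapper: junction MultiIndex -> host gene (NaN if unmapped)."""
    index = _GeneIndex(model)
    keys = list(junctions)
    genes = [map_junction_to_gene(j, model, index=index, tie_break=tie_break) for j in keys]
    return pd.Series(
        genes,
        index=pd.MultiIndex.from_tuples(keys, names=JunctionKey._fields),
        dtype=object,
        name="gene",
    )


def classify_event(
    junction: JunctionKey, model: GeneModel, gene_id: Optional[str]
) -> str:
    """Classify one junction against its host gene's exon models."""
    if gene_id is None or gene_id not in model.genes:
        return EVENT_UNMAPPED
    gene = model.genes[gene_id]
    s, e = junction.intron_start, junction.intron_end

    if (s, e) in gene.introns:
        return EVENT_ANNOTATED

    for tx in gene.transcripts.values():
        tx_starts = {i_s for i_s, _ in tx.introns}
        tx_ends = {i_e for _, i_e in tx.introns}
        if s in tx_starts and e in tx_ends:
            if any(ex_s >= s and ex_e <= e for ex_s, ex_e in tx.exons):
                return EVENT_SKIPPING

    for ex_s, ex_e in gene.exons:
        if ex_s < s < ex_e or ex_s < e < ex_e:
            return EVENT_DELETION

    return EVENT_INSERTION


def classify_events(
    junctions: Iterable[JunctionKey], gene_map: pd.Series, model: GeneModel
) -> pd.Series:
    keys = list(junctions)
    labels = []
    for j in keys:
        gene_id = gene_map.get(tuple(j))
        if gene_id is not None and pd.isna(gene_id):
            gene_id = None
        labels.append(classify_event(j, model, gene_id))
    return pd.Series(
        labels,
        index=pd.MultiIndex.from_tuples(keys, names=JunctionKey._fields),
        name="event_type",
    )
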