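"""Readers and writers for every external format the pipeline touches.

Supported inputs: STAR ``SJ.out.tab`` (9-column TSV) and ``Log.final.out``,
RSEM ``*.genes.results``, TCGA/Firebrowse junction quantification tables,
GENCODE-style GTF annotation (parsed through gffutils), and a two-column
phenotype TSV. The results writer emits one row per (junction, direction)
with deterministic ordering so reruns are byte-identical.
"""

from __future__ import annotations

import logging
import re
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence, Union

import gffutils
import numpy as np
import pandas as pd

from .core import (
    CALL_OVER,
    CALL_UNDER,
    JUNCTION_INDEX_NAMES,
    STRAND_UNDETERMINED,
    EventResult,
    Gene,
    GeneModel,
    JunctionCountMatrix,
    JunctionKey,
    NormalizedJunctionMatrix,
    Transcript,
    junction_index,
    sort_junctions,
)

logger = logging.getLogger(__name__)

PathLike = Union[str, Path]

_STAR_STRAND = {0: STRAND_UNDETERMINED, 1: "+", 2: "-"}

#: groups accepted in phenotype files
TUMOR, NORMAL = "tumor", "normal"


class ParseError(ValueError):
    """Raised when an input file does not follow its declared layout."""


def read_star_sj(path: PathLike, min_unique_reads: int = 1) -> dict[JunctionKey, int]:
    """Parse one STAR SJ.out.tab file into {JunctionKey: unique-read count}.

    Only column 7 (uniquely mapping reads) is used; junctions below
    ``min_unique_reads`` are dropped. An empty file yields an empty map.
    """
    out: dict[JunctionKey, int] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 9:
                raise ParseError(
                    f"{path}: line {lineno}: expected >=9 tab-separated columns, got {len(fields)}"
                )
            try:
                start, end = int(fields[1]), int(fields[2])
                strand_code = int(fields[3])
                unique = int(fields[6])
            except ValueError as exc:
                raise ParseError(f"{path}: line {lineno}: non-integer field ({exc})") from None
            if strand_code not in _STAR_STRAND:
                raise ParseError(f"{path}: line {lineno}: invalid strand code {strand_code}")
            if unique < min_unique_reads:
                continue
            key = JunctionKey(fields[0], start, end, _STAR_STRAND[strand_code]).validate()
            out[key] = unique
    return out


def assemble_junction_counts(
    sj_maps: Mapping[str, Mapping[JunctionKey, int]],
    library_sizes: pd.Series,
) -> JunctionCountMatrix:
    """Union per-sample junction maps into one cohort count matrix.

    A junction absent from a sample's map gets count 0 there; rows are sorted
    by (chromosome, start, end, strand) so assembly is order-independent up to
    column permutation.
    """
    all_keys = sort_junctions({k for m in sj_maps.values() for k in m})
    samples = list(sj_maps)
    data = np.zeros((len(all_keys), len(samples)), dtype=np.int64)
    pos = {k: i for i, k in enumerate(all_keys)}
    for j, sample in enumerate(samples):
        for key, count in sj_maps[sample].items():
            data[pos[key], j] = count
    counts = pd.DataFrame(data, index=junction_index(all_keys), columns=samples)
    return JunctionCountMatrix(counts=counts, library_sizes=library_sizes)


_LIBSIZE_LABEL = "Uniquely mapped reads number"


def read_library_sizes(paths: Mapping[str, PathLike]) -> pd.Series:
    """Extract total uniquely mapped reads from STAR Log.final.out files."""
    sizes: dict[str, int] = {}
    for sample, path in paths.items():
        found: Optional[int] = None
        with open(path) as fh:
            for line in fh:
                if _LIBSIZE_LABEL in line:
                    value = int(line.split("|")[-1].strip())
                    if found is None:
                        found = value
                    else:
                        logger.warning(
                            "%s: duplicate '%s' line; first occurrence (%d) used",
                            path, _LIBSIZE_LABEL, found,
                        )
                        break
        if found is None:
            raise ParseError(f"{path}: no line containing '{_LIBSIZE_LABEL}'")
        sizes[sample] = found
    return pd.Series(sizes, name="library_size")


_VERSION_SUFFIX = re.compile(r"\.\d+$")


def strip_gene_version(gene_id: str) -> str:
    return _VERSION_SUFFIX.sub("", gene_id)


def read_rsem_genes(
    paths: Mapping[str, PathLike], strip_versions: bool = True
) -> pd.DataFrame:
    """Assemble RSEM *.genes.results expected counts into genes x samples.

    Inconsistent gene sets across samples are outer-joined with 0 fill (and a
    warning); gene identifier version suffixes are stripped by default.
    """
    columns: dict[str, pd.Series] = {}
    gene_sets: set[frozenset[str]] = set()
    for sample, path in paths.items():
        table = pd.read_csv(path, sep="\t")
        for needed in ("gene_id", "expected_count"):
            if needed not in table.columns:
                raise ParseError(f"{path}: missing required column '{needed}'")
        ids = table["gene_id"].astype(str)
        if strip_versions:
            ids = ids.map(strip_gene_version)
        columns[sample] = pd.Series(table["expected_count"].to_numpy(float), index=ids)
        gene_sets.add(frozenset(ids))
    if len(gene_sets) > 1:
        logger.warning("inconsistent gene sets across RSEM files; outer union with 0 fill")
    expr = pd.DataFrame(columns).fillna(0.0)
    expr.index.name = "gene_id"
    return expr.sort_index()


_FIREBROWSE_TOKEN = re.compile(r"^([^:]+):(\d+):([+-.])$")


def _parse_firebrowse_id(token: str) -> JunctionKey:
    parts = token.split(",")
    if len(parts) != 2:
        raise ParseError(f"unparsable Firebrowse junction id: {token!r}")
    sites = []
    for part in parts:
        m = _FIREBROWSE_TOKEN.match(part.strip())
        if m is None:
            raise ParseError(f"unparsable Firebrowse junction id: {token!r}")
        sites.append((m.group(1), int(m.group(2)), m.group(3)))
    (chrom_a, pos_a, strand_a), (chrom_b, pos_b, strand_b) = sites
    if chrom_a != chrom_b or strand_a != strand_b:
        raise ParseError(f"donor/acceptor mismatch in Firebrowse junction id: {token!r}")
    # positions are the flanking exon boundaries; +1/-1 converts to the intron
    return JunctionKey(chrom_a, min(pos_a, pos_b) + 1, max(pos_a, pos_b) - 1, strand_a).validate()


def read_firebrowse_junctions(
    path: PathLike, library_sizes: Optional[pd.Series] = None
) -> JunctionCountMatrix:
    """Read a TCGA/Firebrowse junction quantification table.

    The first column encodes each junction as
    ``chrom:pos:strand,chrom:pos:strand`` (last base of the upstream exon,
    first base of the downstream exon). Library sizes default to per-sample
    column sums; an all-zero sample falls back to size 1 with a warning.
    """
    table = pd.read_csv(path, sep="\t", index_col=0)
    keys = [_parse_firebrowse_id(str(tok)) for tok in table.index]
    counts = pd.DataFrame(
        np.rint(table.to_numpy(float)).astype(np.int64),
        index=junction_index(keys),
        columns=[str(c) for c in table.columns],
    )
    order = np.lexsort(
        (
            counts.index.get_level_values(3),
            counts.index.get_level_values(2),
            counts.index.get_level_values(1),
            counts.index.get_level_values(0),
        )
    )
    counts = counts.iloc[order]
    if library_sizes is None:
        library_sizes = counts.sum(axis=0)
        zero = library_sizes == 0
        if zero.any():
            logger.warning(
                "samples with all-zero junction counts %s: library size fallback 1",
                library_sizes.index[zero].tolist(),
            )
            library_sizes[zero] = 1
    return JunctionCountMatrix(counts=counts, library_sizes=library_sizes)


def read_phenotype(path: PathLike) -> pd.Series:
    """Read the two-column (sample, tumor|normal) phenotype TSV."""
    assignment: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != 2:
                raise ParseError(f"{path}: line {lineno}: expected 2 columns")
            sample, group = fields[0].strip(), fields[1].strip().lower()
            if lineno == 1 and group in ("group", "phenotype", "condition", "class"):
                continue  # header line
            if group not in (TUMOR, NORMAL):
                raise ParseError(
                    f"{path}: line {lineno}: group must be '{TUMOR}' or '{NORMAL}', got {group!r}"
                )
            if sample in assignment:
                logger.warning("%s: duplicate sample %s; first occurrence used", path, sample)
                continue
            assignment[sample] = group
    return pd.Series(assignment, name="group")


def write_phenotype(phenotype: pd.Series, path: PathLike) -> None:
    with open(path, "w") as fh:
        fh.write("sample\tgroup\n")
        for sample, group in phenotype.items():
            fh.write(f"{sample}\t{group}\n")


def validate_phenotype(phenotype: pd.Series, samples: Sequence[str]) -> pd.Series:
    """Check coverage and group sizes; returns the phenotype restricted to samples."""
    missing = [s for s in samples if s not in phenotype.index]
    if missing:
        raise ValueError(f"samples without phenotype assignment: {missing}")
    pheno = phenotype.reindex(samples)
    n_normal = int((pheno == NORMAL).sum())
    n_tumor = int((pheno == TUMOR).sum())
    if n_normal < 2 or n_tumor < 1:
        raise ValueError(
            f"need >=2 normal and >=1 tumor samples, got {n_normal} normal / {n_tumor} tumor"
        )
    return pheno


def read_gene_model(path: PathLike) -> GeneModel:
    """Load exon models from a GTF (GENCODE dialect) via gffutils.

    Exon features lacking a transcript_id are skipped with a warning.
    """
    db = gffutils.create_db(
        str(path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        disable_infer_genes=True,
        disable_infer_transcripts=True,
    )
    grouped: dict[str, dict] = {}
    for feat in db.features_of_type("exon"):
        tx_ids = feat.attributes.get("transcript_id")
        if not tx_ids:
            logger.warning("exon at %s:%d-%d without transcript_id skipped", feat.seqid, feat.start, feat.end)
            continue
        gene_ids = feat.attributes.get("gene_id", [tx_ids[0]])
        names = feat.attributes.get("gene_name", gene_ids)
        info = grouped.setdefault(
            tx_ids[0],
            {
                "gene_id": gene_ids[0],
                "gene_name": names[0],
                "chromosome": feat.seqid,
                "strand": feat.strand if feat.strand in ("+", "-") else STRAND_UNDETERMINED,
                "exons": [],
            },
        )
        info["exons"].append((feat.start, feat.end))
    model = GeneModel()
    for tx_id, info in grouped.items():
        exons = tuple(sorted(info["exons"]))
        model.add_transcript(
            Transcript(
                transcript_id=tx_id,
                gene_id=info["gene_id"],
                chromosome=info["chromosome"],
                strand=info["strand"],
                exons=exons,
            ),
            gene_name=info["gene_name"],
        )
    return model


def write_gtf(model: GeneModel, path: PathLike, source: str = "spliceoutlier") -> None:
    """Serialize a GeneModel as a GENCODE-style GTF (gene/transcript/exon rows)."""
    with open(path, "w") as fh:
        for gene_id in sorted(model.genes):
            gene = model.genes[gene_id]
            span = gene.span
            attrs = f'gene_id "{gene.gene_id}"; gene_name "{gene.name}";'
            fh.write(
                f"{gene.chromosome}\t{source}\tgene\t{span[0]}\t{span[1]}\t.\t{gene.strand}\t.\t{attrs}\n"
            )
            for tx_id in sorted(gene.transcripts):
                tx = gene.transcripts[tx_id]
                tx_attrs = attrs + f' transcript_id "{tx.transcript_id}";'
                fh.write(
                    f"{tx.chromosome}\t{source}\ttranscript\t{tx.exons[0][0]}\t{tx.exons[-1][1]}"
                    f"\t.\t{tx.strand}\t.\t{tx_attrs}\n"
                )
                for start, end in tx.exons:
                    fh.write(
                        f"{tx.chromosome}\t{source}\texon\t{start}\t{end}\t.\t{tx.strand}\t.\t{tx_attrs}\n"
                    )


def write_expression_tsv(expr: pd.DataFrame, path: PathLike) -> None:
    expr.to_csv(path, sep="\t", index_label="gene_id", float_format="%.17g")


def read_expression_tsv(path: PathLike) -> pd.DataFrame:
    return pd.read_csv(
        path, sep="\t", index_col="gene_id", float_precision="round_trip"
    ).astype(float)


def write_sj_tab(sj_map: Mapping[JunctionKey, int], path: PathLike) -> None:
    """Write a map of junction counts in STAR SJ.out.tab layout."""
    strand_code = {STRAND_UNDETERMINED: 0, "+": 1, "-": 2}
    with open(path, "w") as fh:
        for key in sort_junctions(sj_map):
            fh.write(
                f"{key.chromosome}\t{key.intron_start}\t{key.intron_end}"
                f"\t{strand_code[key.strand]}\t0\t1\t{sj_map[key]}\t0\t50\n"
            )


def write_log_final(library_size: int, path: PathLike) -> None:
    """Write a minimal STAR Log.final.out carrying the library size."""
    with open(path, "w") as fh:
        fh.write(f"                   {_LIBSIZE_LABEL} |\t{library_size}\n")


_RESULT_FIXED_COLUMNS = [
    "chromosome",
    "intron_start",
    "intron_end",
    "strand",
    "gene",
    "event_type",
    "direction",
    "tumor_outlier_count",
    "normal_outlier_count",
    "tumor_n",
    "normal_n",
    "p_value",
    "fdr",
]
_FLAG_PREFIX = "outlier:"


def _result_sort_key(r: EventResult):
    return (
        r.junction.chromosome,
        r.junction.intron_start,
        r.junction.intron_end,
        r.junction.strand,
        r.direction,
    )


def write_results(
    results: Sequence[EventResult], path: PathLike, samples: Optional[Sequence[str]] = None
) -> None:
    """Write the per-event results TSV (one row per junction and direction).

    Per-sample outlier flags appear as 0/1 columns prefixed ``outlier:``;
    floats are serialized with full precision so a round-trip read reproduces
    the EventResult list exactly.
    """
    if samples is None:
        seen: list[str] = []
        for r in results:
            for s in r.outlier_samples:
                if s not in seen:
                    seen.append(s)
        samples = seen
    with open(path, "w") as fh:
        header = _RESULT_FIXED_COLUMNS + [f"{_FLAG_PREFIX}{s}" for s in samples]
        fh.write("\t".join(header) + "\n")
        for r in sorted(results, key=_result_sort_key):
            flags = ["1" if s in r.outlier_samples else "0" for s in samples]
            row = [
                r.junction.chromosome,
                str(r.junction.intron_start),
                str(r.junction.intron_end),
                r.junction.strand,
                r.gene if r.gene is not None else "NA",
                r.event_type,
                r.direction,
                str(r.tumor_outliers),
                str(r.normal_outliers),
                str(r.tumor_n),
                str(r.normal_n),
                format(r.p_value, ".17g"),
                format(r.fdr, ".17g"),
            ]
            fh.write("\t".join(row + flags) + "\n")


def read_results(path: PathLike) -> list[EventResult]:
    table = pd.read_csv(
        path,
        sep="\t",
        dtype={"chromosome": str, "strand": str, "gene": str},
        float_precision="round_trip",
    )
    flag_cols = [c for c in table.columns if c.startswith(_FLAG_PREFIX)]
    samples = [c[len(_FLAG_PREFIX):] for c in flag_cols]
    out: list[EventResult] = []
    for _, row in table.iterrows():
        outliers = tuple(s for s, c in zip(samples, flag_cols) if row[c] == 1)
        gene = row["gene"]
        out.append(
            EventResult(
                junction=JunctionKey(
                    row["chromosome"], int(row["intron_start"]), int(row["intron_end"]), row["strand"]
                ),
                gene=None if pd.isna(gene) or gene == "NA" else str(gene),
                event_type=str(row["event_type"]),
                direction=str(row["direction"]),
                tumor_outliers=int(row["tumor_outlier_count"]),
                normal_outliers=int(row["normal_outlier_count"]),
                tumor_n=int(row["tumor_n"]),
                normal_n=int(row["normal_n"]),
                p_value=float(row["p_value"]),
                fdr=float(row["fdr"]),
                outlier_samples=outliers,
            )
        )
    return out


def write_normalized_matrix(matrix: NormalizedJunctionMatrix, path: PathLike) -> None:
    """Export normalized junction expression; undefined cells written as NA."""
    out = matrix.values.copy()
    out.insert(0, "gene", matrix.gene.fillna("NA"))
    out.reset_index().to_csv(path, sep="\t", index=False, na_rep="NA", float_format="%.17g")


def read_normalized_matrix(path: PathLike) -> NormalizedJunctionMatrix:
    table = pd.read_csv(
        path, sep="\t", dtype={"chromosome": str, "strand": str, "gene": str}
    )
    table = table.set_index(list(JUNCTION_INDEX_NAMES))
    gene = table.pop("gene").replace("NA", np.nan)
    return NormalizedJunctionMatrix(
        values=table.astype(float), gene=gene, no_gene=gene.isna()
    )
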