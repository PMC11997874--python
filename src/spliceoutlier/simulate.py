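"""Synthetic tumor/normal cohorts with ground truth, at the junction-count level.

The generator emulates the statistical design of a read-level splicing
benchmark without synthesizing reads: ~1000 single-canonical-transcript genes
laid out on autosomes, of which 200 carry an alternative transcript that
skips one internal exon. Every transcript receives a per-sample expression
multiplier around a baseline of 600 reads — canonical transcripts uniform
1-2x in all samples; alternative transcripts 1x in normals, uniform 1-2x in
half the tumors and uniform 4-5x in the other half, the latter constituting
the ground-truth over-expressed events. Junction counts are noise draws
(Poisson by default) around the summed expected reads of the transcripts
containing each junction, and gene expression is simulated the same way at
the gene level, so the full detection pipeline runs on the output exactly as
it would on STAR/RSEM-derived data.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import io as fio
from .core import (
    GeneModel,
    JunctionCountMatrix,
    JunctionKey,
    Transcript,
    junction_index,
    sort_junctions,
)

NOISE_POISSON = "poisson"
NOISE_NEGATIVE_BINOMIAL = "negative_binomial"
NOISE_NONE = "none"


@dataclass(frozen=True)
class SimConfig:
    """Cohort design parameters (defaults are the benchmark conditions)."""

    n_genes: int = 1000
    n_alt_genes: int = 200
    n_normals: int = 20
    n_tumors: int = 40
    n_tumors_high: int = 20
    baseline_reads: int = 600
    canonical_mult_range: tuple[float, float] = (1.0, 2.0)
    alt_normal_mult: float = 1.0
    alt_tumor_low_range: tuple[float, float] = (1.0, 2.0)
    alt_tumor_high_range: tuple[float, float] = (4.0, 5.0)
    exons_per_transcript_range: tuple[int, int] = (3, 8)
    exon_length_range: tuple[int, int] = (100, 300)
    intron_length_range: tuple[int, int] = (500, 2000)
    genes_per_chromosome: int = 50
    intergenic_gap: int = 10000
    noise: str = NOISE_POISSON
    nb_dispersion: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_alt_genes > self.n_genes:
            raise ValueError("n_alt_genes must be <= n_genes")
        if self.n_tumors_high > self.n_tumors:
            raise ValueError("n_tumors_high must be <= n_tumors")
        if self.exons_per_transcript_range[0] < 3:
            raise ValueError("alternative transcripts need >= 3 exons to skip one")
        if self.noise not in (NOISE_POISSON, NOISE_NEGATIVE_BINOMIAL, NOISE_NONE):
            raise ValueError(f"unknown noise model {self.noise!r}")


@dataclass
class SimTruth:
    """Ground truth: which genes carry a true alternative event, and where."""

    alt_genes: frozenset[str]
    alt_junctions: dict[str, frozenset[JunctionKey]]
    high_tumors: tuple[str, ...] = ()
    multipliers: Optional[pd.DataFrame] = None  # transcripts x samples


@dataclass
class SimulatedData:
    """One synthetic cohort ready for the detection pipeline."""

    counts: JunctionCountMatrix
    gene_expression: pd.DataFrame
    phenotype: pd.Series
    truth: SimTruth
    model: GeneModel
    config: SimConfig


def build_gene_models(config: SimConfig, rng: np.random.Generator) -> tuple[GeneModel, SimTruth]:
    """Lay out synthetic genes with canonical (and, for some, skipping) transcripts."""
    model = GeneModel()
    alt_idx = set(rng.choice(config.n_genes, size=config.n_alt_genes, replace=False).tolist())
    alt_genes: set[str] = set()
    alt_junctions: dict[str, frozenset[JunctionKey]] = {}

    cursor = 0
    chrom_no = 0
    for i in range(config.n_genes):
        if i % config.genes_per_chromosome == 0:
            chrom_no += 1
            cursor = config.intergenic_gap
        chrom = f"chr{chrom_no}"
        gene_id = f"SIMG{i:05d}"
        n_exons = int(
            rng.integers(
                config.exons_per_transcript_range[0], config.exons_per_transcript_range[1] + 1
            )
        )
        strand = "+" if rng.random() < 0.5 else "-"
        exons: list[tuple[int, int]] = []
        pos = cursor
        for _ in range(n_exons):
            length = int(rng.integers(*config.exon_length_range))
            exons.append((pos, pos + length - 1))
            pos += length + int(rng.integers(*config.intron_length_range))
        cursor = exons[-1][1] + config.intergenic_gap

        canonical = Transcript(
            transcript_id=f"{gene_id}.C",
            gene_id=gene_id,
            chromosome=chrom,
            strand=strand,
            exons=tuple(exons),
        )
        model.add_transcript(canonical, gene_name=f"GENE{i:05d}")

        if i in alt_idx:
            skip = int(rng.integers(1, n_exons - 1))  # internal exon
            alt_exons = tuple(e for k, e in enumerate(exons) if k != skip)
            alt = Transcript(
                transcript_id=f"{gene_id}.A",
                gene_id=gene_id,
                chromosome=chrom,
                strand=strand,
                exons=alt_exons,
            )
            model.add_transcript(alt, gene_name=f"GENE{i:05d}")
            alt_genes.add(gene_id)
            novel = set(alt.intron_keys()) - set(canonical.intron_keys())
            alt_junctions[gene_id] = frozenset(novel)

    return model, SimTruth(alt_genes=frozenset(alt_genes), alt_junctions=alt_junctions)


def _noise_draw(expected: np.ndarray, config: SimConfig, rng: np.random.Generator) -> np.ndarray:
    if config.noise == NOISE_NONE:
        return np.rint(expected)
    if config.noise == NOISE_POISSON:
        return rng.poisson(expected).astype(float)
    # gamma-poisson mixture: var = mu + dispersion * mu^2
    shape = 1.0 / config.nb_dispersion
    lam = rng.gamma(shape, expected * config.nb_dispersion)
    return rng.poisson(lam).astype(float)


def simulate_counts(
    model: GeneModel,
    truth: SimTruth,
    config: SimConfig,
    rng: np.random.Generator,
) -> SimulatedData:
    """Draw per-sample expression multipliers and junction/gene counts."""
    normals = [f"Normal_{i + 1:02d}" for i in range(config.n_normals)]
    tumors = [f"Tumor_{i + 1:02d}" for i in range(config.n_tumors)]
    samples = normals + tumors
    high = sorted(
        rng.choice(tumors, size=config.n_tumors_high, replace=False).tolist()
    )
    low = [t for t in tumors if t not in set(high)]

    transcripts = sorted(model.transcripts(), key=lambda t: t.transcript_id)
    tx_ids = [t.transcript_id for t in transcripts]
    mult = pd.DataFrame(index=tx_ids, columns=samples, dtype=float)
    lo_c, hi_c = config.canonical_mult_range
    for t in transcripts:
        if t.transcript_id.endswith(".A"):
            row = np.empty(len(samples))
            row[: len(normals)] = config.alt_normal_mult
            for j, s in enumerate(tumors):
                if s in set(high):
                    row[len(normals) + j] = rng.uniform(*config.alt_tumor_high_range)
                else:
                    row[len(normals) + j] = rng.uniform(*config.alt_tumor_low_range)
        else:
            row = rng.uniform(lo_c, hi_c, size=len(samples))
        mult.loc[t.transcript_id] = row

    expected_tx = mult.to_numpy(dtype=float) * config.baseline_reads  # tx x samples
    tx_pos = {tx: k for k, tx in enumerate(tx_ids)}

    junction_tx: dict[JunctionKey, list[int]] = {}
    for t in transcripts:
        for key in t.intron_keys():
            junction_tx.setdefault(key, []).append(tx_pos[t.transcript_id])
    junctions = sort_junctions(junction_tx)
    expected_j = np.zeros((len(junctions), len(samples)))
    for r, key in enumerate(junctions):
        expected_j[r] = expected_tx[junction_tx[key]].sum(axis=0)

    counts = _noise_draw(expected_j, config, rng).astype(np.int64)

    gene_ids = sorted(model.genes)
    expected_g = np.zeros((len(gene_ids), len(samples)))
    for r, gid in enumerate(gene_ids):
        rows = [tx_pos[tid] for tid in model.genes[gid].transcripts]
        expected_g[r] = expected_tx[rows].sum(axis=0)
    gene_counts = _noise_draw(expected_g, config, rng)
    gene_expression = pd.DataFrame(gene_counts, index=gene_ids, columns=samples)
    gene_expression.index.name = "gene_id"

    library_sizes = pd.Series(
        np.maximum(gene_counts.sum(axis=0), 1.0).astype(np.int64), index=samples
    )
    jcm = JunctionCountMatrix(
        counts=pd.DataFrame(counts, index=junction_index(junctions), columns=samples),
        library_sizes=library_sizes,
    )
    phenotype = pd.Series(
        {**{s: fio.NORMAL for s in normals}, **{s: fio.TUMOR for s in tumors}}, name="group"
    )
    full_truth = SimTruth(
        alt_genes=truth.alt_genes,
        alt_junctions=truth.alt_junctions,
        high_tumors=tuple(high),
        multipliers=mult,
    )
    return SimulatedData(
        counts=jcm,
        gene_expression=gene_expression,
        phenotype=phenotype,
        truth=full_truth,
        model=model,
        config=config,
    )


def simulate_cohort(config: SimConfig) -> SimulatedData:
    """Seeded end-to-end generation: models, multipliers and count matrices."""
    rng = np.random.default_rng(config.seed)
    model, truth = build_gene_models(config, rng)
    return simulate_counts(model, truth, config, rng)


def export_fixture(data: SimulatedData, outdir) -> None:
    """Write the cohort as on-disk files that round-trip through the readers.

    Layout: annotation.gtf, sj/<sample>.SJ.out.tab, logs/<sample>.Log.final.out,
    gene_expression.tsv, phenotype.tsv, truth.json. Zero-count junctions are
    (correctly) absent from a sample's SJ file and restored as zeros on
    cohort assembly.
    """
    outdir = Path(outdir)
    (outdir / "sj").mkdir(parents=True, exist_ok=True)
    (outdir / "logs").mkdir(exist_ok=True)
    fio.write_gtf(data.model, outdir / "annotation.gtf")
    junctions = data.counts.junctions
    for sample in data.counts.samples:
        col = data.counts.counts[sample].to_numpy()
        sj_map = {j: int(c) for j, c in zip(junctions, col) if c > 0}
        fio.write_sj_tab(sj_map, outdir / "sj" / f"{sample}.SJ.out.tab")
        fio.write_log_final(
            int(data.counts.library_sizes[sample]), outdir / "logs" / f"{sample}.Log.final.out"
        )
    fio.write_expression_tsv(data.gene_expression, outdir / "gene_expression.tsv")
    fio.write_phenotype(data.phenotype, outdir / "phenotype.tsv")
    truth_obj = {
        "alt_genes": sorted(data.truth.alt_genes),
        "high_tumors": list(data.truth.high_tumors),
        "alt_junctions": {
            g: [list(j) for j in sorted(js)] for g, js in data.truth.alt_junctions.items()
        },
    }
    (outdir / "truth.json").write_text(json.dumps(truth_obj, indent=1) + "\n")


def load_fixture(outdir) -> tuple[JunctionCountMatrix, pd.DataFrame, pd.Series, dict]:
    """Read an exported fixture back through the standard readers."""
    outdir = Path(outdir)
    sj_dir = outdir / "sj"
    samples = sorted(p.name.replace(".SJ.out.tab", "") for p in sj_dir.glob("*.SJ.out.tab"))
    sj_maps = {s: fio.read_star_sj(sj_dir / f"{s}.SJ.out.tab") for s in samples}
    library_sizes = fio.read_library_sizes(
        {s: outdir / "logs" / f"{s}.Log.final.out" for s in samples}
    )
    jcm = fio.assemble_junction_counts(sj_maps, library_sizes)
    gene_expression = fio.read_expression_tsv(outdir / "gene_expression.tsv")
    phenotype = fio.read_phenotype(outdir / "phenotype.tsv")
    truth = json.loads((outdir / "truth.json").read_text())
    return jcm, gene_expression, phenotype, truth
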