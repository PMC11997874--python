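import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from spliceoutlier.core import (
    GeneModel,
    JunctionKey,
    NormalizedJunctionMatrix,
    Transcript,
    junction_index,
)
from spliceoutlier.simulate import SimConfig, simulate_cohort

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=40,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture
def three_exon_model():
    """One gene, one plus-strand transcript with exons 100-200/300-400/500-600."""
    model = GeneModel()
    model.add_transcript(
        Transcript(
            transcript_id="T1",
            gene_id="G1",
            chromosome="chr1",
            strand="+",
            exons=((100, 200), (300, 400), (500, 600)),
        )
    )
    return model


@pytest.fixture
def small_cohort():
    """Tiny seeded synthetic cohort for end-to-end tests."""
    return simulate_cohort(SimConfig(n_genes=30, n_alt_genes=8, seed=11))


def make_normalized(values, samples, chrom="chr1", genes=None):
    """Build a NormalizedJunctionMatrix from a plain array for unit tests."""
    values = np.asarray(values, dtype=float)
    keys = [JunctionKey(chrom, 100 * (i + 1), 100 * (i + 1) + 50, "+") for i in range(values.shape[0])]
    idx = junction_index(keys)
    gene = pd.Series(genes if genes is not None else [None] * len(keys), index=idx, dtype=object)
    return NormalizedJunctionMatrix(
        values=pd.DataFrame(values, index=idx, columns=samples),
        gene=gene,
        no_gene=gene.isna(),
    )


def make_phenotype(samples, groups):
    return pd.Series(dict(zip(samples, groups)), name="group")
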