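import numpy as np
import pandas as pd
import pytest

from methlink.diffmeth import MethCountTable
from methlink.regions import TranscriptModel, build_partition
from methlink.simulate import SimDesign, cpg_sites, make_genome


@pytest.fixture(scope="session")
def toy_design():
    return SimDesign(n_chroms=2, chrom_length=80_000, n_genes=6, seed=7)


@pytest.fixture(scope="session")
def toy_genome(toy_design):
    return make_genome(toy_design)


@pytest.fixture(scope="session")
def toy_models(toy_genome):
    return toy_genome[1]


@pytest.fixture(scope="session")
def toy_partition(toy_genome):
    genome, models = toy_genome
    return build_partition(models, {c: len(s) for c, s in genome.items()})


@pytest.fixture(scope="session")
def toy_sites(toy_genome):
    return cpg_sites(toy_genome[0])


@pytest.fixture
def plus_gene():
    """The hand-computed worked example: + strand, TSS=10001, two exons."""
    return TranscriptModel(
        gene_id="gA",
        transcript_id="gA.t1",
        chrom="chr1",
        strand="+",
        mrna_start=10_001,
        mrna_end=12_000,
        exons=((10_001, 10_500), (11_500, 12_000)),
    )


def make_meth_table(methylated, coverage, diets, tissue="gonads"):
    methylated = np.asarray(methylated)
    samples = pd.DataFrame(
        {
            "sample_id": [f"s{i}" for i in range(len(diets))],
            "tissue": tissue if isinstance(tissue, list) else [tissue] * len(diets),
            "diet": diets,
        }
    )
    sites = [f"chr1:{100 + 2 * i}" for i in range(methylated.shape[0])]
    return MethCountTable(sites, samples, methylated, np.asarray(coverage))


@pytest.fixture
def meth_table_factory():
    return make_meth_table
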