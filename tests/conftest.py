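import networkx as nx
import pytest

from cohortnet.io import Cohort
from cohortnet.networks import Interactome
from cohortnet.simulate import SimulationConfig
from cohortnet.variants import AnnotatedVariant


def make_variant(
    chrom="1",
    pos=1000,
    ref="A",
    alt="G",
    qual=100.0,
    depth=50,
    qd=10.0,
    fs=5.0,
    xamb=0,
    genotypes=None,
    gene="G0001",
    func="exonic",
    polyphen=0.99,
    sift=0.01,
    cadd=25.0,
    maf=0.01,
):
    return AnnotatedVariant(
        chrom=chrom, pos=pos, ref=ref, alt=alt, qual=qual, depth=depth, qd=qd,
        fs=fs, xamb=xamb, genotypes=genotypes or {}, gene=gene, func=func,
        polyphen2_hdiv=polyphen, sift=sift, cadd_phred=cadd, maf_ref=maf,
    )


def make_interactome(edges, default_score=900):
    g = nx.Graph()
    for e in edges:
        if len(e) == 3:
            u, v, s = e
        else:
            (u, v), s = e, default_score
        g.add_edge(u, v, score=s)
    return Interactome(g)


@pytest.fixture
def path_interactome():
    """Path graph a-b-c-d."""
    return make_interactome([("a", "b"), ("b", "c"), ("c", "d")])


@pytest.fixture
def tiny_cohort():
    samples = ["P1", "P2", "P3", "P4"]
    status = {"P1": "case", "P2": "case", "P3": "control", "P4": "control"}
    return Cohort(samples=samples, status=status)


@pytest.fixture
def small_sim_config():
    """Reduced simulation design for fast end-to-end unit tests."""
    return SimulationConfig(
        n_cases=12,
        n_controls=16,
        n_interactome_nodes=300,
        attachment_degree=3,
        module_size=8,
        background_variants_per_sample=40,
        rng_seed=7,
    )
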