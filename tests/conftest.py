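import networkx as nx
import numpy as np
import pytest

from epinet.genotype_io import GenotypeDataset


def make_dataset(genotypes, phenotype, snp_ids=None) -> GenotypeDataset:
    g = np.asarray(genotypes)
    if snp_ids is None:
        snp_ids = [f"N{i}" for i in range(g.shape[1])]
    return GenotypeDataset(genotypes=g, phenotype=np.asarray(phenotype), snp_ids=snp_ids)


def random_dataset(rng: np.random.Generator, n_samples: int, n_snps: int) -> GenotypeDataset:
    """A random dataset guaranteed to carry both phenotype classes."""
    g = rng.integers(0, 3, size=(n_samples, n_snps))
    y = rng.integers(0, 2, size=n_samples)
    y[0] = 0
    y[-1] = 1
    return make_dataset(g, y)


@pytest.fixture
def eight_sample_dataset() -> GenotypeDataset:
    """8 samples x 2 SNPs with a mixed genotype-phenotype relationship."""
    g = [(0, 0), (0, 1), (1, 0), (1, 1), (2, 2), (2, 0), (0, 0), (1, 1)]
    y = [0, 0, 0, 1, 1, 1, 0, 1]
    return make_dataset(g, y)


@pytest.fixture
def two_disjoint_5_cliques() -> nx.Graph:
    return nx.disjoint_union(nx.complete_graph(5), nx.complete_graph(5))


@pytest.fixture
def bridged_6_cliques() -> nx.Graph:
    g = nx.disjoint_union(nx.complete_graph(6), nx.complete_graph(6))
    g.add_edge(0, 6)
    return g


@pytest.fixture
def shared_6_cliques() -> nx.Graph:
    """Two 6-cliques sharing nodes 0 and 1."""
    g = nx.Graph()
    for clique in ([0, 1, 2, 3, 4, 5], [0, 1, 6, 7, 8, 9]):
        for i in range(6):
            for j in range(i + 1, 6):
                g.add_edge(clique[i], clique[j])
    return g


def planted_partition_graph(seed: int) -> tuple[nx.Graph, list[set[int]]]:
    """20 nodes, two dense blocks (p_in=0.9) over sparse background (p_out=0.05)."""
    rng = np.random.default_rng(seed)
    g = nx.Graph()
    g.add_nodes_from(range(20))
    for i in range(20):
        for j in range(i + 1, 20):
            p = 0.9 if (i < 10) == (j < 10) else 0.05
            if rng.random() < p:
                g.add_edge(i, j)
    return g, [set(range(10)), set(range(10, 20))]
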