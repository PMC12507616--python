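import numpy as np
import pytest

import snpbn as s


@pytest.fixture(scope="session")
def table1():
    return s.build_table1_fixture()


@pytest.fixture(scope="session")
def scenario():
    return s.default_scenario()


@pytest.fixture(scope="session")
def scenario_dataset(scenario):
    return s.simulate(scenario)


def make_dataset(genotypes, phenotype, loci=None, subjects=None):
    genotypes = np.asarray(genotypes, dtype=np.int8)
    n, m = genotypes.shape
    if loci is None:
        loci = [s.Locus(f"rs{j}", ("A", "AG", "G")) for j in range(m)]
    if subjects is None:
        subjects = [f"S{i}" for i in range(n)]
    return s.GenotypeDataset(subjects, loci, genotypes, np.asarray(phenotype))


def random_ternary_network(rng, n_nodes, max_parents=3):
    """A random CPTSet over ternary nodes with Dirichlet(1) rows."""
    nodes = tuple(f"n{i}" for i in range(n_nodes))
    cpts = {}
    for i, node in enumerate(nodes):
        pool = list(nodes[:i])
        k = int(rng.integers(0, min(max_parents, len(pool)) + 1))
        parents = tuple(sorted(rng.choice(pool, size=k, replace=False))) if k else ()
        tab = rng.dirichlet(np.ones(3), size=3 ** len(parents))
        cpts[node] = s.NodeCPT(node, parents, (3,) * len(parents), tab)
    return s.CPTSet(nodes, cpts)
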