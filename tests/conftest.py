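import dendropy
import numpy as np
import pytest

from elevdiv.occurrence_io import OccurrenceRecord, SiteRecord
from elevdiv.synthetic import CommunityParams, simulate_community, study_params


@pytest.fixture
def small_sites():
    return [
        SiteRecord("s1", "T01", 1, 900.0),
        SiteRecord("s2", "T01", 2, 920.0),
        SiteRecord("s3", "T02", 1, 1100.0),
        SiteRecord("s4", "T03", 1, 1500.0),
        SiteRecord("s5", "T04", 1, 2100.0),
    ]


@pytest.fixture
def small_records(small_sites):
    return [
        OccurrenceRecord("spA", "s1", 3, 900.0),
        OccurrenceRecord("spA", "s3", 2, 1100.0),
        OccurrenceRecord("spB", "s3", 1, 1100.0),
        OccurrenceRecord("spC", "s4", 4, 1500.0),
        OccurrenceRecord("spC", "s5", 1, 2100.0),
    ]


@pytest.fixture(scope="session")
def study_community():
    """One deterministic study-preset community shared across tests."""
    params = study_params(seed=42)
    sites, truth, records = simulate_community(params)
    return params, sites, truth, records


@pytest.fixture(scope="session")
def null_community():
    """A null (beta = 0, uniform midpoints) community."""
    params = CommunityParams(seed=7)
    sites, truth, records = simulate_community(params)
    return params, sites, truth, records


def random_abundance_vector(rng: np.random.Generator, max_species=25, max_count=40):
    s = rng.integers(2, max_species + 1)
    return rng.integers(1, max_count + 1, size=s)


def random_additive_tree(n_taxa, pyrng):
    """Random binary tree with positive branch lengths: labels, patristic
    distance matrix, and the set of non-trivial bipartitions (frozensets of
    frozensets of labels).  Serves as the independent oracle for
    distance-based tree reconstruction."""
    taxa = [f"t{i}" for i in range(n_taxa)]
    tns = dendropy.TaxonNamespace(taxa)
    tree = dendropy.simulate.treesim.birth_death_tree(
        birth_rate=1.0,
        death_rate=0.0,
        num_extant_tips=n_taxa,
        taxon_namespace=tns,
        rng=pyrng,
    )
    for edge in tree.preorder_edge_iter():
        edge.length = pyrng.uniform(0.5, 3.0)
    tree.is_rooted = False

    pdm = tree.phylogenetic_distance_matrix()
    m = np.zeros((n_taxa, n_taxa))
    for i, ti in enumerate(tns):
        for j, tj in enumerate(tns):
            if i < j:
                m[i, j] = m[j, i] = pdm.patristic_distance(ti, tj)
    all_leaves = frozenset(t.label for t in tns)
    bips = set()
    for node in tree.preorder_internal_node_iter():
        side = frozenset(lf.taxon.label for lf in node.leaf_iter())
        if 2 <= len(side) <= n_taxa - 2:
            bips.add(frozenset({side, all_leaves - side}))
    return [t.label for t in tns], m, bips


def unrooted_bipartitions(tree: dendropy.Tree):
    """Non-trivial bipartitions of an (unrooted) dendropy tree as canonical
    frozenset-of-frozensets keys."""
    all_leaves = frozenset(lf.taxon.label for lf in tree.leaf_node_iter())
    bips = set()
    for node in tree.preorder_internal_node_iter():
        if node is tree.seed_node:
            continue
        side = frozenset(lf.taxon.label for lf in node.leaf_iter())
        if 2 <= len(side) <= len(all_leaves) - 2:
            bips.add(frozenset({side, all_leaves - side}))
    return bips
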