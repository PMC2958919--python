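"""Shared fixtures: small simulated datasets with ground truth."""

from __future__ import annotations

import dendropy
import numpy as np
import pytest

from aflpdelim.distance_nets import DistanceMatrix
from aflpdelim.synthetic_data import PopModel, simulate_aflp


@pytest.fixture(scope="session")
def three_pop_aflp():
    """Well-differentiated 3-population AFLP matrix (n=60, L=300, F=0.6)."""
    model = PopModel(K=3, L=300, F=0.6, n_per_pop=20, seed=11)
    return simulate_aflp(model)


@pytest.fixture(scope="session")
def two_pop_hybrid_aflp():
    """Two populations plus two first-generation hybrids (q = 0.5/0.5)."""
    model = PopModel(K=2, L=300, F=0.5, n_per_pop=25, hybrid_count=2, seed=7)
    return simulate_aflp(model)


def random_additive_metric(n: int, rng: np.random.Generator):
    """A random binary tree with uniform branch lengths and its path metric.

    Returns (dendropy tree, DistanceMatrix); the tree is the oracle for
    distance-based reconstruction: NJ must recover its topology and branch
    lengths exactly, neighbor-net its bipartitions as split weights.
    """
    ids = [f"T{i}" for i in range(n)]
    tns = dendropy.TaxonNamespace(ids)
    nodes = [dendropy.Node(taxon=tns.get_taxon(i)) for i in ids]
    while len(nodes) > 3:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        u = dendropy.Node()
        u.add_child(nodes[i])
        nodes[i].edge.length = float(rng.uniform(0.1, 2.0))
        u.add_child(nodes[j])
        nodes[j].edge.length = float(rng.uniform(0.1, 2.0))
        nodes = [nd for k, nd in enumerate(nodes) if k not in (i, j)] + [u]
    centre = dendropy.Node()
    for nd in nodes:
        centre.add_child(nd)
        nd.edge.length = float(rng.uniform(0.1, 2.0))
    tree = dendropy.Tree(taxon_namespace=tns)
    tree.seed_node = centre
    tree.is_rooted = False
    pdm = tree.phylogenetic_distance_matrix()
    D = np.zeros((n, n))
    for i, a in enumerate(ids):
        for j, b in enumerate(ids):
            if i != j:
                D[i, j] = pdm.distance(tns.get_taxon(a), tns.get_taxon(b))
    return tree, DistanceMatrix(ids, D)


def circular_metric(ids, ordering, splits):
    """Distance matrix of an explicit weighted circular split system.

    ``splits`` is a list of (member-set, weight); the metric sums the weights
    of the splits separating each pair.
    """
    n = len(ids)
    D = np.zeros((n, n))
    for side, w in splits:
        for a in range(n):
            for b in range(n):
                if (ids[a] in side) != (ids[b] in side):
                    D[a, b] += w
    return DistanceMatrix(list(ids), D)
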