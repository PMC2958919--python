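import numpy as np
import pytest
from scipy.optimize import nnls

from aflpdelim.distance_nets import (
    DistanceMatrix,
    SplitSystem,
    bootstrap_support,
    circular_split_weights,
    jaccard_matrix,
    neighbor_net,
    nj_tree,
    tree_bipartitions,
    write_phylip_distances,
)
from aflpdelim.io_formats import AFLPMatrix

from conftest import circular_metric, random_additive_metric


def _matrix(rows, ids=None):
    rows = np.asarray(rows)
    ids = ids or [f"s{i}" for i in range(rows.shape[0])]
    return AFLPMatrix(ids, [f"m{j}" for j in range(rows.shape[1])], rows)


class TestJaccard:
    def test_hand_enumeration(self):
        d = jaccard_matrix(_matrix([[1, 1, 0, 1], [1, 0, 1, 1]]))
        assert d.values[0, 1] == pytest.approx(0.5)

    def test_identity_and_disjoint(self):
        d = jaccard_matrix(_matrix([[1, 0, 1], [1, 0, 1], [0, 1, 0]]))
        assert d.values[0, 1] == 0.0
        assert d.values[0, 2] == 1.0

    def test_shared_absences_ignored(self):
        # adding a column of double absences must not change the distance
        a = jaccard_matrix(_matrix([[1, 0], [0, 1]])).values[0, 1]
        b = jaccard_matrix(_matrix([[1, 0, 0], [0, 1, 0]])).values[0, 1]
        assert a == b == 1.0

    def test_missing_pairwise_deletion(self):
        # marker 2 missing for s1: the pair is scored on markers 0, 1 only
        d = jaccard_matrix(_matrix([[1, 1, -1], [1, 0, 1]]))
        assert d.values[0, 1] == pytest.approx(0.5)

    def test_zero_union_pair_names_specimens(self):
        # the only marker scored in both specimens is absent in both
        with pytest.raises(ValueError, match="'s0'.*'s1'"):
            jaccard_matrix(_matrix([[1, 0], [-1, 0]]))

    def test_metric_axioms_on_random_matrices(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            n, L = rng.integers(4, 9), rng.integers(20, 60)
            vals = rng.integers(0, 2, size=(n, L)).astype(np.int8)
            vals[:, 0] = 1  # guarantee non-zero unions
            d = jaccard_matrix(_matrix(vals)).values
            assert np.allclose(d, d.T)
            assert (np.diag(d) == 0).all()
            for i in range(n):
                for j in range(n):
                    for k in range(n):
                        assert d[i, j] <= d[i, k] + d[k, j] + 1e-12


class TestNeighborJoining:
    def test_three_taxon_closed_form(self):
        D = np.array([[0, 3, 4], [3, 0, 5], [4, 5, 0]], dtype=float)
        t = nj_tree(DistanceMatrix(["a", "b", "c"], D))
        lengths = {l.taxon.label: l.edge.length for l in t.tree.leaf_node_iter()}
        assert lengths["a"] == pytest.approx(1.0)
        assert lengths["b"] == pytest.approx(2.0)
        assert lengths["c"] == pytest.approx(3.0)

    def test_additive_recovery_topology_and_lengths(self):
        rng = np.random.default_rng(17)
        for _ in range(10):
            tree, dm = random_additive_metric(int(rng.integers(5, 9)), rng)
            est = nj_tree(dm)
            assert tree_bipartitions(est.tree) == tree_bipartitions(tree)
            pdm = est.tree.phylogenetic_distance_matrix()
            tn = est.tree.taxon_namespace
            for i, a in enumerate(dm.ids):
                for j, b in enumerate(dm.ids):
                    if i < j:
                        assert pdm.distance(tn.get_taxon(a), tn.get_taxon(b)) == (
                            pytest.approx(dm.values[i, j], abs=1e-9)
                        )

    def test_permutation_equivariance(self):
        rng = np.random.default_rng(3)
        _, dm = random_additive_metric(7, rng)
        perm = rng.permutation(7)
        dm2 = DistanceMatrix([dm.ids[i] for i in perm],
                             dm.values[np.ix_(perm, perm)])
        assert tree_bipartitions(nj_tree(dm).tree) == tree_bipartitions(nj_tree(dm2).tree)

    def test_too_few_taxa_rejected(self):
        with pytest.raises(ValueError):
            nj_tree(DistanceMatrix(["a", "b"], np.array([[0.0, 1.0], [1.0, 0.0]])))

    def test_negative_lengths_clamped(self):
        # a metric violating additivity can produce negative NJ limbs
        D = np.array([
            [0, 1, 6, 6], [1, 0, 6, 6], [6, 6, 0, 1], [6, 6, 1, 0],
        ], dtype=float) * np.array([[1.0]])
        D[0, 1] = D[1, 0] = 0.001
        t = nj_tree(DistanceMatrix(list("abcd"), D))
        for e in t.tree.preorder_edge_iter():
            if e.length is not None:
                assert e.length >= 0


class TestBootstrap:
    def test_fixed_differences_give_full_support(self):
        rng = np.random.default_rng(1)
        block = rng.integers(0, 2, size=(8, 30))
        fixed = np.zeros((8, 50), dtype=int)
        fixed[:4] = 1
        m = _matrix(np.hstack([block, fixed]).astype(np.int8))
        t = bootstrap_support(m, replicates=100, seed=0)
        side = frozenset(m.specimen_ids[4:])
        assert t.supports[side] == pytest.approx(100.0)

    def test_single_replicate_support_binary(self):
        rng = np.random.default_rng(2)
        m = _matrix(rng.integers(0, 2, size=(6, 40)).astype(np.int8))
        m.values[:, 0] = 1
        t = bootstrap_support(m, replicates=1, seed=3)
        assert set(t.supports.values()) <= {0.0, 100.0}

    def test_same_seed_identical(self):
        rng = np.random.default_rng(4)
        vals = rng.integers(0, 2, size=(6, 40)).astype(np.int8)
        vals[:, 0] = 1
        assert (bootstrap_support(_matrix(vals), 20, seed=9).supports
                == bootstrap_support(_matrix(vals), 20, seed=9).supports)

    def test_zero_replicates_rejected(self):
        with pytest.raises(ValueError):
            bootstrap_support(_matrix([[1, 0], [0, 1], [1, 1]]), replicates=0)


class TestNeighborNet:
    def test_three_taxa_pendant_splits_only(self):
        D = np.array([[0, 3, 4], [3, 0, 5], [4, 5, 0]], dtype=float)
        ss = neighbor_net(DistanceMatrix(["a", "b", "c"], D))
        assert ss.nontrivial() == []

    def test_tree_metric_recovers_bipartitions_and_lengths(self):
        rng = np.random.default_rng(23)
        tree, dm = random_additive_metric(7, rng)
        ss = neighbor_net(dm)
        ind = ss.induced_distances()
        idx = {t: i for i, t in enumerate(ind.ids)}
        for i, a in enumerate(dm.ids):
            for j, b in enumerate(dm.ids):
                assert ind.values[idx[a], idx[b]] == pytest.approx(
                    dm.values[i, j], abs=1e-6)
        allt = frozenset(dm.ids)
        ref = sorted(dm.ids)[0]
        got = {(allt - s if ref in s else s) for s, _ in ss.nontrivial()}
        assert got == tree_bipartitions(tree)

    def test_incompatible_splits_recovered_with_weights(self):
        ids = ["A", "B", "C", "D"]
        gen = [({"A", "B"}, 0.6), ({"B", "C"}, 0.4),
               ({"A"}, 0.3), ({"B"}, 0.2), ({"C"}, 0.25), ({"D"}, 0.35)]
        dm = circular_metric(ids, ids, gen)
        ss = neighbor_net(dm)
        weights = {frozenset(s): w for s, w in ss.splits}
        allt = frozenset(ids)

        def w(side):
            side = frozenset(side)
            return weights.get(side, weights.get(allt - side, 0.0))

        assert w({"A", "B"}) == pytest.approx(0.6, abs=1e-8)
        assert w({"B", "C"}) == pytest.approx(0.4, abs=1e-8)
        assert w({"A"}) == pytest.approx(0.3, abs=1e-8)

    def test_matches_brute_force_nnls_on_known_ordering(self):
        # oracle: NNLS over all splits of the generating circular ordering,
        # with the design matrix built directly from first principles
        rng = np.random.default_rng(31)
        ids = [f"T{i}" for i in range(6)]
        gen = [({"T0", "T1"}, 0.5), ({"T1", "T2"}, 0.3), ({"T2", "T3", "T4"}, 0.7),
               ({"T4", "T5"}, 0.4)] + [({t}, float(rng.uniform(0.2, 0.6))) for t in ids]
        dm = circular_metric(ids, ids, gen)
        ss = neighbor_net(dm)
        # brute-force oracle
        n = len(ids)
        splits, rows = [], []
        for i in range(1, n):
            for j in range(i, n):
                splits.append(frozenset(ids[i:j + 1]))
        pairs = [(a, b) for a in range(n) for b in range(a + 1, n)]
        A = np.zeros((len(pairs), len(splits)))
        for c, side in enumerate(splits):
            for r, (a, b) in enumerate(pairs):
                A[r, c] = (ids[a] in side) != (ids[b] in side)
        y = np.array([dm.values[a, b] for a, b in pairs])
        w, _ = nnls(A, y)
        oracle = {s: x for s, x in zip(splits, w) if x > 1e-8}
        got = {}
        allt = frozenset(ids)
        for s, x in ss.splits:
            got[s if ids[0] not in s else allt - s] = x
        oracle = {s if ids[0] not in s else allt - s: x for s, x in oracle.items()}
        assert set(got) == set(oracle)
        for s in got:
            assert got[s] == pytest.approx(oracle[s], abs=1e-6)

    def test_permutation_equivariance(self):
        rng = np.random.default_rng(8)
        _, dm = random_additive_metric(6, rng)
        perm = rng.permutation(6)
        dm2 = DistanceMatrix([dm.ids[i] for i in perm], dm.values[np.ix_(perm, perm)])
        s1 = {frozenset(s): round(w, 9) for s, w in neighbor_net(dm).nontrivial()}
        s2 = {frozenset(s): round(w, 9) for s, w in neighbor_net(dm2).nontrivial()}
        allt = frozenset(dm.ids)
        canon1 = {(s if dm.ids[0] not in s else allt - s): w for s, w in s1.items()}
        canon2 = {(s if dm.ids[0] not in s else allt - s): w for s, w in s2.items()}
        assert canon1 == canon2

    def test_split_system_validates_circularity(self):
        with pytest.raises(ValueError, match="circular"):
            SplitSystem(["a", "b", "c", "d"], [(frozenset({"a", "c"}), 1.0)])


def test_phylip_export_contains_all_rows():
    D = np.array([[0, 1.0], [1.0, 0]])
    # use 3 taxa for a valid write
    D = np.array([[0, 1, 2], [1, 0, 1.5], [2, 1.5, 0]], dtype=float)
    text = write_phylip_distances(DistanceMatrix(["a", "b", "c"], D))
    lines = text.strip().splitlines()
    assert lines[0].strip() == "3"
    assert len(lines) == 4
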