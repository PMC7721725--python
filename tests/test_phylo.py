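import numpy as np
import pandas as pd
import pytest
from scipy.cluster.hierarchy import average, fcluster
from scipy.spatial.distance import squareform
from skbio import TreeNode

from methorigin.containers import BetaMatrix, ValidationError
from methorigin.phylo import (
    DistanceMatrix,
    clade_membership,
    correlation_distance,
    nj_tree,
    root_tree,
)
from methorigin.simulate import SimulationConfig, simulate_cohort

from _oracles import naive_nj


def _beta(values):
    values = np.asarray(values, float)
    return BetaMatrix(
        pd.DataFrame(
            values,
            index=[f"cg{i:05d}" for i in range(values.shape[0])],
            columns=[f"s{j}" for j in range(values.shape[1])],
        )
    )


def _tip_distances(tree):
    dm = tree.tip_tip_distances()
    ids = sorted(dm.ids)
    return ids, np.array([[dm[a, b] for b in ids] for a in ids])


def _random_additive_tree(rng, names):
    nodes = [TreeNode(name=n, length=float(rng.uniform(0.05, 1.0))) for n in names]
    while len(nodes) > 3:
        i = rng.integers(len(nodes))
        a = nodes.pop(i)
        j = rng.integers(len(nodes))
        b = nodes.pop(j)
        nodes.append(TreeNode(children=[a, b], length=float(rng.uniform(0.05, 1.0))))
    root = TreeNode(children=nodes)
    return root


class TestCorrelationDistance:
    def test_identical_samples_have_zero_distance(self):
        rng = np.random.default_rng(0)
        col = rng.uniform(0, 1, 60)
        beta = _beta(np.column_stack([col, col, rng.uniform(0, 1, 60)]))
        d = correlation_distance(beta)
        assert d.D[0, 1] == pytest.approx(0.0, abs=1e-12)

    def test_anticorrelated_samples_have_distance_two(self):
        rng = np.random.default_rng(1)
        col = rng.uniform(0, 1, 60)
        beta = _beta(np.column_stack([col, 1 - col, rng.uniform(0, 1, 60)]))
        d = correlation_distance(beta)
        assert d.D[0, 1] == pytest.approx(2.0, abs=1e-12)

    def test_matches_elementwise_oracle(self):
        rng = np.random.default_rng(2)
        beta = _beta(rng.uniform(0, 1, (80, 5)))
        d = correlation_distance(beta)
        arr = beta.values.to_numpy()
        for i in range(5):
            for j in range(5):
                x, y = arr[:, i], arr[:, j]
                r = np.sum((x - x.mean()) * (y - y.mean())) / np.sqrt(
                    np.sum((x - x.mean()) ** 2) * np.sum((y - y.mean()) ** 2)
                )
                assert abs(d.D[i, j] - (1 - r)) < 1e-12

    def test_invariant_to_positive_affine_transform(self):
        rng = np.random.default_rng(3)
        arr = rng.uniform(0.2, 0.6, (100, 4))
        d0 = correlation_distance(_beta(arr))
        d1 = correlation_distance(_beta(0.5 * arr + 0.1))
        assert np.allclose(d0.D, d1.D, atol=1e-12)

    def test_zero_variance_sample_is_named(self):
        arr = np.random.default_rng(4).uniform(0, 1, (50, 3))
        arr[:, 1] = 0.5
        with pytest.raises(ValidationError, match="s1"):
            correlation_distance(_beta(arr))


class TestNeighborJoining:
    def test_three_taxon_closed_form(self):
        D = np.array([[0.0, 0.4, 0.6], [0.4, 0.0, 0.8], [0.6, 0.8, 0.0]])
        tree = nj_tree(DistanceMatrix(["A", "B", "C"], D))
        assert tree.find("A").length == pytest.approx((0.4 + 0.6 - 0.8) / 2)
        assert tree.find("B").length == pytest.approx((0.4 + 0.8 - 0.6) / 2)
        assert tree.find("C").length == pytest.approx((0.6 + 0.8 - 0.4) / 2)

    def test_additive_matrix_recovered_exactly(self):
        rng = np.random.default_rng(5)
        for rep in range(5):
            names = [f"t{i}" for i in range(5)]
            true = _random_additive_tree(rng, names)
            ids, D = _tip_distances(true)
            est = nj_tree(DistanceMatrix(ids, D))
            assert true.compare_rfd(est) == 0.0
            ids2, D2 = _tip_distances(est)
            assert ids2 == ids
            assert np.allclose(D, D2, atol=1e-10)

    def test_matches_textbook_implementation_on_random_matrices(self):
        rng = np.random.default_rng(6)
        for rep in range(20):
            n = 8
            M = rng.uniform(0.1, 1.0, (n, n))
            D = (M + M.T) / 2
            np.fill_diagonal(D, 0.0)
            labels = [f"x{i}" for i in range(n)]
            mine = nj_tree(DistanceMatrix(labels, D))
            ref = naive_nj(labels, D)
            assert mine.compare_rfd(ref) == 0.0
            _, dm = _tip_distances(mine)
            _, dr = _tip_distances(ref)
            assert np.allclose(dm, dr, atol=1e-8)

    def test_invariant_to_label_order(self):
        rng = np.random.default_rng(7)
        n = 7
        M = rng.uniform(0.1, 1.0, (n, n))
        D = (M + M.T) / 2
        np.fill_diagonal(D, 0.0)
        labels = [f"x{i}" for i in range(n)]
        t1 = nj_tree(DistanceMatrix(labels, D))
        perm = rng.permutation(n)
        t2 = nj_tree(DistanceMatrix([labels[i] for i in perm], D[np.ix_(perm, perm)]))
        assert t1.compare_rfd(t2) == 0.0
        _, d1 = _tip_distances(t1)
        _, d2 = _tip_distances(t2)
        assert np.allclose(d1, d2, atol=1e-10)

    def test_ultrametric_agrees_with_average_linkage(self):
        rng = np.random.default_rng(8)
        for rep in range(5):
            # build an ultrametric tree: equal root-to-tip depth
            n = 6
            X = rng.normal(0, 1, (n, 1))
            # ultrametric distances via single-point average clustering heights
            D = np.abs(X - X.T)
            Z = average(squareform(D, checks=False))
            # cophenetic distances are ultrametric
            from scipy.cluster.hierarchy import cophenet

            U = squareform(cophenet(Z))
            labels = [f"u{i}" for i in range(n)]
            tree = nj_tree(DistanceMatrix(labels, U))
            # compare bipartitions with average-linkage cuts
            for k in (2, 3):
                cut = fcluster(Z, k, criterion="maxclust")
                groups = {}
                for lab, c in zip(labels, cut):
                    groups.setdefault(c, set()).add(lab)
                tip_sets = [
                    set(t.name for t in node.tips())
                    for node in tree.traverse()
                    if not node.is_tip()
                ]
                all_tips = set(labels)
                for members in groups.values():
                    # pendant-edge bipartitions are trivially present
                    if len(members) <= 1 or len(members) >= n - 1:
                        continue
                    assert members in tip_sets or (all_tips - members) in tip_sets

    def test_non_symmetric_matrix_rejected(self):
        D = np.array([[0, 1, 2], [1.5, 0, 1], [2, 1, 0]], float)
        with pytest.raises(ValidationError, match="symmetric"):
            DistanceMatrix(["a", "b", "c"], D)


class TestRootingAndClades:
    def test_rooting_three_taxa_bisects_pendant_edge(self):
        D = np.array([[0.0, 0.4, 0.6], [0.4, 0.0, 0.8], [0.6, 0.8, 0.0]])
        tree = nj_tree(DistanceMatrix(["A", "B", "C"], D))
        la = tree.find("A").length
        rooted = root_tree(tree, "A")
        tip = rooted.find("A")
        assert tip.parent is rooted
        assert tip.length == pytest.approx(la / 2)

    def test_reroot_then_unroot_preserves_topology(self):
        rng = np.random.default_rng(9)
        names = [f"t{i}" for i in range(8)]
        true = _random_additive_tree(rng, names)
        ids, D = _tip_distances(true)
        tree = nj_tree(DistanceMatrix(ids, D))
        rooted = root_tree(tree, ids[3])
        assert tree.compare_rfd(rooted, rooted=False) == 0.0

    def test_unknown_outgroup_rejected(self):
        D = np.array([[0.0, 0.4, 0.6], [0.4, 0.0, 0.8], [0.6, 0.8, 0.0]])
        tree = nj_tree(DistanceMatrix(["A", "B", "C"], D))
        with pytest.raises(ValidationError, match="nope"):
            root_tree(tree, "nope")

    def test_planted_groups_recovered_from_tree(self, small_cohort):
        cohort = small_cohort
        refs = cohort.reference_sheet.table
        ab = refs.index[refs["cell_type"].isin(["alpha", "beta"])].tolist()
        gt = cohort.ground_truth
        dm_probes = gt.marker_probes["alpha"] + gt.marker_probes["beta"]
        combined = BetaMatrix(
            pd.concat(
                [cohort.reference_beta.select_samples(ab).values, cohort.tumour_beta.values],
                axis=1,
            )
        )
        tree = nj_tree(correlation_distance(combined, dm_probes))
        ref_tips = {sid: refs.loc[sid, "cell_type"] for sid in ab}
        labels = clade_membership(tree, ref_tips)
        truth = gt.sample_truth["group"]
        alpha_group = truth.index[truth == "alpha_like"]
        frac = (labels.loc[alpha_group, "label"] == "alpha").mean()
        assert frac >= 0.95

    def test_no_reference_tips_rejected(self):
        D = np.array([[0.0, 0.4, 0.6], [0.4, 0.0, 0.8], [0.6, 0.8, 0.0]])
        tree = nj_tree(DistanceMatrix(["A", "B", "C"], D))
        with pytest.raises(ValidationError):
            clade_membership(tree, {})

    def test_zero_distance_tumour_labelled_by_its_reference(self):
        rng = np.random.default_rng(10)
        col_a = rng.uniform(0, 1, 60)
        col_b = rng.uniform(0, 1, 60)
        beta = _beta(np.column_stack([col_a, col_b, col_a, rng.uniform(0, 1, 60)]))
        tree = nj_tree(correlation_distance(beta))
        labels = clade_membership(tree, {"s0": "alpha", "s1": "beta"})
        assert labels.loc["s2", "label"] == "alpha"
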