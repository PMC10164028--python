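import numpy as np
import pytest

import meddecode as md
from meddecode.decoding import CVConfig, CVResult, FoldResult
from meddecode.util import ValidationError


def fake_cv(selections, weights, n_edges, accuracy=0.8):
    """CVResult with hand-specified per-fold selections and weights."""
    folds = [
        FoldResult(accuracy=accuracy,
                   selected_edges=np.asarray(sel, dtype=int),
                   weights=np.asarray(w, dtype=float), intercept=0.0,
                   train_subjects=("a",), test_subjects=("b",))
        for sel, w in zip(selections, weights)
    ]
    cfg = CVConfig(n_repetitions=len(folds), k_features=len(selections[0]),
                   seed=0)
    return CVResult(folds=folds, config=cfg, n_edges=n_edges)


@pytest.fixture
def toy4():
    # 2 networks x 2 ROIs; one left/right pair per network
    return md.parcellation_from_lists(
        ["A", "B", "C", "D"], ["net1", "net1", "net2", "net2"],
        ["L", "R", "L", "R"])


class TestSelectionProbability:
    def test_simple_fractions(self, toy4):
        edges = md.build_edge_table(toy4)
        cv = fake_cv([[0, 1], [0, 2]], [[1.0, -1.0]] * 2, edges.n_edges)
        sp = md.selection_probability(cv, edges)
        assert sp.per_edge[0] == 1.0
        assert sp.per_edge[1] == 0.5
        assert sp.per_edge[2] == 0.5
        assert sp.per_edge[3] == 0.0
        assert sp.matrix[0, 1] == sp.matrix[1, 0] == 1.0

    def test_probability_mass_equals_k(self, toy4):
        edges = md.build_edge_table(toy4)
        rng = np.random.default_rng(0)
        sels = [rng.choice(edges.n_edges, size=3, replace=False)
                for _ in range(10)]
        cv = fake_cv(sels, [np.ones(3)] * 10, edges.n_edges)
        sp = md.selection_probability(cv, edges)
        assert sp.per_edge.sum() == pytest.approx(3.0)


class TestNetworkRelevance:
    def test_uniform_probability_uniform_blocks(self, toy4):
        edges = md.build_edge_table(toy4)
        sp = md.SelectionProbabilityMatrix(
            matrix=md.matrix_from_vector(np.full(edges.n_edges, 0.3), edges),
            per_edge=np.full(edges.n_edges, 0.3), n_repetitions=10)
        nr = md.network_relevance(sp, toy4, edges)
        np.testing.assert_allclose(nr.block_matrix, 0.3)
        np.testing.assert_allclose(nr.per_network, 0.3)

    def test_hand_computed_blocks(self, toy4):
        edges = md.build_edge_table(toy4)
        # edges: (A,B)=0 within net1, (A,C)=1, (A,D)=2, (B,C)=3, (B,D)=4
        # between, (C,D)=5 within net2
        p = np.array([0.8, 0.1, 0.2, 0.3, 0.4, 0.6])
        sp = md.SelectionProbabilityMatrix(
            matrix=md.matrix_from_vector(p, edges), per_edge=p,
            n_repetitions=10)
        nr = md.network_relevance(sp, toy4, edges)
        assert nr.block_matrix[0, 0] == pytest.approx(0.8)
        assert nr.block_matrix[1, 1] == pytest.approx(0.6)
        assert nr.block_matrix[0, 1] == pytest.approx(np.mean([0.1, 0.2, 0.3, 0.4]))
        assert nr.block_matrix[0, 1] == nr.block_matrix[1, 0]
        assert nr.per_network[0] == pytest.approx((0.8 + 0.25) / 2)

    def test_single_roi_network_within_block_missing(self):
        parc = md.parcellation_from_lists(["A", "B", "C"],
                                          ["net1", "net1", "net2"],
                                          ["L", "R", "L"])
        edges = md.build_edge_table(parc)
        p = np.array([0.5, 0.5, 0.5])
        sp = md.SelectionProbabilityMatrix(
            matrix=md.matrix_from_vector(p, edges), per_edge=p,
            n_repetitions=4)
        nr = md.network_relevance(sp, parc, edges)
        assert np.isnan(nr.block_matrix[1, 1])  # net2 has a single ROI


class TestStableEdges:
    def test_thresholds(self, toy4):
        edges = md.build_edge_table(toy4)
        p = np.array([1.0, 0.99, 0.5, 0.0, 1.0, 0.7])
        sp = md.SelectionProbabilityMatrix(
            matrix=md.matrix_from_vector(p, edges), per_edge=p,
            n_repetitions=100)
        np.testing.assert_array_equal(md.stable_edges(sp), [0, 4])
        np.testing.assert_array_equal(md.stable_edges(sp, 0.0),
                                      np.arange(6))

    def test_none_stable_is_empty(self, toy4):
        edges = md.build_edge_table(toy4)
        p = np.full(6, 0.5)
        sp = md.SelectionProbabilityMatrix(
            matrix=md.matrix_from_vector(p, edges), per_edge=p,
            n_repetitions=2)
        assert md.stable_edges(sp).size == 0


class TestWeightMap:
    def test_sign_tags_and_normalization(self, toy4):
        edges = md.build_edge_table(toy4)
        cv = fake_cv([[0, 5], [0, 5]],
                     [[3.0, -4.0], [3.0, -4.0]], edges.n_edges)
        wm = md.weight_map(cv, np.array([0, 5]))
        # L2 normalization: (3, -4)/5
        np.testing.assert_allclose(wm.mean_weight, [0.6, -0.8])
        assert wm.condition.tolist() == ["FA", "OM"]

    def test_constant_weights_maximal_t(self, toy4):
        edges = md.build_edge_table(toy4)
        cv = fake_cv([[1]] * 5, [[2.0]] * 5, edges.n_edges)
        wm = md.weight_map(cv, np.array([1]), weight_norm="none")
        assert np.isinf(wm.t_stat[0])
        assert wm.p_adj[0] == 0.0

    def test_flipped_weights_swap_tags(self, toy4):
        edges = md.build_edge_table(toy4)
        sels = [[0, 2], [0, 2]]
        ws = [[1.0, -0.5], [0.8, -0.7]]
        wm = md.weight_map(fake_cv(sels, ws, edges.n_edges), np.array([0, 2]))
        flipped = md.weight_map(
            fake_cv(sels, [[-a, -b] for a, b in ws], edges.n_edges),
            np.array([0, 2]))
        swap = {"FA": "OM", "OM": "FA"}
        assert [swap[c] for c in wm.condition] == flipped.condition.tolist()

    def test_empty_stable_set(self, toy4):
        edges = md.build_edge_table(toy4)
        cv = fake_cv([[0]], [[1.0]], edges.n_edges)
        wm = md.weight_map(cv, np.array([], dtype=int))
        assert wm.edge_ids.size == 0


class TestRelevantFeatureFStats:
    def test_degrees_of_freedom(self, expert_dataset):
        out = md.relevant_feature_fstats(expert_dataset, np.array([0, 1, 2]))
        assert (out["df2"] == 70).all()  # 72 samples -> df2 = n - 2

    def test_matches_scipy_f_oneway(self):
        from scipy.stats import f_oneway
        from conftest import make_tiny_dataset
        ds = make_tiny_dataset(n_subjects=8, separation=0.5, seed=0)
        out = md.relevant_feature_fstats(ds, np.array([0, 3]))
        for row, e in zip(out.itertuples(), [0, 3]):
            ref = f_oneway(ds.X[ds.y == "FA", e], ds.X[ds.y == "OM", e])
            assert row.F == pytest.approx(ref.statistic, rel=1e-10)
            assert row.p == pytest.approx(ref.pvalue, rel=1e-8)

    def test_empty_stable_rejected(self, expert_dataset):
        with pytest.raises(ValidationError):
            md.relevant_feature_fstats(expert_dataset, np.array([], dtype=int))


class TestHemisphericAnalysis:
    def test_empty_stable_set_skips_tests(self, toy4):
        edges = md.build_edge_table(toy4)
        cv = fake_cv([[0]], [[1.0]], edges.n_edges)
        wm = md.weight_map(cv, np.array([], dtype=int))
        hemi = md.hemispheric_analysis(wm, edges, toy4)
        assert all(v == 0 for v in hemi.counts.values())
        assert hemi.mw_U is None

    def test_all_left_concentration_detected(self):
        # 10 left + 2 right ROIs; all stable edges intra-left
        parc = md.parcellation_from_lists(
            [f"r{i}" for i in range(12)], ["net1"] * 12,
            ["L"] * 10 + ["R"] * 2)
        edges = md.build_edge_table(parc)
        left_edges = np.nonzero(edges.hemi_class == "intra_left")[0][:8]
        cv = fake_cv([left_edges], [np.ones(8)], edges.n_edges)
        wm = md.weight_map(cv, left_edges)
        hemi = md.hemispheric_analysis(wm, edges, parc, n_perm=200, seed=0)
        assert hemi.counts["intra_left"] == 8
        assert hemi.counts["intra_right"] == 0
        # with 10/12 ROIs left, all-left sets are common under permutation;
        # the p-value must still be a valid probability and count correct
        assert 0 < hemi.count_p["intra_left"] <= 1

    def test_left_excess_small_p_balanced_atlas(self):
        parc = md.parcellation_from_lists(
            [f"r{i}" for i in range(12)], ["net1"] * 12,
            ["L"] * 6 + ["R"] * 6)
        edges = md.build_edge_table(parc)
        left_edges = np.nonzero(edges.hemi_class == "intra_left")[0]
        cv = fake_cv([left_edges], [np.ones(left_edges.size)], edges.n_edges)
        wm = md.weight_map(cv, left_edges)
        hemi = md.hemispheric_analysis(wm, edges, parc, n_perm=400, seed=0)
        assert hemi.counts["intra_left"] == 15
        assert hemi.count_p["intra_left"] < 0.05
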