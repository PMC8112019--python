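"""Guided Grad-CAM, effect sizes, betweenness, communities and hubs."""

import numpy as np
import pytest

from conftest import random_symmetric
from oracles import exhaustive_edge_betweenness, exhaustive_max_modularity
from wassconn import (
    CAMMatrix,
    EdgePermutation,
    ModelSpec,
    average_cams,
    cam_vs_effects,
    communities_by_modularity,
    edge_betweenness_matrix,
    edge_effect_sizes,
    gradcam_edge_map,
    hub_report,
    rank_univariate_cam,
    train_member,
)
from wassconn.nn import TrainedModel, _init_bn_stats, _init_params
from wassconn.saliency import cam_region_strength


def zeroed_model(spec, rect_shape, n_channels=1):
    rng = np.random.default_rng(0)
    params = _init_params(spec, rect_shape, n_channels, rng)
    return TrainedModel(
        spec=spec, rect_shape=rect_shape, n_channels=n_channels,
        params={k: np.zeros_like(v) for k, v in params.items()},
        bn_stats=_init_bn_stats(spec),
    )


def planted_cell_model(perm, cells):
    """A network whose case logit is exactly the sum of the chosen cells.

    Filter i is an indicator of column c_i; the single dense layer picks the
    (row r_i, filter i) activation; batch norm is left at identity.  For a
    positive input rectangle the guided Grad-CAM saliency is then nonzero at
    exactly the chosen cells.
    """
    rows, cols = perm.rect_shape
    spec = ModelSpec(n_filters=len(cells) + 1, dense_units=len(cells),
                     n_dense=1, dropout=0.0, epochs=1, seed=0)
    rng = np.random.default_rng(0)
    params = _init_params(spec, (rows, cols), 1, rng)
    params = {k: np.zeros_like(v) for k, v in params.items()}
    for i, (r, c) in enumerate(cells):
        params["Wc"][i, c] = 1.0
        params["W0"][r * spec.n_filters + i, i] = 1.0
    params["gamma0"] = np.ones(spec.dense_units)
    params["Wo"][:, 1] = 1.0
    params["Wo"][:, 0] = -1.0
    return TrainedModel(
        spec=spec, rect_shape=(rows, cols), n_channels=1,
        params=params, bn_stats=_init_bn_stats(spec),
    )


class TestGradCam:
    def test_zero_weight_model_gives_zero_map(self):
        perm = EdgePermutation(8, seed=0)
        spec = ModelSpec(n_filters=4, dense_units=3, n_dense=1, dropout=0.0,
                         epochs=1, seed=0)
        model = zeroed_model(spec, perm.rect_shape)
        rect = np.abs(np.random.default_rng(1).normal(size=perm.rect_shape))
        assert np.allclose(gradcam_edge_map(model, rect, perm), 0.0)

    def test_planted_cells_are_top_edges(self, rng):
        perm = EdgePermutation(8, seed=3)
        cells = [(0, 0), (2, 1), (5, 3)]
        model = planted_cell_model(perm, cells)
        rect = rng.uniform(0.5, 1.5, size=perm.rect_shape)
        sal = gradcam_edge_map(model, rect, perm)
        planted_edges = {
            (int(perm.rows_i[r, c]), int(perm.rows_j[r, c])) for r, c in cells
        }
        iu = np.triu_indices(8, k=1)
        order = np.argsort(sal[iu])[::-1]
        top3 = {(int(iu[0][k]), int(iu[1][k])) for k in order[:3]}
        assert top3 == planted_edges
        assert np.count_nonzero(sal[iu]) == 3

    def test_trained_model_map_nonnegative_symmetric(self, rng):
        perm = EdgePermutation(8, seed=1)
        spec = ModelSpec(n_filters=8, dense_units=8, n_dense=2, epochs=5,
                         batch_size=16, seed=4)
        x = rng.normal(size=(60, *perm.rect_shape, 1))
        y = rng.integers(0, 2, size=60)
        x[:, 0, 0, 0] += 2.0 * (2 * y - 1)
        model = train_member(spec, x, y, x[:20], y[:20])
        sal = gradcam_edge_map(model, x[0], perm)
        assert np.all(sal >= 0)
        assert np.array_equal(sal, sal.T)
        assert np.allclose(np.diag(sal), 0.0)


class TestAverageCams:
    def test_single_map_is_itself(self, rng):
        m = np.abs(random_symmetric(rng, 6))
        cam = average_cams([m])
        assert np.array_equal(cam.values, m)
        assert cam.n_contributions == 1

    def test_map_and_negation_average_to_zero(self, rng):
        m = random_symmetric(rng, 6)
        assert np.allclose(average_cams([m, -m]).values, 0.0)

    def test_matches_two_pass_mean(self, rng):
        maps = [np.abs(random_symmetric(rng, 5)) for _ in range(100)]
        cam = average_cams(maps)
        expected = sum(maps) / len(maps)
        assert np.allclose(cam.values, expected, atol=1e-12)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            average_cams([])


class TestEdgeEffectSizes:
    def test_planted_shift_detected(self, rng):
        n = 8
        edges = [(0, 1), (0, 2), (1, 3), (2, 5), (4, 6)]

        def unit_sd_symmetric():
            m = np.zeros((n, n))
            iu = np.triu_indices(n, k=1)
            m[iu] = rng.normal(size=len(iu[0]))  # edgewise s.d. exactly 1
            return m + m.T

        cases, controls = [], []
        for _ in range(100):
            controls.append(unit_sd_symmetric())
            shifted = unit_sd_symmetric()
            for i, j in edges:  # shift of one pooled s.d.
                shifted[i, j] += 1.0
                shifted[j, i] = shifted[i, j]
            cases.append(shifted)
        eff = edge_effect_sizes(cases, controls)
        iu = np.triu_indices(n, k=1)
        d = np.abs(eff.d_values[iu])
        top5 = set(np.argsort(d)[::-1][:5])
        edge_idx = {
            k for k, (i, j) in enumerate(zip(*iu)) if (int(i), int(j)) in edges
        }
        assert top5 == edge_idx
        for k in edge_idx:
            assert d[k] == pytest.approx(1.0, abs=0.3)

    def test_null_groups_small_d(self, rng):
        mats = [random_symmetric(rng, 6) for _ in range(80)]
        eff = edge_effect_sizes(mats[:40], mats[40:])
        iu = np.triu_indices(6, k=1)
        assert np.nanmean(np.abs(eff.d_values[iu])) < 0.3
        assert np.all((eff.q_values[iu] >= 0) & (eff.q_values[iu] <= 1))

    def test_constant_groups_all_missing(self):
        const = [np.zeros((4, 4)) for _ in range(3)]
        with pytest.warns(UserWarning):
            eff = edge_effect_sizes(const, const)
        iu = np.triu_indices(4, k=1)
        assert np.all(np.isnan(eff.d_values[iu]))


class TestCamVsEffects:
    def test_monotone_transform_perfect_spearman(self, rng):
        cam_vals = np.abs(random_symmetric(rng, 8))
        cam = CAMMatrix(values=cam_vals)
        d = np.exp(cam_vals)  # strictly monotone in the CAM
        np.fill_diagonal(d, 0)
        eff = type("E", (), {"d_values": d})()
        res = cam_vs_effects(cam, eff)
        assert res["spearman_rho"] == pytest.approx(1.0)

    def test_constant_cam_rejected(self, rng):
        cam = CAMMatrix(values=np.ones((5, 5)) - np.eye(5))
        d = random_symmetric(rng, 5)
        eff = type("E", (), {"d_values": d})()
        from wassconn.features import InsufficientDataError

        with pytest.raises(InsufficientDataError):
            cam_vs_effects(cam, eff)


def random_weighted_graph(rng, n, p=0.6):
    m = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            if rng.random() < p:
                m[i, j] = m[j, i] = rng.uniform(0.1, 2.0)
    return m


class TestEdgeBetweenness:
    def test_three_node_path(self):
        m = np.zeros((3, 3))
        m[0, 1] = m[1, 0] = 1.0
        m[1, 2] = m[2, 1] = 1.0
        bw = edge_betweenness_matrix(CAMMatrix(values=m))
        assert bw[0, 1] == pytest.approx(2.0)
        assert bw[1, 2] == pytest.approx(2.0)

    def test_complete_equal_weight_graph(self):
        m = np.ones((4, 4)) - np.eye(4)
        bw = edge_betweenness_matrix(CAMMatrix(values=m))
        iu = np.triu_indices(4, k=1)
        assert np.allclose(bw[iu], 1.0)

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_exhaustive_path_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 9))
        m = random_weighted_graph(rng, n)
        if not m.any():
            return
        bw = edge_betweenness_matrix(CAMMatrix(values=m))
        eps = 1e-12 * m.max()
        lengths = {
            (i, j): 1.0 / (m[i, j] + eps)
            for i in range(n) for j in range(i + 1, n) if m[i, j] > 0
        }
        oracle = exhaustive_edge_betweenness(lengths, n)
        for (i, j), v in oracle.items():
            assert bw[i, j] == pytest.approx(v, abs=1e-8)

    def test_all_zero_cam_rejected(self):
        with pytest.raises(ValueError):
            edge_betweenness_matrix(CAMMatrix(values=np.zeros((4, 4))))


class TestCommunities:
    def test_two_cliques_recovered_at_exhaustive_maximum(self):
        n = 8
        m = np.zeros((n, n))
        for block in (range(4), range(4, 8)):
            for i in block:
                for j in block:
                    if i < j:
                        m[i, j] = m[j, i] = 1.0
        m[3, 4] = m[4, 3] = 0.1  # weak bridge
        part = communities_by_modularity(m, seed=0)
        groups = {}
        for node, cid in part.assignment.items():
            groups.setdefault(cid, set()).add(node)
        assert sorted(map(sorted, groups.values())) == [[0, 1, 2, 3], [4, 5, 6, 7]]
        best_q, _ = exhaustive_max_modularity(m)
        assert part.modularity == pytest.approx(best_q, abs=1e-9)

    def test_uniform_clique_single_community(self):
        m = np.ones((5, 5)) - np.eye(5)
        part = communities_by_modularity(m, seed=1)
        assert len(set(part.assignment.values())) == 1

    @pytest.mark.parametrize("seed", range(10))
    def test_never_below_trivial_partition(self, seed):
        rng = np.random.default_rng(100 + seed)
        m = random_weighted_graph(rng, 7)
        if not m.any():
            return
        part = communities_by_modularity(m, seed=seed)
        assert part.modularity >= 0.0 - 1e-12  # trivial partition has Q = 0


class TestHubReport:
    def test_star_center_is_rank_one(self):
        n = 6
        m = np.zeros((n, n))
        for j in range(1, n):
            m[0, j] = m[j, 0] = 1.0
        part = communities_by_modularity(m, seed=0)
        rep = hub_report(part, CAMMatrix(values=m), k=1)
        assert rep.top_hubs[0][0] == 0

    def test_ranking_matches_recomputed_strengths(self, rng):
        m = np.abs(random_symmetric(rng, 8))
        part = communities_by_modularity(m, seed=2)
        rep = hub_report(part, CAMMatrix(values=m), k=3)
        comm = part.assignment
        for cid, ranked in rep.per_community.items():
            members = [i for i, c in comm.items() if c == cid]
            strengths = {
                i: sum(m[i, j] for j in members if j != i) for i in members
            }
            expect = sorted(members, key=lambda i: (-strengths[i], i))
            assert [r for r, _ in ranked] == expect

    def test_invalid_k(self, rng):
        m = np.abs(random_symmetric(rng, 4))
        part = communities_by_modularity(m, seed=0)
        with pytest.raises(ValueError):
            hub_report(part, CAMMatrix(values=m), k=0)


class TestUnivariateRanking:
    def test_one_hot_and_tie_order(self):
        ranked = rank_univariate_cam([0, 0, 1, 0])
        assert ranked[0][0] == 2
        const = rank_univariate_cam([0.5, 0.5, 0.5])
        assert [r[0] for r in const] == [0, 1, 2]  # stable by region id

    def test_matches_sort_oracle(self, rng):
        v = rng.uniform(size=10)
        ranked = rank_univariate_cam(v)
        assert [r[0] for r in ranked] == list(np.argsort(-v, kind="stable"))

    def test_region_strength_helper(self, rng):
        m = np.abs(random_symmetric(rng, 5))
        assert np.allclose(cam_region_strength(CAMMatrix(values=m)), m.sum(axis=1))
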