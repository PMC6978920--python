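"""Graph construction and metrics against explicit oracles."""

import numpy as np
import pytest

from connectomaze.connectome import (
    BrainGraph,
    EmptyGraphError,
    R_CLIP,
    ConnectivityMatrix,
    correlation_matrix,
    graph_metrics,
    high_strength_subnetwork,
    rich_club_curve,
    seed_connectivity,
    threshold_density,
)
from connectomaze.types import RoiTimeSeriesSet
from conftest import random_brain_graph
from oracles import (
    clustering_onnela_brute,
    path_length_floyd,
    pearson_direct,
    rich_club_brute,
)


def _series(X, labels=None, dt=2.0):
    X = np.atleast_2d(np.asarray(X, dtype=float))
    labels = labels or [f"roi{i}" for i in range(X.shape[0])]
    return RoiTimeSeriesSet(signals=X, roi_labels=labels, dt=dt)


def _graph_from_weights(W, labels=None):
    labels = labels or [f"n{i}" for i in range(W.shape[0])]
    return BrainGraph(weights=np.asarray(W, dtype=float), roi_labels=labels,
                      density=1.0)


class TestCorrelationMatrix:
    def test_pair_count_identity_150_nodes(self):
        """A 150-node symmetric graph has n(n-1)/2 = 11,175 unique pairs."""
        rng = np.random.default_rng(0)
        s = _series(rng.normal(size=(150, 30)))
        cm = correlation_matrix(s)
        assert cm.n_pairs == 11175
        iu = np.triu_indices(150, 1)
        assert np.isfinite(cm.z_values[iu]).sum() == 11175

    def test_perfect_anticorrelation_hits_clip(self, rng):
        x = rng.normal(size=40)
        cm = correlation_matrix(_series(np.vstack([x, -x])), n_drop=0)
        assert cm.z_values[0, 1] == pytest.approx(np.arctanh(-R_CLIP))

    def test_matches_textbook_pearson(self):
        X = np.array([
            [1.2, 0.7, -0.3, 2.2, 1.1, 0.4, -1.0, 0.8, 1.9, 0.0],
            [0.9, 1.1, 0.2, 1.8, 0.7, 0.9, -0.4, 0.3, 1.5, 0.6],
            [-2.0, 0.5, 1.4, -0.7, 0.1, -1.2, 0.8, -0.9, -1.6, 0.2],
        ])
        cm = correlation_matrix(_series(X), n_drop=0)
        for i in range(3):
            for j in range(i + 1, 3):
                expected = np.arctanh(pearson_direct(X[i], X[j]))
                assert cm.z_values[i, j] == pytest.approx(expected, abs=1e-12)

    def test_first_volumes_dropped(self, rng):
        X = rng.normal(size=(2, 50))
        full = correlation_matrix(_series(X), n_drop=9)
        manual = np.arctanh(np.clip(pearson_direct(X[0, 9:], X[1, 9:]), -R_CLIP, R_CLIP))
        assert full.z_values[0, 1] == pytest.approx(manual, abs=1e-12)

    def test_constant_roi_flagged_not_zeroed(self, rng):
        X = np.vstack([rng.normal(size=30), np.full(30, 2.0), rng.normal(size=30)])
        cm = correlation_matrix(_series(X), n_drop=0)
        assert not cm.valid[1]
        assert np.isnan(cm.z_values[1, 0]) and np.isnan(cm.z_values[1, 2])
        assert np.isfinite(cm.z_values[0, 2])


class TestThresholdDensity:
    def _cm(self, z):
        n = z.shape[0]
        return ConnectivityMatrix(z_values=z, roi_labels=[f"r{i}" for i in range(n)])

    def test_full_density_keeps_all_pairs(self, rng):
        z = rng.normal(size=(6, 6)) + 2
        z = (z + z.T) / 2
        g = threshold_density(self._cm(z), density=1.0)
        assert g.n_edges == 15
        assert g.weights.max() == 1.0

    def test_150_nodes_15pct_keeps_1676_edges(self, rng):
        z = rng.normal(size=(150, 150))
        z = (z + z.T) / 2
        g = threshold_density(self._cm(z), density=0.15)
        assert g.n_edges == 1676  # floor(0.15 * 11175)
        assert g.meta["n_edges"] == 1676

    def test_requested_density_within_one_edge(self, rng):
        for n, d in [(10, 0.3), (25, 0.15), (40, 0.07)]:
            z = rng.normal(size=(n, n))
            z = (z + z.T) / 2
            g = threshold_density(self._cm(z), density=d)
            assert abs(g.n_edges - d * n * (n - 1) / 2) <= 1

    def test_tie_break_by_index_order(self):
        z = np.ones((4, 4))
        np.fill_diagonal(z, np.nan)
        g = threshold_density(self._cm(z), density=0.5)  # keep 3 of 6 equal edges
        kept = {tuple(e) for e in zip(*np.nonzero(np.triu(g.weights, 1)))}
        assert kept == {(0, 1), (0, 2), (0, 3)}
        assert "index" in g.meta["tie_break"]

    def test_zero_edge_density_raises(self, rng):
        z = rng.normal(size=(4, 4))
        z = (z + z.T) / 2
        with pytest.raises(EmptyGraphError):
            threshold_density(self._cm(z), density=0.01)

    def test_signed_ranking_prefers_positive(self):
        z = np.array([[np.nan, 0.9, -2.0], [0.9, np.nan, 0.5], [-2.0, 0.5, np.nan]])
        g = threshold_density(self._cm(z), density=1 / 3)
        assert g.weights[0, 1] == 1.0 and g.weights[0, 2] == 0.0


class TestGraphMetrics:
    def test_unit_triangle(self):
        W = np.array([[0, 1, 1], [1, 0, 1], [1, 1, 0]], dtype=float)
        gm = graph_metrics(_graph_from_weights(W))
        np.testing.assert_allclose(gm.strength, 2.0)
        np.testing.assert_allclose(gm.degree, 2)
        assert gm.clustering == pytest.approx(1.0)
        assert gm.path_length == pytest.approx(1.0)

    def test_unit_path_graph(self):
        W = np.array([[0, 1, 0], [1, 0, 1], [0, 1, 0]], dtype=float)
        gm = graph_metrics(_graph_from_weights(W))
        assert gm.degree[1] == 2
        assert gm.clustering == pytest.approx(0.0)
        # distances: 1,1,2 in both directions -> mean 4/3
        assert gm.path_length == pytest.approx(4 / 3)

    def test_path_length_matches_floyd_oracle(self):
        g = random_brain_graph(20, seed=5, p_edge=0.3)
        gm = graph_metrics(g)
        expected, frac = path_length_floyd(g.weights)
        assert gm.path_length == pytest.approx(expected, abs=1e-10)
        assert gm.frac_unreachable == pytest.approx(frac, abs=1e-12)

    def test_strength_bounded_by_degree(self):
        for seed in range(10):
            g = random_brain_graph(15, seed=seed, p_edge=0.4)
            gm = graph_metrics(g)
            assert np.all(gm.strength <= gm.degree + 1e-12)
        unit = _graph_from_weights((random_brain_graph(8, 3).weights > 0).astype(float))
        gm = graph_metrics(unit)
        np.testing.assert_allclose(gm.strength, gm.degree)

    def test_too_small_graph_rejected(self):
        with pytest.raises(ValueError, match="3 nodes"):
            graph_metrics(_graph_from_weights(np.zeros((2, 2))))

    def test_smallworldness_of_random_graph_near_one(self):
        """A random graph is its own degree-preserving null: sigma ~ 1."""
        g = random_brain_graph(30, seed=9, p_edge=0.3)
        gm = graph_metrics(g, n_nulls=20, rng_seed=0)
        assert 0.75 < gm.small_worldness < 1.3

    def test_smallworldness_elevated_for_clustered_graph(self):
        """A ring-lattice-like weighted graph has sigma well above 1."""
        n = 30
        W = np.zeros((n, n))
        for i in range(n):
            for step in (1, 2):
                j = (i + step) % n
                W[i, j] = W[j, i] = 1.0
        gm = graph_metrics(_graph_from_weights(W), n_nulls=20, rng_seed=1)
        assert gm.small_worldness > 1.5


class TestRichClub:
    def test_complete_graph_phi_one(self):
        W = 1.0 - np.eye(5)
        rc = rich_club_curve(_graph_from_weights(W), k_max=3)
        assert np.all(rc.defined)
        np.testing.assert_allclose(rc.phi, 1.0)

    def test_star_graph_undefined_above_one(self):
        W = np.zeros((6, 6))
        W[0, 1:] = W[1:, 0] = 1.0
        rc = rich_club_curve(_graph_from_weights(W), k_max=4)
        assert rc.defined[0]  # all six nodes have degree > 0
        assert not rc.defined[1:].any()  # only the hub survives k >= 1

    def test_defined_flags_monotone(self):
        for seed in range(20):
            g = random_brain_graph(10, seed=seed, p_edge=0.35)
            rc = rich_club_curve(g)
            d = rc.defined.astype(int)
            assert np.all(np.diff(d) <= 0)  # once undefined, stays undefined

    def test_planted_hub_graph_matches_enumeration(self):
        rng = np.random.default_rng(17)
        n = 12
        W = np.zeros((n, n))
        hubs = [0, 1, 2, 3]
        for i in hubs:  # dense, heavy core
            for j in hubs:
                if i < j:
                    W[i, j] = W[j, i] = 1.0
        for i in hubs:  # spokes
            for j in range(4, n):
                if rng.random() < 0.6:
                    W[i, j] = W[j, i] = rng.uniform(0.2, 0.8)
        rc = rich_club_curve(_graph_from_weights(W))
        for k, phi, defined in zip(rc.k_values, rc.phi, rc.defined):
            expected = rich_club_brute(W, int(k))
            if expected is None:
                assert not defined
            else:
                assert phi == pytest.approx(expected, abs=1e-12)

    def test_k_max_above_max_degree_rejected(self):
        g = random_brain_graph(8, seed=0)
        with pytest.raises(ValueError, match="k_max"):
            rich_club_curve(g, k_max=int(g.degree().max()) + 5)


class TestSeedConnectivity:
    def _cm(self):
        labels = ["ACC_L", "ACC_R", "DLS_L", "DLS_R", "DMS_L", "DMS_R"]
        z = np.full((6, 6), 0.1)
        z[0, 2] = z[2, 0] = 0.4  # ACC_L-DLS_L
        z[1, 3] = z[3, 1] = 0.6  # ACC_R-DLS_R
        z[0, 4] = z[4, 0] = 0.5
        z[1, 5] = z[5, 1] = 0.5
        np.fill_diagonal(z, np.nan)
        return ConnectivityMatrix(z_values=z, roi_labels=labels)

    def test_hemisphere_average(self):
        res = seed_connectivity(self._cm(), "ACC", ["DLS", "DMS"])
        by_target = {r.target_label: r for r in res}
        assert by_target["DLS"].z_mean == pytest.approx(0.5)
        assert by_target["DMS"].z_mean == pytest.approx(0.5)
        assert by_target["DLS"].z_left == pytest.approx(0.4)

    def test_invariant_to_roi_ordering(self, rng):
        cm = self._cm()
        perm = rng.permutation(6)
        cm2 = ConnectivityMatrix(
            z_values=cm.z_values[np.ix_(perm, perm)],
            roi_labels=[cm.roi_labels[i] for i in perm],
        )
        a = seed_connectivity(cm, "ACC", ["DLS"])[0]
        b = seed_connectivity(cm2, "ACC", ["DLS"])[0]
        assert (a.z_left, a.z_right) == (b.z_left, b.z_right)

    def test_unknown_seed_raises(self):
        with pytest.raises(KeyError, match="missing hemisphere"):
            seed_connectivity(self._cm(), "HPC", ["DLS"])


class TestHighStrengthSubnetwork:
    def test_empty_when_all_below_threshold(self):
        g = random_brain_graph(10, seed=1, p_edge=0.3)
        nodes, induced = high_strength_subnetwork([g], s_min=1e6)
        assert nodes == [] and induced.shape == (0, 0)

    def test_single_strong_node(self):
        W = np.zeros((5, 5))
        W[0, 1:] = W[1:, 0] = 1.0  # node 0 strength 4, rest 1
        g = _graph_from_weights(W)
        nodes, _ = high_strength_subnetwork([g], s_min=3.0)
        assert nodes == ["n0"]

    def test_recovers_planted_high_strength_nodes(self):
        """16 planted hub ROIs are exactly the recovered subnetwork."""
        from connectomaze.preprocess import preprocess_series
        from connectomaze.synth import TimeSeriesSimConfig, gen_roi_timeseries

        graphs = []
        for seed in range(3):
            cfg = TimeSeriesSimConfig(
                n_rois=60, n_volumes=300, hub_set=tuple(range(16)),
                hub_r=0.6, hub_out_r=0.3, rng_seed=seed,
            )
            s = gen_roi_timeseries(cfg)
            cm = correlation_matrix(preprocess_series(s))
            graphs.append(threshold_density(cm, density=0.15))
        mean_strength = np.mean([g.strength() for g in graphs], axis=0)
        s_min = np.sort(mean_strength)[-17]  # between hub and non-hub strengths
        nodes, _ = high_strength_subnetwork(graphs, s_min=s_min)
        expected = set(graphs[0].roi_labels[:16])
        assert set(nodes) == expected
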