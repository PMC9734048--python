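import networkx as nx
import numpy as np
import pytest

from neuroflex import (
    MultilayerNetwork,
    build_layer_stack,
    generalized_louvain,
    multilayer_modularity,
    node_flexibility,
    repeated_detection,
)
from neuroflex.errors import ConfigurationError, UndefinedQualityError

from _oracles import exhaustive_best_quality


def two_triangles():
    a = np.zeros((6, 6))
    for i, j in [(0, 1), (1, 2), (0, 2), (3, 4), (4, 5), (3, 5)]:
        a[i, j] = a[j, i] = 1.0
    return a


class TestMultilayerModularity:
    def test_single_community_single_layer_is_zero(self):
        net = MultilayerNetwork(two_triangles()[None], omega=1.0)
        q = multilayer_modularity(net, np.zeros((6, 1), dtype=int))
        assert q == pytest.approx(0.0, abs=1e-12)

    def test_relabeling_invariance(self, rng):
        weights = rng.uniform(0, 1, (2, 5, 5))
        weights = (weights + weights.transpose(0, 2, 1)) / 2
        for w in weights:
            np.fill_diagonal(w, 0.0)
        net = MultilayerNetwork(weights, omega=0.7)
        labels = rng.integers(0, 3, (5, 2))
        q1 = multilayer_modularity(net, labels)
        relabeled = 10 - labels  # bijective relabeling
        q2 = multilayer_modularity(net, relabeled)
        assert q1 == pytest.approx(q2, abs=1e-12)

    def test_undefined_when_everything_empty(self):
        net = MultilayerNetwork(np.zeros((2, 4, 4)), omega=0.0)
        with pytest.raises(UndefinedQualityError):
            multilayer_modularity(net, np.zeros((4, 2), dtype=int))

    def test_zero_weight_layer_keeps_coupling(self):
        layers = np.stack([two_triangles(), np.zeros((6, 6))])
        net = MultilayerNetwork(layers, omega=1.0)
        labels = np.repeat([[0], [0], [0], [1], [1], [1]], 2, axis=1)
        # numerator: intralayer 6 (layer 1 only) + coupling 12
        assert multilayer_modularity(net, labels) == pytest.approx(
            (6 + 12) / (12 + 12), abs=1e-12
        )

    def test_invalid_parameters(self):
        with pytest.raises(ConfigurationError):
            MultilayerNetwork(two_triangles()[None], omega=-0.1)
        with pytest.raises(ConfigurationError):
            MultilayerNetwork(two_triangles()[None], gamma=0.0)


class TestGeneralizedLouvain:
    def test_recovers_disconnected_triangles(self):
        net = MultilayerNetwork(two_triangles()[None], omega=1.0)
        res = generalized_louvain(net, seed=5)
        labels = res.labels[:, 0]
        assert len(set(labels[:3])) == 1 and len(set(labels[3:])) == 1
        assert labels[0] != labels[3]
        assert res.quality == pytest.approx(0.5, abs=1e-12)

    def test_quality_equals_reported_labels_quality(self):
        net = MultilayerNetwork(two_triangles()[None], omega=1.0)
        res = generalized_louvain(net, seed=9)
        assert multilayer_modularity(net, res.labels) == res.quality

    def test_matches_exhaustive_on_strong_two_layer_instance(self):
        tri = np.array([[0, 1, 1], [1, 0, 1], [1, 1, 0]], dtype=float)
        net = MultilayerNetwork(np.stack([tri, tri]), omega=2.0)
        best_q, _ = exhaustive_best_quality(net, multilayer_modularity)
        res = generalized_louvain(net, seed=1)
        assert res.quality == pytest.approx(best_q, abs=1e-12)
        # constant-across-layers partition under strong coupling
        assert np.all(res.labels[:, 0] == res.labels[:, 1])

    def test_never_beats_exhaustive_on_random_tiny_instances(self, rng):
        for trial in range(6):
            w, r = (1, 5) if trial % 2 else (2, 3)
            weights = rng.uniform(0, 1, (w, r, r))
            weights = (weights + weights.transpose(0, 2, 1)) / 2
            for lay in weights:
                np.fill_diagonal(lay, 0.0)
            net = MultilayerNetwork(weights, omega=float(rng.uniform(0, 2)))
            best_q, _ = exhaustive_best_quality(net, multilayer_modularity)
            res = generalized_louvain(net, seed=int(rng.integers(1000)))
            assert res.quality <= best_q + 1e-12

    def test_seed_determinism(self):
        net = MultilayerNetwork(two_triangles()[None], omega=1.0)
        a = generalized_louvain(net, seed=42)
        b = generalized_louvain(net, seed=42)
        np.testing.assert_array_equal(a.labels, b.labels)
        assert a.quality == b.quality

    def test_quality_at_least_singleton_quality(self, rng):
        weights = rng.uniform(0, 0.5, (3, 6, 6))
        weights = (weights + weights.transpose(0, 2, 1)) / 2
        for lay in weights:
            np.fill_diagonal(lay, 0.0)
        net = MultilayerNetwork(weights, omega=0.5)
        singleton = multilayer_modularity(
            net, np.arange(18).reshape(3, 6).T
        )
        res = generalized_louvain(net, seed=0)
        assert res.quality >= singleton - 1e-12

    def test_single_layer_agrees_with_networkx_louvain(self):
        # ring of three 4-cliques: planted partition both methods recover
        g = nx.ring_of_cliques(3, 4)
        a = nx.to_numpy_array(g)
        net = MultilayerNetwork(a[None], omega=0.0, gamma=1.0)
        res = generalized_louvain(net, seed=2)
        ours = {frozenset(np.flatnonzero(res.labels[:, 0] == c))
                for c in np.unique(res.labels[:, 0])}
        theirs = {frozenset(c) for c in
                  nx.community.louvain_communities(g, seed=4)}
        assert ours == theirs
        q_nx = nx.community.modularity(g, [set(c) for c in theirs])
        assert res.quality == pytest.approx(q_nx, abs=1e-12)


class TestRepeatedDetection:
    def test_single_repetition(self):
        net = MultilayerNetwork(two_triangles()[None], omega=1.0)
        out = repeated_detection(net, n_reps=1, master_seed=0)
        assert len(out) == 1

    def test_zero_reps_rejected(self):
        net = MultilayerNetwork(two_triangles()[None], omega=1.0)
        with pytest.raises(ConfigurationError):
            repeated_detection(net, n_reps=0)

    def test_master_seed_determinism(self):
        net = MultilayerNetwork(two_triangles()[None], omega=1.0)
        a = repeated_detection(net, n_reps=5, master_seed=3)
        b = repeated_detection(net, n_reps=5, master_seed=3)
        for x, y in zip(a, b):
            np.testing.assert_array_equal(x.labels, y.labels)
            assert x.quality == y.quality

    def test_well_separated_structure_stable_across_reps(self):
        layers = np.stack([two_triangles()] * 3)
        net = MultilayerNetwork(layers, omega=1.0)
        reps = repeated_detection(net, n_reps=10, master_seed=7)
        # co-assignment matrices identical across runs (partition equal up to relabeling)
        ref = reps[0].labels.ravel()
        ref_co = ref[:, None] == ref[None, :]
        for a in reps[1:]:
            flat = a.labels.ravel()
            np.testing.assert_array_equal(flat[:, None] == flat[None, :], ref_co)

    def test_strong_coupling_freezes_labels_over_time(self, rng, tiny_cohort):
        _, cohort = tiny_cohort
        stack = build_layer_stack(cohort.timeseries[0], width=30)
        loose = repeated_detection(MultilayerNetwork(stack, omega=0.1), 5, 1)
        tight = repeated_detection(MultilayerNetwork(stack, omega=50.0), 5, 1)
        flex_loose = np.mean([node_flexibility(a.labels).mean() for a in loose])
        flex_tight = np.mean([node_flexibility(a.labels).mean() for a in tight])
        assert flex_tight <= flex_loose
        assert flex_tight < 0.01
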