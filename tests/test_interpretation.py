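import numpy as np
import pandas as pd
import pytest
from scipy import stats

from deeplrp import (
    ExpressionDataset,
    LRPConfig,
    MLPNetwork,
    ProbeAnnotation,
    associate_genes,
    class_relevance_profile,
    cluster_relevance_vectors,
    extract_subnetwork,
    forward_trace,
    relevance_from_output,
    sample_relevance_matrix,
    select_important_connections,
    select_important_neurons,
    wm_scores,
)
from deeplrp.interpretation import (
    ClassRelevanceProfile,
    ImportantConnectionSet,
    ImportantNeuronSet,
    _mean_connection_matrices,
    neuron_id,
)
from deeplrp.lrp import connection_relevances
from deeplrp.synthetic import make_toy_network

EPS0 = LRPConfig(epsilon=0.0)


def _dataset(X, labels=None, classes=None):
    n, p = X.shape
    labels = labels or ["a"] * n
    classes = classes or sorted(set(labels))
    return ExpressionDataset(X, [f"s{i}" for i in range(n)],
                             [f"P{j}" for j in range(p)], labels, classes)


def _positive_net(rng, p, hidden=(5, 4), K=2):
    sizes = [p, *hidden, K]
    weights = [np.abs(rng.normal(size=(sizes[l], sizes[l + 1])))
               for l in range(len(sizes) - 1)]
    biases = [np.zeros(s) for s in sizes[1:]]
    return MLPNetwork(weights=weights, biases=biases, classes=["a", "b"])


class TestClassRelevanceProfile:
    def test_single_sample_profile_equals_its_vector(self, rng):
        net = _positive_net(rng, 6)
        X = np.abs(rng.normal(size=(1, 6)))
        ds = _dataset(X, ["a"], ["a", "b"])
        trace = forward_trace(net, X)
        k = int(trace.a[net.L][0].argmax())
        profile = class_relevance_profile(net, ds, k, EPS0)
        rvec = relevance_from_output(net, trace, k, EPS0)
        for l in profile.layers:
            np.testing.assert_allclose(profile.mean[l], rvec.relevances[l][0])
        assert profile.n_examples == 1

    def test_duplicated_sample_invariance(self, rng):
        net = _positive_net(rng, 6)
        x = np.abs(rng.normal(size=6))
        ds1 = _dataset(x[None, :], ["a"], ["a", "b"])
        ds3 = _dataset(np.tile(x, (3, 1)), ["a"] * 3, ["a", "b"])
        k = int(forward_trace(net, x).a[net.L][0].argmax())
        p1 = class_relevance_profile(net, ds1, k, EPS0)
        p3 = class_relevance_profile(net, ds3, k, EPS0)
        for l in p1.layers:
            np.testing.assert_allclose(p1.mean[l], p3.mean[l])

    def test_matches_per_sample_recompute(self, rng):
        net = _positive_net(rng, 5)
        X = np.abs(rng.normal(size=(10, 5)))
        ds = _dataset(X, ["a"] * 10, ["a", "b"])
        trace = forward_trace(net, X)
        preds = trace.a[net.L].argmax(axis=1)
        k = int(np.bincount(preds).argmax())
        profile = class_relevance_profile(net, ds, k, EPS0)
        idx = np.flatnonzero(preds == k)
        # independent recompute: one LRP call per sample, then plain average
        per_sample = [relevance_from_output(net, forward_trace(net, X[i]), k, EPS0)
                      for i in idx]
        for l in profile.layers:
            mean = np.mean([r.relevances[l][0] for r in per_sample], axis=0)
            np.testing.assert_allclose(profile.mean[l], mean, atol=1e-12)

    def test_no_predicted_samples_raises(self, rng):
        net = _positive_net(rng, 6)
        X = np.abs(rng.normal(size=(4, 6)))
        ds = _dataset(X, ["a"] * 4, ["a", "b"])
        preds = forward_trace(net, X).a[net.L].argmax(axis=1)
        missing = [k for k in range(2) if not np.any(preds == k)]
        if not missing:
            pytest.skip("both classes predicted in this draw")
        with pytest.raises(ValueError, match="no samples predicted"):
            class_relevance_profile(net, ds, missing[0], EPS0)

    def test_profile_linearity_over_merged_sets(self, rng):
        net = _positive_net(rng, 5)
        Xa = np.abs(rng.normal(size=(4, 5)))
        Xb = np.abs(rng.normal(size=(8, 5)))
        preds = forward_trace(net, np.vstack([Xa, Xb])).a[net.L].argmax(axis=1)
        k = int(np.bincount(preds).argmax())  # class predicted in every subset
        dsa, dsb = _dataset(Xa), _dataset(Xb)
        dsm = _dataset(np.vstack([Xa, Xb]))
        try:
            pa = class_relevance_profile(net, dsa, k, EPS0)
            pb = class_relevance_profile(net, dsb, k, EPS0)
        except ValueError:
            pytest.skip("majority class absent from one subset in this draw")
        pm = class_relevance_profile(net, dsm, k, EPS0)
        na, nb = pa.n_examples, pb.n_examples
        for l in pm.layers:
            weighted = (na * pa.mean[l] + nb * pb.mean[l]) / (na + nb)
            np.testing.assert_allclose(pm.mean[l], weighted, atol=1e-12)


def _profile_from_scores(scores):
    scores = np.asarray(scores, dtype=float)
    sigma = float(np.sqrt(np.mean(scores**2)))
    return ClassRelevanceProfile(
        class_index=0, class_name="a", n_examples=10,
        mean={0: scores, 1: np.zeros(2)}, sigma={0: sigma, 1: 0.0}, epsilon=0.0,
    )


class TestSelectImportantNeurons:
    def test_all_zero_scores_empty_with_warning(self):
        profile = _profile_from_scores(np.zeros(10))
        with pytest.warns(UserWarning, match="degenerate"):
            sel = select_important_neurons(profile, layers=[0])
        assert len(sel.entries) == 0

    def test_planted_outlier_exactly_recovered(self):
        rng = np.random.default_rng(42)
        scores = np.append(rng.normal(size=1000), 50.0)
        profile = _profile_from_scores(scores)
        sel = select_important_neurons(profile, alpha=0.05, layers=[0])
        assert sel.entries["index"].tolist() == [1000]
        # threshold computed explicitly: z_{1 - 0.025/1001} * sigma_hat
        sigma = np.sqrt(np.mean(scores**2))
        thr = stats.norm.isf(0.025 / 1001) * sigma
        assert np.isclose(sel.entries["threshold"].iloc[0], thr)
        assert 50.0 > thr > np.abs(scores[:1000]).max()

    def test_two_sided_symmetric_selection(self):
        scores = np.concatenate([np.full(1, 30.0), np.full(1, -30.0),
                                 np.random.default_rng(0).normal(size=200)])
        sel = select_important_neurons(_profile_from_scores(scores), layers=[0])
        assert set(sel.entries["index"]) == {0, 1}

    def test_alpha_monotonicity(self):
        rng = np.random.default_rng(3)
        scores = rng.standard_t(df=3, size=500) * 2
        profile = _profile_from_scores(scores)
        prev: set[int] = set()
        for alpha in (0.2, 0.1, 0.05, 0.01):
            got = set(select_important_neurons(profile, alpha=alpha,
                                               layers=[0]).entries["index"])
            if prev:
                assert got <= prev
            prev = got

    def test_sorted_by_absolute_score(self):
        scores = np.zeros(100)
        scores[[7, 3]] = [40.0, -60.0]
        sel = select_important_neurons(_profile_from_scores(scores), layers=[0])
        assert sel.entries["index"].tolist() == [3, 7]


class TestImportantConnections:
    def test_dominant_connection_ranked_first(self, rng):
        net, x = make_toy_network("two_input")
        ds = _dataset(np.tile(x, (5, 1)))
        sel = select_important_connections(net, ds, 0, EPS0, method="topk", top_k=2)
        first = sel.entries.iloc[0]
        assert (first["from_neuron"], first["to_neuron"]) == ("L0:N001", "L1:N000")
        assert np.isclose(first["mean_relevance"], 3.0)

    def test_mean_matches_per_sample_loop(self, rng):
        net = _positive_net(rng, 4, hidden=(3,))
        X = np.abs(rng.normal(size=(6, 4)))
        ds = _dataset(X)
        trace = forward_trace(net, X)
        preds = trace.a[net.L].argmax(axis=1)
        k = int(np.bincount(preds).argmax())
        means, n = _mean_connection_matrices(net, ds, k, EPS0)
        idx = np.flatnonzero(preds == k)
        maps = []
        for i in idx:
            t = forward_trace(net, X[i])
            r = relevance_from_output(net, t, k, EPS0)
            maps.append(connection_relevances(net, t, r))
        for m in means:
            ref = np.mean([mp.matrices[m][0] for mp in maps], axis=0)
            np.testing.assert_allclose(means[m], ref, atol=1e-12)

    def test_all_zero_relevance_empty(self):
        net, _ = make_toy_network("two_input")
        ds = _dataset(np.zeros((3, 2)))
        with pytest.warns(UserWarning, match="degenerate"):
            sel = select_important_connections(net, ds, 0, EPS0)
        assert len(sel.entries) == 0


class TestAssociateGenes:
    def test_selection_restricted_to_wired_inputs(self, rng):
        # neuron (1, 0) receives from inputs 0..2 only
        w1 = np.zeros((5, 2))
        w1[:3, 0] = [2.0, 1.0, 1.5]
        w1[:, 1] = rng.normal(size=5)
        w2 = np.ones((2, 2))
        net = MLPNetwork(weights=[w1, w2], biases=[np.zeros(2), np.zeros(2)])
        X = np.abs(rng.normal(size=(8, 5))) + 0.5
        ds = _dataset(X, ["a"] * 8, ["a", "b"])
        ann = ProbeAnnotation({f"P{j}": f"G{j}" for j in range(5)})
        preds = forward_trace(net, X).a[2].argmax(axis=1)
        k = int(np.bincount(preds).argmax())
        assoc = associate_genes(net, ds, k, (1, 0), ann, EPS0, alpha=0.5)
        assert set(assoc.probes["probe_id"]) <= {"P0", "P1", "P2"}
        assert set(assoc.genes) <= {"G0", "G1", "G2"}

    def test_unmapped_probes_kept_in_probe_list_only(self, rng):
        net = _positive_net(rng, 4, hidden=(3,))
        X = np.abs(rng.normal(size=(6, 4)))
        ds = _dataset(X)
        ann = ProbeAnnotation({"P0": "G0", "P1": "G1"})  # P2, P3 unmapped
        preds = forward_trace(net, X).a[net.L].argmax(axis=1)
        k = int(np.bincount(preds).argmax())
        assoc = associate_genes(net, ds, k, (1, 0), ann, EPS0, alpha=0.9)
        assert set(assoc.genes) <= {"G0", "G1"}
        assert len(assoc.probes) >= len(assoc.genes)

    def test_dead_neuron_gives_empty_association(self):
        w1 = np.array([[-1.0, 1.0]])
        w2 = np.array([[1.0, 0.0], [1.0, 1.0]])
        net = MLPNetwork(weights=[w1, w2], biases=[np.zeros(2), np.zeros(2)])
        ds = _dataset(np.full((3, 1), 2.0))
        ann = ProbeAnnotation({"P0": "G0"})
        preds = forward_trace(net, ds.X).a[2].argmax(axis=1)
        assoc = associate_genes(net, ds, int(preds[0]), (1, 0), ann, EPS0)
        assert len(assoc.probes) == 0 and assoc.genes == []


class TestWMScores:
    def test_variants(self):
        net = MLPNetwork(weights=[np.array([[2.0, -2.0]])], biases=[np.zeros(2)])
        assert wm_scores(net, 0, "mean_abs_outgoing").scores[0] == 2.0
        assert wm_scores(net, 0, "sum_outgoing").scores[0] == 0.0
        assert wm_scores(net, 0, "sum_abs_outgoing").scores[0] == 4.0

    def test_random_net_matches_row_statistics(self, rng):
        net = _positive_net(rng, 5)
        for layer in range(net.L):
            w = net.weights[layer]
            np.testing.assert_allclose(wm_scores(net, layer).scores,
                                       np.abs(w).mean(axis=1))

    def test_wm_data_independent_lrp_not(self, rng):
        # mixed-sign weights so the ReLU states differ across samples (a
        # fully linear regime would make the mean profile depend on column
        # means only, which survive the shuffle below)
        sizes = [6, 5, 4, 2]
        net = MLPNetwork(
            weights=[rng.normal(size=(sizes[l], sizes[l + 1])) for l in range(3)],
            biases=[rng.normal(size=s) * 0.1 for s in sizes[1:]],
        )
        X = rng.normal(size=(12, 6))
        # break the sample structure by shuffling every probe independently
        X_shuffled = np.column_stack([rng.permutation(X[:, j]) for j in range(6)])
        wm_before = wm_scores(net, 0).scores
        # WM ignores the data entirely, so any dataset gives the same scores
        np.testing.assert_array_equal(wm_before, wm_scores(net, 0).scores)
        preds = forward_trace(net, X).a[net.L].argmax(axis=1)
        k = int(np.bincount(preds).argmax())
        p1 = class_relevance_profile(net, _dataset(X), k, EPS0)
        try:
            p2 = class_relevance_profile(net, _dataset(X_shuffled), k, EPS0)
        except ValueError:
            return  # predictions themselves changed: LRP clearly data-dependent
        assert not np.allclose(p1.mean[0], p2.mean[0])

    def test_fig3_style_inversion(self):
        # high-weight/low-activation input wins under WM, the well-propagated
        # input wins under LRP
        net, x = make_toy_network("fig3_style")
        wm = wm_scores(net, 0).scores
        rvec = relevance_from_output(net, forward_trace(net, x), 0, EPS0)
        lrp = rvec.input_relevances()[0]
        assert wm.argmax() != lrp.argmax()
        assert lrp.argmax() == 2  # i3, the well-propagated path


class TestClustering:
    def test_two_identical_groups_recovered(self):
        v = np.vstack([np.tile([1.0, 0.0], (4, 1)), np.tile([0.0, 5.0], (3, 1))])
        vectors = pd.DataFrame(v, index=[f"s{i}" for i in range(7)])
        res = cluster_relevance_vectors(vectors, k=2)
        labels = res.labels
        assert len(set(labels[:4])) == 1 and len(set(labels[4:])) == 1
        assert labels[0] != labels[-1]
        assert res.linkage.shape == (6, 4)

    def test_identical_vectors_single_cluster(self):
        vectors = pd.DataFrame(np.ones((5, 3)))
        res = cluster_relevance_vectors(vectors, k=None, height=0.5)
        assert len(set(res.labels)) == 1

    def test_k_exceeding_samples_rejected(self):
        vectors = pd.DataFrame(np.eye(3))
        with pytest.raises(ValueError, match="exceeds"):
            cluster_relevance_vectors(vectors, k=5)

    def test_sample_relevance_matrix_shapes(self, rng):
        net = _positive_net(rng, 6)
        X = np.abs(rng.normal(size=(10, 6)))
        ds = _dataset(X, ["a"] * 10, ["a", "b"])
        preds = forward_trace(net, X).a[net.L].argmax(axis=1)
        k = int(np.bincount(preds).argmax())
        vectors, meta = sample_relevance_matrix(net, ds, k, EPS0)
        assert len(vectors) == int((preds == k).sum())
        assert vectors.shape[1] == 6 + 5 + 4  # all layers below the output
        assert list(meta.columns) == ["label", "predicted", "correct"]


class TestSubnetwork:
    def _neurons(self, entries):
        df = pd.DataFrame(entries, columns=["neuron", "layer", "index",
                                            "mean_score", "standardized",
                                            "threshold"])
        return ImportantNeuronSet(class_index=0, class_name="a", alpha=0.05,
                                  entries=df)

    def _connections(self, entries):
        df = pd.DataFrame(entries, columns=["layer_from", "from_index", "to_index",
                                            "from_neuron", "to_neuron",
                                            "mean_relevance"])
        return ImportantConnectionSet(class_index=0, class_name="a", alpha=0.05,
                                      entries=df)

    def test_two_neurons_one_connection(self):
        neurons = self._neurons([
            (neuron_id(1, 2), 1, 2, 5.0, 10.0, 1.0),
            (neuron_id(2, 0), 2, 0, 4.0, 9.0, 1.0),
        ])
        conns = self._connections([
            (1, 2, 0, neuron_id(1, 2), neuron_id(2, 0), 3.0),
        ])
        sub = extract_subnetwork(neurons, conns)
        assert len(sub.nodes) == 3  # two neurons + class output neuron
        assert sub.nodes["is_output"].sum() == 1
        assert len(sub.edges) == 1

    def test_unselected_endpoint_dropped(self):
        neurons = self._neurons([(neuron_id(1, 2), 1, 2, 5.0, 10.0, 1.0)])
        conns = self._connections([
            (0, 9, 2, neuron_id(0, 9), neuron_id(1, 2), 3.0),  # L0:N009 unselected
        ])
        sub = extract_subnetwork(neurons, conns)
        assert len(sub.edges) == 0

    def test_empty_sets_valid(self):
        sub = extract_subnetwork(self._neurons([]), self._connections([]))
        assert len(sub.nodes) == 0 and len(sub.edges) == 0

    def test_mismatched_classes_rejected(self):
        neurons = self._neurons([])
        conns = self._connections([])
        conns.class_index = 1
        with pytest.raises(ValueError, match="different classes"):
            extract_subnetwork(neurons, conns)
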