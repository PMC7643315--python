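import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from deeplrp import (
    LRPConfig,
    MLPNetwork,
    connection_relevances,
    forward_trace,
    relevance_from_hidden,
    relevance_from_output,
)
from deeplrp.experiments import random_relu_network
from deeplrp.lrp import _propagate
from deeplrp.reference import naive_relevance
from deeplrp.synthetic import make_toy_network

EPS0 = LRPConfig(epsilon=0.0)


def _random_case(rng, **kwargs):
    """Random net + input with a start score bounded away from 0."""
    while True:
        net = random_relu_network(rng, **kwargs)
        x = rng.normal(size=net.n_inputs)
        trace = forward_trace(net, x)
        if abs(trace.z[net.L][0, 0]) > 0.1:
            return net, x, trace


class TestBasicExamples:
    def test_single_path_conservation(self):
        net, x = make_toy_network("single_path")
        rvec = relevance_from_output(net, forward_trace(net, x), 0, EPS0)
        assert rvec.start_relevance[0] == 6.0
        assert rvec.input_relevances()[0, 0] == 6.0

    def test_two_input_proportional_split(self):
        net, x = make_toy_network("two_input")
        rvec = relevance_from_output(net, forward_trace(net, x), 0, EPS0)
        np.testing.assert_allclose(rvec.input_relevances()[0], [1.0, 3.0])

    def test_linear_closed_form_exact(self, rng):
        w = rng.normal(size=(6, 2))
        net = MLPNetwork(weights=[w], biases=[np.zeros(2)])
        x = rng.normal(size=6)
        trace = forward_trace(net, x)
        for k in range(2):
            rvec = relevance_from_output(net, trace, k, EPS0)
            assert np.array_equal(rvec.input_relevances()[0], x * w[:, k])


class TestConservation:
    @pytest.mark.parametrize("seed", range(10))
    def test_zero_bias_sums_to_start(self, seed):
        rng = np.random.default_rng(seed)
        net, x, trace = _random_case(rng, zero_bias=True)
        rvec = relevance_from_output(net, trace, 0, EPS0)
        start = rvec.start_relevance[0]
        for layer in range(net.L):
            total = rvec.relevances[layer][0].sum()
            assert abs(total - start) <= 1e-9 * abs(start)

    @pytest.mark.parametrize("seed", range(10))
    def test_bias_accounting(self, seed):
        rng = np.random.default_rng(100 + seed)
        net, x, trace = _random_case(rng, zero_bias=False)
        rvec = relevance_from_output(net, trace, 0, EPS0)
        start = abs(rvec.start_relevance[0])
        for layer in range(net.L):
            assert abs(rvec.conservation_residual(layer)[0]) <= 1e-9 * start

    def test_hidden_target_conservation(self, rng):
        net, x, trace = _random_case(rng)
        layer = 1
        # pick an active neuron if any
        active = np.flatnonzero(trace.a[layer][0] > 0)
        if len(active) == 0:
            pytest.skip("no active neuron in this draw")
        i = int(active[0])
        rvec = relevance_from_hidden(net, trace, layer, i, EPS0)
        total = rvec.relevances[0][0].sum() + rvec.bias_absorbed[1][0]
        a_i = trace.a[layer][0, i]
        assert abs(total - a_i) <= 1e-9 * a_i

    @settings(derandomize=True, max_examples=25, deadline=None)
    @given(st.integers(0, 10_000), st.floats(0.5, 3.0))
    def test_conservation_any_draw_and_input_scale(self, seed, scale):
        """Exact conservation holds for arbitrary random nets and input
        scalings (the propagation is scale-covariant)."""
        rng = np.random.default_rng(seed)
        net, x, trace = _random_case(rng, zero_bias=True)
        trace = forward_trace(net, scale * x)
        rvec = relevance_from_output(net, trace, 0, EPS0)
        start = rvec.start_relevance[0]
        if abs(start) < 1e-6:
            return  # degenerate draw after rescaling
        for layer in range(net.L):
            total = rvec.relevances[layer][0].sum()
            assert abs(total - start) <= 1e-9 * abs(start)

    def test_scaling_linearity(self, rng):
        net, x, trace = _random_case(rng)
        L = net.L
        r_start = np.zeros_like(trace.z[L])
        r_start[:, 0] = trace.z[L][:, 0]
        rel1, bias1 = _propagate(net, trace, L, r_start, EPS0)
        rel3, bias3 = _propagate(net, trace, L, 3.0 * r_start, EPS0)
        for l in rel1:
            np.testing.assert_allclose(rel3[l], 3.0 * rel1[l], rtol=1e-12)
        for m in bias1:
            np.testing.assert_allclose(bias3[m], 3.0 * bias1[m], rtol=1e-12)


class TestOracleEquivalence:
    @pytest.mark.parametrize("seed,epsilon", [(s, e) for s in range(6)
                                              for e in (0.0, 1e-9)])
    def test_matches_naive_recursion(self, seed, epsilon):
        rng = np.random.default_rng(2000 + seed)
        net, x, trace = _random_case(rng, max_width=5)
        cfg = LRPConfig(epsilon=epsilon)
        rvec = relevance_from_output(net, trace, 0, cfg)
        start = np.zeros(net.n_outputs)
        start[0] = trace.z[net.L][0, 0]
        ref, ref_bias = naive_relevance(net.weights, net.biases, x, net.L, start,
                                        epsilon=epsilon)
        for l, vals in ref.items():
            np.testing.assert_allclose(rvec.relevances[l][0], vals, atol=1e-10)
        for m, share in ref_bias.items():
            assert abs(rvec.bias_absorbed[m][0] - share) <= 1e-10


class TestEpsilonBehaviour:
    def test_epsilon_continuity(self):
        rng = np.random.default_rng(77)
        while True:
            net, x, trace = _random_case(rng)
            if min(abs(trace.z[l]).min() for l in trace.z) > 0.05:
                break
        r0 = relevance_from_output(net, trace, 0, EPS0).input_relevances()
        devs = []
        for eps in (1e-6, 1e-9, 1e-12):
            r = relevance_from_output(net, trace, 0,
                                      LRPConfig(epsilon=eps)).input_relevances()
            devs.append(float(np.abs(r - r0).max()))
        assert devs[0] >= devs[1] >= devs[2]
        assert devs[2] < 1e-9

    def test_epsilon0_degenerate_raises(self):
        # force nonzero relevance onto a neuron with exactly zero pre-activation
        net = MLPNetwork(weights=[np.array([[1.0], [-1.0]])], biases=[np.zeros(1)])
        trace = forward_trace(net, np.array([1.0, 1.0]))  # z = 0
        assert trace.z[1][0, 0] == 0.0
        with pytest.raises(ZeroDivisionError, match="neuron 0"):
            _propagate(net, trace, 1, np.array([[5.0]]), EPS0)

    def test_negative_epsilon_rejected(self):
        with pytest.raises(ValueError):
            LRPConfig(epsilon=-1e-9)


class TestHiddenTargets:
    def test_dead_neuron_all_zero(self):
        w1 = np.array([[-1.0, 1.0]])
        w2 = np.array([[1.0], [1.0]])
        net = MLPNetwork(weights=[w1, w2], biases=[np.zeros(2), np.zeros(1)])
        trace = forward_trace(net, np.array([2.0]))
        assert trace.a[1][0, 0] == 0.0  # ReLU-dead
        rvec = relevance_from_hidden(net, trace, 1, 0, EPS0)
        assert np.all(rvec.input_relevances() == 0.0)

    def test_layer_bounds_checked(self):
        net, x = make_toy_network("fig3_style")
        trace = forward_trace(net, x)
        with pytest.raises(ValueError, match="hidden layer"):
            relevance_from_hidden(net, trace, 2, 0)


class TestConnectionRelevances:
    def test_two_input_connection_values(self):
        net, x = make_toy_network("two_input")
        trace = forward_trace(net, x)
        rvec = relevance_from_output(net, trace, 0, EPS0)
        cmap = connection_relevances(net, trace, rvec)
        np.testing.assert_allclose(cmap.matrices[1][0, :, 0], [1.0, 3.0])

    def test_zero_input_all_zero(self):
        net, _ = make_toy_network("two_input")
        trace = forward_trace(net, np.zeros(2))
        rvec = relevance_from_output(net, trace, 0, EPS0)
        cmap = connection_relevances(net, trace, rvec)
        assert np.all(cmap.matrices[1] == 0.0)

    def test_internal_consistency(self, rng):
        net, x, trace = _random_case(rng, zero_bias=True)
        rvec = relevance_from_output(net, trace, 0, EPS0)
        cmap = connection_relevances(net, trace, rvec)
        for m, mat in cmap.matrices.items():
            # column sums reproduce R_j of the upper layer (zero biases)
            np.testing.assert_allclose(mat[0].sum(axis=0), rvec.relevances[m][0],
                                       atol=1e-10)
            # row sums over outgoing connections reproduce R_i of the lower layer
            np.testing.assert_allclose(mat[0].sum(axis=1),
                                       rvec.relevances[m - 1][0], atol=1e-10)
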