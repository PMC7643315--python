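"""Layer-wise relevance propagation (epsilon rule) for the perceptron.

Relevance starts at a target neuron and is redistributed backwards,
proportionally to the signal each connection carried in the forward pass.
With z_ij = a_i^(l) * w_ij the signal from neuron i of layer l into neuron
j of layer l+1, and z_j the pre-activation of j, the rules are

    R_{i<-j} = R_j * z_ij / (z_j + eps * sign(z_j))       (connection)
    R_i^(l)  = sum_j R_{i<-j}                              (neuron)

For an output target the start value is the *pre-softmax* score
R_k^(L) = z_k^(L); for a hidden target it is the activation a_i^(l). The
bias of each neuron also receives its proportional share
R_j * b_j / (z_j + eps * sign(z_j)); having no upstream inputs, that share
terminates there and is tracked per layer as "bias-absorbed" relevance so
the conservation identity

    R_target = sum_i R_i^(l) + sum_{m > l} bias_absorbed(m)

holds exactly when eps = 0. With eps > 0 conservation is relaxed in
exchange for numerical stability near z_j = 0. ``sign(0)`` is taken as +1;
under ReLU a neuron with z_j = 0 has zero activation and hence zero
relevance, so the convention only matters for the degenerate eps = 0 case,
which raises instead of dividing by zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .mlp import ForwardTrace, MLPNetwork

__all__ = [
    "LRPConfig",
    "RelevanceVector",
    "ConnectionRelevanceMap",
    "relevance_from_output",
    "relevance_from_hidden",
    "connection_relevances",
]


@dataclass
class LRPConfig:
    """epsilon: stabilizer added to the denominators (0 allowed, exact
    conservation, but degenerate pre-activations then raise)."""

    epsilon: float = 1e-9

    def __post_init__(self) -> None:
        if self.epsilon < 0:
            raise ValueError("epsilon must be >= 0")


@dataclass
class RelevanceVector:
    """Relevances of every neuron below (and at) the propagation target.

    ``relevances[l]`` has shape (n_examples, n_l); ``bias_absorbed[m]``
    (shape (n_examples,)) is the relevance captured by the biases of layer m
    while propagating into layer m-1. ``target`` records where propagation
    started: ``("output", k)`` or ``("hidden", layer, neuron)``.
    """

    target: tuple
    relevances: dict[int, np.ndarray]
    bias_absorbed: dict[int, np.ndarray]
    epsilon: float

    @property
    def start_layer(self) -> int:
        return max(self.relevances)

    @property
    def n_examples(self) -> int:
        return self.relevances[self.start_layer].shape[0]

    @property
    def start_relevance(self) -> np.ndarray:
        """The propagated quantity per example (z_k for output targets,
        a_i for hidden targets)."""
        return self.relevances[self.start_layer].sum(axis=1)

    def input_relevances(self) -> np.ndarray:
        return self.relevances[0]

    def conservation_residual(self, layer: int) -> np.ndarray:
        """start relevance minus (neuron sum at ``layer`` + bias absorbed
        above it); zero up to floating point when epsilon = 0."""
        total = self.relevances[layer].sum(axis=1)
        for m, shares in self.bias_absorbed.items():
            if m > layer:
                total = total + shares
        return self.start_relevance - total


@dataclass
class ConnectionRelevanceMap:
    """Per-layer matrices of connection relevances R_{i<-j}.

    ``matrices[m]`` has shape (n_examples, n_{m-1}, n_m): the relevance of
    the connection from neuron i of layer m-1 into neuron j of layer m.
    Summing over i recovers R_j minus the bias share of neuron j.
    """

    matrices: dict[int, np.ndarray]
    epsilon: float


def _stabilized(z: np.ndarray, epsilon: float) -> np.ndarray:
    return np.where(z >= 0, z + epsilon, z - epsilon)


def _propagate(network: MLPNetwork, trace: ForwardTrace, start_layer: int,
               r_start: np.ndarray, config: LRPConfig):
    """Run the epsilon rule from ``start_layer`` down to the input layer."""
    eps = config.epsilon
    relevances = {start_layer: r_start}
    bias_absorbed: dict[int, np.ndarray] = {}
    r_upper = r_start
    for m in range(start_layer, 0, -1):
        z = trace.z[m]
        if eps == 0.0:
            bad = (z == 0.0) & (r_upper != 0.0)
            if bad.any():
                _, j = np.argwhere(bad)[0]
                raise ZeroDivisionError(
                    f"epsilon=0 with zero pre-activation and nonzero relevance "
                    f"at layer {m}, neuron {j}"
                )
            denom = np.where(z == 0.0, 1.0, z)  # neutral where relevance is 0
        else:
            denom = _stabilized(z, eps)
        factor = r_upper / denom
        r_lower = trace.a[m - 1] * (factor @ network.weights[m - 1].T)
        bias_absorbed[m] = factor @ network.biases[m - 1]
        relevances[m - 1] = r_lower
        r_upper = r_lower
    return relevances, bias_absorbed


def _check_trace(network: MLPNetwork, trace: ForwardTrace) -> None:
    if trace.L != network.L or trace.a[0].shape[1] != network.n_inputs:
        raise ValueError("trace does not match network architecture")


def relevance_from_output(network: MLPNetwork, trace: ForwardTrace, class_k: int,
                          config: LRPConfig | None = None) -> RelevanceVector:
    """Backpropagate the pre-softmax score z_k^(L) of output neuron k.

    The resulting input-layer relevances R_j^(0) quantify each probe's
    contribution to the class-k score for every example in the trace.
    """
    config = config or LRPConfig()
    _check_trace(network, trace)
    K = network.n_outputs
    if not 0 <= class_k < K:
        raise ValueError(f"class index {class_k} out of range for {K} outputs")
    L = network.L
    r_start = np.zeros_like(trace.z[L])
    r_start[:, class_k] = trace.z[L][:, class_k]
    relevances, bias_absorbed = _propagate(network, trace, L, r_start, config)
    return RelevanceVector(
        target=("output", class_k),
        relevances=relevances,
        bias_absorbed=bias_absorbed,
        epsilon=config.epsilon,
    )


def relevance_from_hidden(network: MLPNetwork, trace: ForwardTrace, layer: int,
                          neuron: int, config: LRPConfig | None = None) -> RelevanceVector:
    """Backpropagate the activation a_i^(l) of a hidden neuron to the inputs.

    Only layers below ``layer`` are populated. A ReLU-inactive neuron
    (a_i = 0) yields a valid all-zero relevance vector.
    """
    config = config or LRPConfig()
    _check_trace(network, trace)
    if not 1 <= layer <= network.L - 1:
        raise ValueError(f"hidden layer must be in [1, {network.L - 1}], got {layer}")
    n_l = network.layer_sizes[layer]
    if not 0 <= neuron < n_l:
        raise ValueError(f"neuron {neuron} out of range for layer {layer} (size {n_l})")
    r_start = np.zeros_like(trace.a[layer])
    r_start[:, neuron] = trace.a[layer][:, neuron]
    relevances, bias_absorbed = _propagate(network, trace, layer, r_start, config)
    return RelevanceVector(
        target=("hidden", layer, neuron),
        relevances=relevances,
        bias_absorbed=bias_absorbed,
        epsilon=config.epsilon,
    )


def connection_relevances(network: MLPNetwork, trace: ForwardTrace,
                          rvec: RelevanceVector) -> ConnectionRelevanceMap:
    """Materialize R_{i<-j} for every connection below the target.

    For each propagated layer m, ``matrices[m][s, i, j]`` is the relevance
    example s sends from neuron j of layer m back to neuron i of layer m-1.
    """
    _check_trace(network, trace)
    eps = rvec.epsilon
    matrices: dict[int, np.ndarray] = {}
    for m in range(rvec.start_layer, 0, -1):
        z = trace.z[m]
        r_upper = rvec.relevances[m]
        if eps == 0.0:
            denom = np.where(z == 0.0, 1.0, z)
        else:
            denom = _stabilized(z, eps)
        factor = r_upper / denom  # (n, n_m)
        # R_{i<-j} = a_i * w_ij * factor_j
        matrices[m] = trace.a[m - 1][:, :, None] * network.weights[m - 1][None, :, :] \
            * factor[:, None, :]
    return ConnectionRelevanceMap(matrices=matrices, epsilon=eps)
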