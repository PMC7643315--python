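"""Straightforward per-connection reference implementations used to validate
the vectorized forward pass and relevance propagation.

Everything here is written with explicit Python loops over neurons and
connections, sharing no code with :mod:`deeplrp.mlp` or :mod:`deeplrp.lrp`,
so agreement between the two routes is a meaningful check rather than a
tautology. These functions are O(neurons^2) per layer and intended for tiny
networks only.
"""

from __future__ import annotations

import math

import numpy as np

__all__ = ["naive_forward", "naive_relevance", "naive_hypergeom_tail"]


def naive_forward(weights, biases, x):
    """Scalar-loop forward pass; returns per-layer (z, a) lists.

    ``a[0]`` is the input; hidden layers apply ReLU; the last layer is
    linear (no softmax — relevance propagation starts from z anyway).
    """
    L = len(weights)
    a = [list(map(float, x))]
    z = [None]
    for l in range(1, L + 1):
        w, b = weights[l - 1], biases[l - 1]
        n_out = len(b)
        zl = []
        for j in range(n_out):
            s = float(b[j])
            for i in range(len(a[l - 1])):
                s += a[l - 1][i] * float(w[i][j])
            zl.append(s)
        z.append(zl)
        if l < L:
            a.append([max(0.0, v) for v in zl])
        else:
            a.append(list(zl))
    return z, a


def naive_relevance(weights, biases, x, start_layer, start_values, epsilon=0.0):
    """Per-connection recursive relevance propagation for one example.

    ``start_values`` is the full relevance vector of ``start_layer``
    (zeros except at the target). Returns ``(relevances, bias_absorbed)``
    as dicts keyed by layer, matching the conventions of
    :class:`deeplrp.lrp.RelevanceVector` but computed with explicit loops.
    """
    z, a = naive_forward(weights, biases, x)
    relevances = {start_layer: [float(v) for v in start_values]}
    bias_absorbed: dict[int, float] = {}
    for m in range(start_layer, 0, -1):
        upper = relevances[m]
        w, b = weights[m - 1], biases[m - 1]
        n_in = len(a[m - 1])
        lower = [0.0] * n_in
        bias_share = 0.0
        for j in range(len(upper)):
            r_j = upper[j]
            if r_j == 0.0:
                continue
            zj = z[m][j]
            if epsilon == 0.0:
                if zj == 0.0:
                    raise ZeroDivisionError(
                        f"zero pre-activation with nonzero relevance at layer {m}, "
                        f"neuron {j}"
                    )
                denom = zj
            else:
                denom = zj + epsilon * (1.0 if zj >= 0.0 else -1.0)
            for i in range(n_in):
                lower[i] += r_j * (a[m - 1][i] * float(w[i][j])) / denom
            bias_share += r_j * float(b[j]) / denom
        bias_absorbed[m] = bias_share
        relevances[m - 1] = lower
    return relevances, bias_absorbed


def naive_hypergeom_tail(T, M, N_G, N_term):
    """P(t >= T) by direct summation of exact rational binomial terms."""
    total = 0.0
    denom = math.comb(N_G, M)
    for t in range(T, min(M, N_term) + 1):
        if M - t > N_G - N_term:
            continue
        total += math.comb(N_term, t) * math.comb(N_G - N_term, M - t) / denom
    return total
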