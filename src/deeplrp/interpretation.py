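"""Model-level interpretation built on top of per-example LRP.

The pipeline, per predicted class c_k:

1. run LRP from the predicted output neuron for every test example
   predicted as c_k and average, giving a class relevance profile
   R_hat_{i,k}^(l) per neuron;
2. treat each layer's profile as draws from a zero-centred Gaussian null
   N(0, sigma_k^(l)) — sigma estimated around 0 from the layer's own scores
   — and keep the neurons whose two-sided tail probability falls below a
   Bonferroni-corrected 0.05 (the "important" neurons). The same outlier
   test selects important connections (over the population of connections
   between two layers) and, after backpropagating a hidden neuron's
   activation, the important input probes, which are then mapped to genes;
3. optionally cluster per-example relevance vectors (hierarchical
   clustering) and extract the subnetwork spanned by the important neurons
   and connections.

A weight-magnitude (WM) baseline — importance of a neuron as a statistic of
its outgoing weights, independent of any data — is provided for comparison.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

from .data_io import ExpressionDataset, ProbeAnnotation
from .lrp import LRPConfig, relevance_from_hidden, relevance_from_output
from .mlp import MLPNetwork, forward_trace

__all__ = [
    "ClassRelevanceProfile",
    "ImportantNeuronSet",
    "ImportantConnectionSet",
    "NeuronGeneAssociation",
    "WMScores",
    "RelevanceClustering",
    "Subnetwork",
    "neuron_id",
    "class_relevance_profile",
    "sample_relevance_matrix",
    "select_important_neurons",
    "select_important_connections",
    "associate_genes",
    "wm_scores",
    "cluster_relevance_vectors",
    "extract_subnetwork",
]

WM_VARIANTS = ("mean_abs_outgoing", "sum_outgoing", "sum_abs_outgoing")


def neuron_id(layer: int, index: int) -> str:
    """Canonical neuron identifier, e.g. ``L1:N026`` (L0 = input layer)."""
    return f"L{layer}:N{index:03d}"


def _sigma_around_zero(scores: np.ndarray) -> float:
    """Standard deviation of the zero-centred Gaussian null, i.e. the RMS of
    the scores (the null mean is fixed at 0, not estimated)."""
    return float(np.sqrt(np.mean(np.square(scores))))


def _outlier_threshold(sigma: float, n_tests: int, alpha: float, stat: str,
                       df: int | None = None) -> float:
    """|score| must exceed this for a two-sided Bonferroni-corrected test at
    level ``alpha`` over ``n_tests`` comparisons under N(0, sigma)."""
    tail = alpha / (2.0 * n_tests)
    if stat == "z":
        return sigma * float(stats.norm.isf(tail))
    if stat == "t":
        return sigma * float(stats.t.isf(tail, df if df is not None else n_tests - 1))
    raise ValueError(f"unknown test statistic {stat!r}")


# ---------------------------------------------------------------------------
# class relevance profiles


@dataclass
class ClassRelevanceProfile:
    """Per-neuron mean relevance over the samples predicted as one class.

    ``mean[l]`` (length n_l) is R_hat_{i,k}^(l); ``sigma[l]`` the empirical
    standard deviation of that layer's mean scores around 0, which
    parameterizes the Gaussian null used for selection.
    """

    class_index: int
    class_name: str | None
    n_examples: int
    mean: dict[int, np.ndarray]
    sigma: dict[int, float]
    epsilon: float

    @property
    def layers(self) -> list[int]:
        return sorted(self.mean)


def _predicted_mask(network: MLPNetwork, dataset: ExpressionDataset, class_k: int):
    trace = forward_trace(network, dataset.X)
    preds = trace.a[network.L].argmax(axis=1)
    return trace, preds == class_k


def class_relevance_profile(network: MLPNetwork, dataset: ExpressionDataset,
                            class_k: int, lrp_config: LRPConfig | None = None,
                            ) -> ClassRelevanceProfile:
    """Average LRP relevance per neuron over samples predicted as class k."""
    lrp_config = lrp_config or LRPConfig()
    trace, mask = _predicted_mask(network, dataset, class_k)
    n = int(mask.sum())
    if n == 0:
        name = network.classes[class_k] if network.classes else str(class_k)
        raise ValueError(f"no samples predicted as class {name!r}")
    rvec = relevance_from_output(network, trace.subset(np.flatnonzero(mask)),
                                 class_k, lrp_config)
    mean = {l: r.mean(axis=0) for l, r in rvec.relevances.items()}
    sigma = {l: _sigma_around_zero(m) for l, m in mean.items()}
    return ClassRelevanceProfile(
        class_index=class_k,
        class_name=network.classes[class_k] if network.classes else None,
        n_examples=n,
        mean=mean,
        sigma=sigma,
        epsilon=lrp_config.epsilon,
    )


def sample_relevance_matrix(network: MLPNetwork, dataset: ExpressionDataset,
                            class_k: int, lrp_config: LRPConfig | None = None,
                            layers: list[int] | None = None):
    """Per-sample relevance vectors for the samples predicted as class k.

    Returns ``(vectors, metadata)``: a DataFrame with one row per selected
    sample and layer-tagged neuron columns (relevances of every neuron,
    concatenated over ``layers``, default all layers below the output), and
    a metadata frame with the true label, prediction and correctness flag
    for dendrogram overlays.
    """
    lrp_config = lrp_config or LRPConfig()
    trace, mask = _predicted_mask(network, dataset, class_k)
    idx = np.flatnonzero(mask)
    if len(idx) == 0:
        raise ValueError(f"no samples predicted as class {class_k}")
    rvec = relevance_from_output(network, trace.subset(idx), class_k, lrp_config)
    if layers is None:
        layers = [l for l in sorted(rvec.relevances) if l < network.L]
    blocks, columns = [], []
    for l in layers:
        blocks.append(rvec.relevances[l])
        columns.extend(neuron_id(l, i) for i in range(rvec.relevances[l].shape[1]))
    sample_ids = [dataset.sample_ids[i] for i in idx]
    vectors = pd.DataFrame(np.hstack(blocks), index=sample_ids, columns=columns)
    y = dataset.y
    metadata = pd.DataFrame(
        {
            "label": [dataset.labels[i] for i in idx],
            "predicted": dataset.class_set[class_k],
            "correct": [bool(y[i] == class_k) for i in idx],
        },
        index=sample_ids,
    )
    return vectors, metadata


# ---------------------------------------------------------------------------
# important neurons / connections


@dataclass
class ImportantNeuronSet:
    """Neurons whose class-averaged relevance is an extreme outlier.

    ``entries`` has columns neuron (canonical id), layer, index, mean_score,
    standardized (mean/sigma), threshold; sorted per layer by |mean_score|
    descending.
    """

    class_index: int
    class_name: str | None
    alpha: float
    entries: pd.DataFrame

    def layer(self, l: int) -> pd.DataFrame:
        return self.entries[self.entries["layer"] == l]

    @property
    def neuron_ids(self) -> list[str]:
        return self.entries["neuron"].tolist()

    def neurons(self) -> list[tuple[int, int]]:
        return list(zip(self.entries["layer"], self.entries["index"]))


def select_important_neurons(profile: ClassRelevanceProfile, alpha: float = 0.05,
                             stat: str = "z", layers: list[int] | None = None,
                             ) -> ImportantNeuronSet:
    """Two-sided outlier test of each neuron's mean relevance under the
    zero-centred Gaussian null, Bonferroni-corrected within each layer.

    The output layer (where relevance is the start value itself) is
    excluded by default. A degenerate layer (sigma = 0) selects nothing and
    emits a warning.
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    if layers is None:
        layers = [l for l in profile.layers if l < max(profile.layers)]
    rows = []
    for l in layers:
        scores = profile.mean[l]
        n_l = len(scores)
        sigma = profile.sigma[l]
        if sigma == 0.0 or n_l < 2:
            if sigma == 0.0:
                warnings.warn(
                    f"layer {l}: degenerate null (sigma = 0), no neurons selected",
                    stacklevel=2,
                )
            continue
        threshold = _outlier_threshold(sigma, n_l, alpha, stat, df=n_l - 1)
        selected = np.flatnonzero(np.abs(scores) > threshold)
        order = selected[np.argsort(-np.abs(scores[selected]))]
        for i in order:
            rows.append({
                "neuron": neuron_id(l, int(i)),
                "layer": l,
                "index": int(i),
                "mean_score": float(scores[i]),
                "standardized": float(scores[i] / sigma),
                "threshold": threshold,
            })
    entries = pd.DataFrame(
        rows, columns=["neuron", "layer", "index", "mean_score", "standardized",
                       "threshold"],
    )
    return ImportantNeuronSet(
        class_index=profile.class_index,
        class_name=profile.class_name,
        alpha=alpha,
        entries=entries,
    )


@dataclass
class ImportantConnectionSet:
    """Connections between adjacent layers whose class-averaged relevance is
    an extreme outlier (or, with ``method='topk'``, in the top k by |mean|).

    ``entries`` columns: layer_from, from_index, to_index, from_neuron,
    to_neuron, mean_relevance.
    """

    class_index: int
    class_name: str | None
    alpha: float | None
    entries: pd.DataFrame


def _mean_connection_matrices(network: MLPNetwork, dataset: ExpressionDataset,
                              class_k: int, lrp_config: LRPConfig):
    """Class-averaged R_{i<-j} per inter-layer weight matrix, computed as a
    running matrix product rather than materializing per-sample maps."""
    trace, mask = _predicted_mask(network, dataset, class_k)
    idx = np.flatnonzero(mask)
    if len(idx) == 0:
        raise ValueError(f"no samples predicted as class {class_k}")
    sub = trace.subset(idx)
    rvec = relevance_from_output(network, sub, class_k, lrp_config)
    n = len(idx)
    means: dict[int, np.ndarray] = {}
    for m in range(network.L, 0, -1):
        z = sub.z[m]
        if lrp_config.epsilon == 0.0:
            denom = np.where(z == 0.0, 1.0, z)
        else:
            denom = np.where(z >= 0, z + lrp_config.epsilon, z - lrp_config.epsilon)
        factor = rvec.relevances[m] / denom
        # mean over samples of a_i * w_ij * factor_j
        means[m] = (sub.a[m - 1].T @ factor) / n * network.weights[m - 1]
    return means, n


def select_important_connections(network: MLPNetwork, dataset: ExpressionDataset,
                                 class_k: int, lrp_config: LRPConfig | None = None,
                                 alpha: float = 0.05, stat: str = "z",
                                 method: str = "test", top_k: int | None = None,
                                 ) -> ImportantConnectionSet:
    """Select connections by their class-averaged relevance.

    ``method='test'`` applies the same Gaussian/Bonferroni outlier test over
    each inter-layer connection population; ``method='topk'`` keeps the
    ``top_k`` connections by absolute mean relevance per inter-layer matrix.
    """
    lrp_config = lrp_config or LRPConfig()
    means, _ = _mean_connection_matrices(network, dataset, class_k, lrp_config)
    rows = []
    for m in sorted(means):
        mat = means[m]
        flat = mat.ravel()
        if method == "test":
            sigma = _sigma_around_zero(flat)
            if sigma == 0.0:
                warnings.warn(
                    f"connections into layer {m}: degenerate null, none selected",
                    stacklevel=2,
                )
                continue
            threshold = _outlier_threshold(sigma, flat.size, alpha, stat,
                                           df=flat.size - 1)
            picked = np.flatnonzero(np.abs(flat) > threshold)
        elif method == "topk":
            if top_k is None:
                raise ValueError("method='topk' requires top_k")
            picked = np.argsort(-np.abs(flat))[:top_k]
        else:
            raise ValueError(f"unknown method {method!r}")
        picked = picked[np.argsort(-np.abs(flat[picked]))]
        for pos in picked:
            i, j = np.unravel_index(pos, mat.shape)
            rows.append({
                "layer_from": m - 1,
                "from_index": int(i),
                "to_index": int(j),
                "from_neuron": neuron_id(m - 1, int(i)),
                "to_neuron": neuron_id(m, int(j)),
                "mean_relevance": float(mat[i, j]),
            })
    entries = pd.DataFrame(
        rows, columns=["layer_from", "from_index", "to_index", "from_neuron",
                       "to_neuron", "mean_relevance"],
    )
    return ImportantConnectionSet(
        class_index=class_k,
        class_name=network.classes[class_k] if network.classes else None,
        alpha=alpha if method == "test" else None,
        entries=entries,
    )


# ---------------------------------------------------------------------------
# neuron -> gene association


@dataclass
class NeuronGeneAssociation:
    """Input probes (and their genes) that drive a hidden neuron's activation.

    ``probes`` has columns probe_id, mean_relevance, sorted by
    |mean_relevance| descending; ``genes`` is the deduplicated mapped gene
    list in that order (unmapped probes stay in ``probes`` only).
    """

    layer: int
    index: int
    class_index: int
    alpha: float
    probes: pd.DataFrame
    genes: list[str]

    @property
    def neuron(self) -> str:
        return neuron_id(self.layer, self.index)


def associate_genes(network: MLPNetwork, dataset: ExpressionDataset, class_k: int,
                    neuron: tuple[int, int], annotation: ProbeAnnotation,
                    lrp_config: LRPConfig | None = None, alpha: float = 0.05,
                    stat: str = "z") -> NeuronGeneAssociation:
    """Backpropagate a hidden neuron's activation over the class-predicted
    samples, average the input relevances, and keep the probes passing the
    zero-centred outlier test (Bonferroni over all probes).

    A neuron that is ReLU-dead on every sample yields a valid empty
    association.
    """
    lrp_config = lrp_config or LRPConfig()
    layer, index = neuron
    trace, mask = _predicted_mask(network, dataset, class_k)
    idx = np.flatnonzero(mask)
    if len(idx) == 0:
        raise ValueError(f"no samples predicted as class {class_k}")
    rvec = relevance_from_hidden(network, trace.subset(idx), layer, index, lrp_config)
    mean_inputs = rvec.input_relevances().mean(axis=0)
    sigma = _sigma_around_zero(mean_inputs)
    if sigma == 0.0:
        selected = np.array([], dtype=int)
    else:
        threshold = _outlier_threshold(sigma, len(mean_inputs), alpha, stat,
                                       df=len(mean_inputs) - 1)
        selected = np.flatnonzero(np.abs(mean_inputs) > threshold)
    order = selected[np.argsort(-np.abs(mean_inputs[selected]))]
    probes = pd.DataFrame({
        "probe_id": [dataset.probe_ids[i] for i in order],
        "mean_relevance": mean_inputs[order],
    })
    genes = annotation.genes_for(probes["probe_id"])
    return NeuronGeneAssociation(
        layer=layer, index=index, class_index=class_k, alpha=alpha,
        probes=probes, genes=genes,
    )


# ---------------------------------------------------------------------------
# weight-magnitude baseline


@dataclass
class WMScores:
    """Data-independent importance of each neuron of one layer, computed
    from its outgoing connection weights only."""

    layer: int
    variant: str
    scores: np.ndarray


def wm_scores(network: MLPNetwork, layer: int,
              variant: str = "mean_abs_outgoing") -> WMScores:
    """Weight-magnitude score per neuron of ``layer`` (0 = input layer).

    Variants: ``mean_abs_outgoing`` (mean |w| of the outgoing row, the WM
    definition used for comparisons here), ``sum_outgoing`` and
    ``sum_abs_outgoing``.
    """
    if not 0 <= layer < network.L:
        raise ValueError(f"layer must be in [0, {network.L - 1}], got {layer}")
    w = network.weights[layer]
    if variant == "mean_abs_outgoing":
        scores = np.abs(w).mean(axis=1)
    elif variant == "sum_outgoing":
        scores = w.sum(axis=1)
    elif variant == "sum_abs_outgoing":
        scores = np.abs(w).sum(axis=1)
    else:
        raise ValueError(f"unknown WM variant {variant!r}; choose from {WM_VARIANTS}")
    return WMScores(layer=layer, variant=variant, scores=scores)


# ---------------------------------------------------------------------------
# relevance-vector clustering


@dataclass
class RelevanceClustering:
    """Hierarchical clustering of per-sample relevance vectors."""

    vectors: pd.DataFrame
    linkage: np.ndarray
    labels: np.ndarray
    metadata: pd.DataFrame | None
    distance: str
    linkage_method: str


def cluster_relevance_vectors(vectors: pd.DataFrame,
                              metadata: pd.DataFrame | None = None,
                              distance: str = "euclidean",
                              linkage_method: str = "ward",
                              k: int | None = 2,
                              height: float | None = None) -> RelevanceClustering:
    """Agglomerative clustering of relevance vectors (rows = samples).

    Flat labels are cut at ``k`` clusters (default 2) or at ``height`` if
    given. The dendrogram has one leaf per sample.
    """
    n = len(vectors)
    if n < 2:
        raise ValueError("clustering needs at least 2 samples")
    if k is not None and height is None and k > n:
        raise ValueError(f"k={k} exceeds the number of samples ({n})")
    dists = pdist(vectors.to_numpy(), metric=distance)
    Z = hierarchy.linkage(dists, method=linkage_method)
    if height is not None:
        labels = hierarchy.fcluster(Z, t=height, criterion="distance")
    else:
        labels = hierarchy.fcluster(Z, t=k, criterion="maxclust")
    if metadata is not None and not metadata.index.equals(vectors.index):
        raise ValueError("metadata index does not match vector index")
    return RelevanceClustering(
        vectors=vectors, linkage=Z, labels=labels, metadata=metadata,
        distance=distance, linkage_method=linkage_method,
    )


# ---------------------------------------------------------------------------
# subnetwork extraction


@dataclass
class Subnetwork:
    """Node/edge tables of the important part of the network for one class."""

    nodes: pd.DataFrame
    edges: pd.DataFrame


def extract_subnetwork(important_neurons: ImportantNeuronSet,
                       important_connections: ImportantConnectionSet,
                       network: MLPNetwork | None = None) -> Subnetwork:
    """Graph of the selected neurons plus the class output neuron, with the
    selected connections restricted to endpoints inside that node set.

    Both inputs must refer to the same class. An empty neuron set yields a
    graph containing only the output neuron.
    """
    if important_neurons.class_index != important_connections.class_index:
        raise ValueError("neuron and connection sets refer to different classes")
    out_layer = None
    if network is not None:
        out_layer = network.L
    elif len(important_connections.entries):
        out_layer = int(important_connections.entries["layer_from"].max()) + 1
    elif len(important_neurons.entries):
        out_layer = int(important_neurons.entries["layer"].max()) + 1

    node_rows = [
        {"node": row["neuron"], "layer": row["layer"], "index": row["index"],
         "mean_score": row["mean_score"], "is_output": False}
        for _, row in important_neurons.entries.iterrows()
    ]
    keep = set(important_neurons.entries["neuron"])
    if out_layer is not None:
        out_id = neuron_id(out_layer, important_neurons.class_index)
        node_rows.append({
            "node": out_id, "layer": out_layer,
            "index": important_neurons.class_index,
            "mean_score": np.nan, "is_output": True,
        })
        keep.add(out_id)
    nodes = pd.DataFrame(node_rows,
                         columns=["node", "layer", "index", "mean_score", "is_output"])
    ce = important_connections.entries
    if len(ce):
        mask = ce["from_neuron"].isin(keep) & ce["to_neuron"].isin(keep)
        edges = ce[mask].reset_index(drop=True)
    else:
        edges = ce.copy()
    return Subnetwork(nodes=nodes, edges=edges)
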