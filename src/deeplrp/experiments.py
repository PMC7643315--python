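"""Validation experiments for the interpretation pipeline.

Each function here re-runs a piece of the package under controlled,
seeded conditions and measures how well it behaves: exact conservation of
relevance, agreement with naive per-connection reference implementations,
calibration of the important-neuron test under a signal-free generator,
recovery of planted gene modules end to end, and the LRP-vs-WM comparison.
They are used both by the test suite and by ``scripts/acceptance.py``.

Problem sizes are desk scale: the planted-recovery runs use the default
synthetic spec (2000 samples x 500 probes) with a [500, 64, 32, 16, 2]
network, and the null-calibration runs use 400 x 100 with a
[100, 32, 16, 8, 2] network.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .data_io import save_checkpoint
from .enrichment import _log_pmf, compare_rankings, enrich, hypergeom_tail
from .interpretation import (
    associate_genes,
    class_relevance_profile,
    select_important_neurons,
)
from .lrp import LRPConfig, relevance_from_hidden, relevance_from_output
from .mlp import MLPConfig, MLPNetwork, forward_trace, train
from .reference import naive_relevance
from .synthetic import SyntheticSpec, generate

__all__ = [
    "random_relu_network",
    "conservation_experiment",
    "oracle_experiment",
    "linear_closed_form_error",
    "hypergeom_enumeration_sweep",
    "null_calibration_experiment",
    "planted_recovery_experiment",
    "determinism_experiment",
    "default_training_config",
    "small_training_config",
]


def _derive_seed(base: int, i: int) -> int:
    return int((base * 100_003 + i) % (2**31 - 1))


# ---------------------------------------------------------------------------
# LRP numerical experiments


def random_relu_network(rng: np.random.Generator, max_hidden_layers: int = 3,
                        max_width: int = 8, zero_bias: bool = False,
                        n_outputs: int | None = None) -> MLPNetwork:
    """A random small ReLU net (weight count <= max_hidden_layers + 1)."""
    n_hidden = int(rng.integers(1, max_hidden_layers + 1))
    sizes = [int(rng.integers(2, max_width + 1)) for _ in range(n_hidden + 1)]
    sizes.append(n_outputs if n_outputs is not None else int(rng.integers(1, 4)))
    weights = [rng.normal(0, 1.0, size=(sizes[l], sizes[l + 1]))
               for l in range(len(sizes) - 1)]
    biases = [np.zeros(sizes[l + 1]) if zero_bias
              else rng.normal(0, 0.5, size=sizes[l + 1])
              for l in range(len(sizes) - 1)]
    return MLPNetwork(weights=weights, biases=biases)


def _start_ok(net: MLPNetwork, x: np.ndarray, k: int = 0) -> bool:
    z = forward_trace(net, x).z[net.L][0, k]
    return abs(z) > 1e-1


def conservation_experiment(n_nets: int = 100, seed: int = 0) -> dict:
    """Exact (epsilon = 0) conservation on random ReLU nets.

    Zero-bias nets: the input-layer relevances must sum to the start
    relevance. Biased nets: the neuron sums plus the cumulative
    bias-absorbed shares must reproduce it at every layer. Returns the
    maximum relative residual observed in each regime.
    """
    rng = np.random.default_rng(seed)
    cfg = LRPConfig(epsilon=0.0)
    max_zero_bias = 0.0
    max_biased = 0.0
    for i in range(n_nets):
        zero_bias = i % 2 == 0
        while True:
            net = random_relu_network(rng, zero_bias=zero_bias)
            x = rng.normal(0, 1.0, size=net.n_inputs)
            if _start_ok(net, x):
                break
        trace = forward_trace(net, x)
        rvec = relevance_from_output(net, trace, 0, cfg)
        start = abs(float(rvec.start_relevance[0]))
        for layer in range(net.L):
            resid = abs(float(rvec.conservation_residual(layer)[0])) / start
            if zero_bias:
                max_zero_bias = max(max_zero_bias, resid)
            else:
                max_biased = max(max_biased, resid)
    return {"max_rel_residual_zero_bias": max_zero_bias,
            "max_rel_residual_with_bias": max_biased,
            "n_networks": n_nets}


def oracle_experiment(n_nets: int = 40, seed: int = 0,
                      epsilons=(0.0, 1e-9)) -> dict:
    """Maximum absolute deviation between the vectorized propagation and the
    naive per-connection recursion, over random nets <= 5 neurons/layer,
    for output and hidden targets."""
    rng = np.random.default_rng(seed)
    max_dev = 0.0
    for i in range(n_nets):
        while True:
            net = random_relu_network(rng, max_hidden_layers=3, max_width=5)
            x = rng.normal(0, 1.0, size=net.n_inputs)
            if _start_ok(net, x):
                break
        trace = forward_trace(net, x)
        for eps in epsilons:
            cfg = LRPConfig(epsilon=eps)
            rvec = relevance_from_output(net, trace, 0, cfg)
            start = np.zeros(net.n_outputs)
            start[0] = trace.z[net.L][0, 0]
            ref, ref_bias = naive_relevance(net.weights, net.biases, x, net.L,
                                            start, epsilon=eps)
            for l, vals in ref.items():
                max_dev = max(max_dev, float(np.max(np.abs(
                    rvec.relevances[l][0] - np.asarray(vals)))))
            for m, share in ref_bias.items():
                max_dev = max(max_dev, abs(float(rvec.bias_absorbed[m][0]) - share))
            # hidden target: first neuron of the first hidden layer
            hvec = relevance_from_hidden(net, trace, 1, 0, cfg)
            hstart = np.zeros(net.layer_sizes[1])
            hstart[0] = max(0.0, trace.z[1][0, 0])
            href, _ = naive_relevance(net.weights, net.biases, x, 1, hstart,
                                      epsilon=eps)
            max_dev = max(max_dev, float(np.max(np.abs(
                hvec.relevances[0][0] - np.asarray(href[0])))))
    return {"max_abs_deviation": max_dev, "n_networks": n_nets}


def linear_closed_form_error(seed: int = 0, n_inputs: int = 20,
                             n_outputs: int = 3) -> float:
    """Max |R_j^(0) - a_j * w_jk| on a 0-hidden-layer zero-bias network
    (the closed form holds exactly, so this should be 0.0)."""
    rng = np.random.default_rng(seed)
    w = rng.normal(0, 1.0, size=(n_inputs, n_outputs))
    net = MLPNetwork(weights=[w], biases=[np.zeros(n_outputs)])
    x = rng.normal(0, 1.0, size=n_inputs)
    trace = forward_trace(net, x)
    err = 0.0
    for k in range(n_outputs):
        rvec = relevance_from_output(net, trace, k, LRPConfig(epsilon=0.0))
        err = max(err, float(np.max(np.abs(rvec.relevances[0][0] - x * w[:, k]))))
    return err


# ---------------------------------------------------------------------------
# hypergeometric enumeration oracle


def hypergeom_enumeration_sweep(max_universe: int = 12) -> dict:
    """Compare hypergeom_tail with exhaustive enumeration of all C(N_G, M)
    draws for every configuration with N_G <= max_universe.

    Also reports the worst deviation of the pmf summed over its support
    from 1, and the worked value
    P(t >= 4 | M=4, N_G=10, N_term=5) = C(5,4)C(5,0)/C(10,4) = 5/210.
    """
    max_tail_err = 0.0
    max_sum_err = 0.0
    n_configs = 0
    for n_g in range(1, max_universe + 1):
        for m in range(0, n_g + 1):
            subsets = list(itertools.combinations(range(n_g), m))
            for n_term in range(0, n_g + 1):
                # overlap of each draw with the term {0, ..., n_term-1}
                counts = np.zeros(m + 1, dtype=np.int64)
                for s in subsets:
                    t = sum(1 for e in s if e < n_term)
                    counts[t] += 1
                total = len(subsets)
                tail_counts = np.cumsum(counts[::-1])[::-1]  # #draws with >= T
                for T in range(0, min(m, n_term) + 1):
                    expected = tail_counts[T] / total
                    got = hypergeom_tail(T, m, n_g, n_term)
                    max_tail_err = max(max_tail_err, abs(got - expected))
                    n_configs += 1
                # the log-space pmf must sum to 1 over the support
                t_lo = max(0, m - (n_g - n_term))
                support = np.arange(t_lo, min(m, n_term) + 1)
                pmf_sum = float(np.exp(_log_pmf(support, m, n_g, n_term)).sum())
                max_sum_err = max(max_sum_err, abs(pmf_sum - 1.0))
    worked = hypergeom_tail(4, 4, 10, 5)
    return {
        "max_tail_abs_error": max_tail_err,
        "max_support_sum_error": max_sum_err,
        "worked_example_value": worked,
        "worked_example_expected": 5.0 / 210.0,
        "n_configs": n_configs,
    }


# ---------------------------------------------------------------------------
# pipeline-level experiments


def default_training_config(n_probes: int, n_classes: int, seed: int) -> MLPConfig:
    """Desk-scale training configuration for the default synthetic spec:
    a [p, 64, 32, 16, K] net with the reference L1 strength (1e-3), light
    dropout, Adam at 3e-3 with batch 64, and early stopping (patience 30)
    within at most 300 epochs so the sparse solution is well converged."""
    return MLPConfig(
        layer_sizes=[n_probes, 64, 32, 16, n_classes],
        p_drop=0.1,
        l1=1e-3,
        lr=3e-3,
        batch_size=64,
        max_epochs=300,
        early_stop_patience=30,
        validation_fraction=0.1,
        seed=seed,
    )


def small_training_config(n_probes: int, n_classes: int, seed: int,
                          max_epochs: int = 15) -> MLPConfig:
    """Smaller net/configuration for calibration runs on 400 x 100 data."""
    return MLPConfig(
        layer_sizes=[n_probes, 32, 16, 8, n_classes],
        p_drop=0.0,
        l1=0.0,
        lr=1e-3,
        batch_size=32,
        max_epochs=max_epochs,
        early_stop_patience=max_epochs,
        validation_fraction=0.1,
        seed=seed,
    )


def _split(n: int, test_fraction: float, rng: np.random.Generator):
    order = rng.permutation(n)
    n_test = int(round(test_fraction * n))
    return np.sort(order[n_test:]), np.sort(order[:n_test])


def null_calibration_experiment(n_repeats: int = 50, seed: int = 0,
                                alpha: float = 0.05) -> dict:
    """Selection rate of the important-neuron test under the signal-free
    generator (effect size 0).

    Each repeat generates a fresh null dataset, trains a small net briefly,
    computes the class relevance profile for each class with predicted
    samples and counts the fraction of neurons selected per layer. With a
    correctly calibrated test this per-layer rate stays at or below the
    nominal alpha on average.
    """
    rates = []
    for i in range(n_repeats):
        s = _derive_seed(seed, i)
        spec = SyntheticSpec(n_samples=400, n_probes=100, n_terms=5,
                             genes_per_term=10, effect_size=0.0, seed=s)
        data = generate(spec)
        cfg = small_training_config(spec.n_probes, len(spec.class_names), s)
        net, _ = train(data.dataset, cfg)
        for k in range(len(spec.class_names)):
            try:
                profile = class_relevance_profile(net, data.dataset, k)
            except ValueError:
                continue  # no samples predicted as this class
            selected = select_important_neurons(profile, alpha=alpha)
            for l in profile.layers:
                if l >= max(profile.layers):
                    continue
                n_l = len(profile.mean[l])
                n_sel = int((selected.entries["layer"] == l).sum())
                rates.append(n_sel / n_l)
    return {
        "mean_selection_rate": float(np.mean(rates)) if rates else float("nan"),
        "n_repeats": n_repeats,
        "n_layer_measurements": len(rates),
        "alpha": alpha,
    }


@dataclass
class PlantedRecoveryResult:
    seed: int
    test_accuracy: float
    planted_term: str
    top_term: str | None
    top_term_is_planted: bool
    jaccard_top_neuron: float
    n_important_layer1: int
    lrp_p_at_module_size: float
    wm_p_at_module_size: float

    @property
    def lrp_beats_wm(self) -> bool:
        return self.lrp_p_at_module_size <= self.wm_p_at_module_size


def _jaccard(a, b) -> float:
    a, b = set(a), set(b)
    if not a and not b:
        return 0.0
    return len(a & b) / len(a | b)


def planted_recovery_run(seed: int, spec: SyntheticSpec | None = None,
                         signal_class: str = "cancer",
                         alpha: float = 0.05) -> PlantedRecoveryResult:
    """One end-to-end run: generate, train, interpret, enrich, compare.

    Measures (a) whether the planted annotation term is the top enriched
    term of the gene lists associated with the signal class's important
    first-hidden-layer neurons, (b) the Jaccard overlap between the planted
    module and the genes of the single most important layer-1 neuron, and
    (c) the LRP-vs-WM enrichment p-values at k = module size.
    """
    spec = spec or SyntheticSpec(seed=seed)
    data = generate(spec, seed=seed)
    rng = np.random.default_rng(_derive_seed(seed, 7))
    train_idx, test_idx = _split(spec.n_samples, 0.3, rng)
    train_set = data.dataset.subset(train_idx)
    test_set = data.dataset.subset(test_idx)

    cfg = default_training_config(spec.n_probes, len(spec.class_names), seed)
    net, _ = train(train_set, cfg)
    trace = forward_trace(net, test_set.X)
    preds = trace.a[net.L].argmax(axis=1)
    accuracy = float(np.mean(preds == test_set.y))

    class_k = test_set.class_index(signal_class)
    planted_term = data.truth.informative_terms[signal_class][0]
    planted_genes = set(data.truth.informative_genes[signal_class])

    profile = class_relevance_profile(net, test_set, class_k)
    important = select_important_neurons(profile, alpha=alpha)
    layer1 = important.layer(1)

    top_term = None
    jaccard = 0.0
    if len(layer1):
        union_genes: list[str] = []
        for rank, (_, row) in enumerate(layer1.iterrows()):
            assoc = associate_genes(net, test_set, class_k,
                                    (1, int(row["index"])), data.annotation,
                                    alpha=alpha)
            union_genes.extend(assoc.genes)
            if rank == 0:
                jaccard = _jaccard(assoc.genes, planted_genes)
        union_genes = list(dict.fromkeys(union_genes))
        if union_genes:
            analysis = enrich(union_genes, data.database, alpha=alpha)
            top_term = analysis.top_term

    k_module = len(planted_genes)
    comparison = compare_rankings(net, test_set, class_k, data.database,
                                  planted_term, [k_module], data.annotation)
    return PlantedRecoveryResult(
        seed=seed,
        test_accuracy=accuracy,
        planted_term=planted_term,
        top_term=top_term,
        top_term_is_planted=top_term == planted_term,
        jaccard_top_neuron=jaccard,
        n_important_layer1=len(layer1),
        lrp_p_at_module_size=comparison.p_values["LRP"][0],
        wm_p_at_module_size=comparison.p_values["WM"][0],
    )


def planted_recovery_experiment(n_seeds: int = 20, seed: int = 0) -> dict:
    """Repeat :func:`planted_recovery_run` over independent seeds and
    aggregate the recovery rates."""
    results = [planted_recovery_run(_derive_seed(seed, i)) for i in range(n_seeds)]
    return {
        "results": results,
        "n_seeds": n_seeds,
        "top_term_rate": float(np.mean([r.top_term_is_planted for r in results])),
        "jaccard_ge_half_rate": float(np.mean([r.jaccard_top_neuron >= 0.5
                                               for r in results])),
        "median_jaccard": float(np.median([r.jaccard_top_neuron for r in results])),
        "lrp_beats_wm_rate": float(np.mean([r.lrp_beats_wm for r in results])),
        "mean_test_accuracy": float(np.mean([r.test_accuracy for r in results])),
    }


# ---------------------------------------------------------------------------
# determinism


def determinism_experiment(seed: int, out_dir: str | Path) -> dict:
    """Run generate -> train -> interpret twice with identical seeds and
    compare the bytes of the checkpoints and the interpretation tables."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    spec = SyntheticSpec(n_samples=600, n_probes=100, n_terms=5,
                         genes_per_term=10, seed=seed)

    def run(tag: str) -> tuple[bytes, str]:
        data = generate(spec)
        cfg = small_training_config(spec.n_probes, len(spec.class_names), seed,
                                    max_epochs=20)
        net, _ = train(data.dataset, cfg)
        path = out_dir / f"model_{tag}.ckpt"
        save_checkpoint(net, path, metadata={"seed": seed})
        profile = class_relevance_profile(net, data.dataset, 1)
        table = select_important_neurons(profile).entries.to_csv(sep="\t", index=False)
        return path.read_bytes(), table

    ckpt_a, table_a = run("a")
    ckpt_b, table_b = run("b")
    return {
        "checkpoint_identical": ckpt_a == ckpt_b,
        "interpretation_identical": table_a == table_b,
    }
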