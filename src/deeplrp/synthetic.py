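"""Synthetic two-class expression data with planted, annotated gene modules.

The generator emulates the situation the interpretation pipeline is built
for: a normalized samples x probes matrix whose class signal is carried by
a small number of gene modules, each module tied to a term of a matching
annotation database. Background expression is i.i.d. Normal(0, sigma^2);
for a sample of class c_k every probe of every gene in c_k's informative
terms is shifted by sign_g * delta * sigma, with a per-gene sign fixed by
the seed so relevance is exercised in both directions. Terms partition the
gene universe, so the ground-truth enrichment answer is unambiguous.

Everything downstream (classifier, LRP, neuron selection, gene association,
enrichment, the WM comparison) can be validated against the returned
:class:`GroundTruth`, including a Bayes-optimal decision rule.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .data_io import (
    AnnotationDatabase,
    ExpressionDataset,
    GeneSetTerm,
    ProbeAnnotation,
)
from .mlp import MLPNetwork

__all__ = ["SyntheticSpec", "GroundTruth", "SyntheticData", "generate",
           "make_toy_network"]

TOY_PATTERNS = ("single_path", "two_input", "fig3_style")


@dataclass
class SyntheticSpec:
    """Defaults are the desk-scale study conditions used throughout the
    test suite: 2000 samples, 500 probes (one per gene), two balanced
    classes, 25 terms of 20 genes each, one informative term per class and
    an effect size of 3 noise standard deviations."""

    n_samples: int = 2000
    n_probes: int = 500
    class_names: Sequence[str] = ("normal", "cancer")
    class_proportions: Sequence[float] = (0.5, 0.5)
    n_terms: int = 25
    genes_per_term: int = 20
    informative_terms: Mapping[str, Sequence[str]] | None = None
    effect_size: float = 3.0
    noise_sd: float = 1.0
    probes_per_gene: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.class_names) != len(self.class_proportions):
            raise ValueError("one proportion per class required")
        if abs(sum(self.class_proportions) - 1.0) > 1e-9:
            raise ValueError("class proportions must sum to 1")
        if self.effect_size < 0:
            raise ValueError("effect size must be >= 0")
        if self.noise_sd <= 0:
            raise ValueError("noise sd must be > 0")
        if self.probes_per_gene < 1:
            raise ValueError("probes_per_gene must be >= 1")
        n_genes = self.n_probes // self.probes_per_gene
        if self.n_terms * self.genes_per_term > n_genes:
            raise ValueError(
                f"{self.n_terms} terms x {self.genes_per_term} genes exceed the "
                f"{n_genes} genes available"
            )

    @property
    def n_genes(self) -> int:
        return self.n_probes // self.probes_per_gene

    @property
    def term_ids(self) -> list[str]:
        return [f"T{t + 1:03d}" for t in range(self.n_terms)]

    def default_informative_terms(self) -> dict[str, list[str]]:
        """One informative term per class, in class order (T001 for the
        first class, T002 for the second, ...)."""
        ids = self.term_ids
        return {c: [ids[k]] for k, c in enumerate(self.class_names)}


@dataclass
class GroundTruth:
    """What the generator planted, for use as an oracle in tests."""

    informative_terms: dict[str, list[str]]
    informative_genes: dict[str, list[str]]
    gene_effects: dict[str, float]          # signed shift (in expression units)
    class_means: np.ndarray                 # (K, n_probes) mean profile per class
    noise_sd: float
    class_names: list[str]
    class_proportions: list[float]
    description: str = (
        "Classes are Gaussians N(mu_k, sigma^2 I); the Bayes rule picks "
        "argmax_k [x . mu_k - |mu_k|^2 / 2] / sigma^2 + log pi_k."
    )

    def bayes_predict(self, X: np.ndarray) -> np.ndarray:
        """Bayes-optimal class index per row of ``X`` (probe order must
        match the generated dataset)."""
        X = np.atleast_2d(np.asarray(X, dtype=float))
        mus = self.class_means
        scores = (X @ mus.T - 0.5 * np.sum(mus * mus, axis=1)) / self.noise_sd ** 2
        scores = scores + np.log(np.asarray(self.class_proportions))
        return scores.argmax(axis=1)


@dataclass
class SyntheticData:
    dataset: ExpressionDataset
    annotation: ProbeAnnotation
    database: AnnotationDatabase
    truth: GroundTruth


def generate(spec: SyntheticSpec, seed: int | None = None) -> SyntheticData:
    """Generate a dataset, probe map, GMT-style database and ground truth.

    Deterministic given the seed (``seed`` overrides ``spec.seed``). The
    database comes back with its universe already set to the dataset's
    mapped genes.
    """
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    n, p = spec.n_samples, spec.n_probes
    n_genes, ppg = spec.n_genes, spec.probes_per_gene
    genes = [f"G{g + 1:04d}" for g in range(n_genes)]
    probes = [f"P{j + 1:05d}" for j in range(p)]
    # probe j measures gene j // ppg; probes beyond n_genes*ppg are unmapped
    mapping = {probes[j]: genes[j // ppg] for j in range(n_genes * ppg)}
    annotation = ProbeAnnotation(mapping)

    term_ids = spec.term_ids
    terms = []
    for t in range(spec.n_terms):
        members = genes[t * spec.genes_per_term:(t + 1) * spec.genes_per_term]
        terms.append(GeneSetTerm(term_id=term_ids[t],
                                 name=f"synthetic module {t + 1}",
                                 genes=frozenset(members)))
    database = AnnotationDatabase(terms=terms).with_universe(annotation.genes)

    informative = (dict(spec.informative_terms) if spec.informative_terms is not None
                   else spec.default_informative_terms())
    term_genes = {t.term_id: sorted(t.genes) for t in terms}
    for cls, tids in informative.items():
        if cls not in spec.class_names:
            raise ValueError(f"informative terms given for unknown class {cls!r}")
        for tid in tids:
            if tid not in term_genes:
                raise ValueError(f"informative term {tid!r} does not exist")

    signs = rng.choice([-1.0, 1.0], size=n_genes)
    sign_of = dict(zip(genes, signs))
    gene_index = {g: i for i, g in enumerate(genes)}

    # per-class mean profiles (probe space)
    K = len(spec.class_names)
    class_means = np.zeros((K, p))
    informative_genes: dict[str, list[str]] = {}
    gene_effects: dict[str, float] = {}
    for k, cls in enumerate(spec.class_names):
        gset: list[str] = []
        for tid in informative.get(cls, []):
            gset.extend(term_genes[tid])
        gset = sorted(dict.fromkeys(gset))
        informative_genes[cls] = gset
        for g in gset:
            shift = sign_of[g] * spec.effect_size * spec.noise_sd
            gene_effects.setdefault(g, shift)
            gi = gene_index[g]
            class_means[k, gi * ppg:(gi + 1) * ppg] = shift

    counts = np.floor(np.asarray(spec.class_proportions) * n).astype(int)
    counts[-1] = n - counts[:-1].sum()
    y = np.repeat(np.arange(K), counts)
    y = rng.permutation(y)

    X = rng.normal(0.0, spec.noise_sd, size=(n, p))
    X += class_means[y]

    dataset = ExpressionDataset(
        matrix=X,
        sample_ids=[f"S{i + 1:05d}" for i in range(n)],
        probe_ids=probes,
        labels=[spec.class_names[k] for k in y],
        class_set=list(spec.class_names),
    )
    truth = GroundTruth(
        informative_terms={c: list(t) for c, t in informative.items()},
        informative_genes=informative_genes,
        gene_effects=gene_effects,
        class_means=class_means,
        noise_sd=spec.noise_sd,
        class_names=list(spec.class_names),
        class_proportions=list(spec.class_proportions),
    )
    return SyntheticData(dataset=dataset, annotation=annotation,
                         database=database, truth=truth)


def make_toy_network(pattern: str):
    """Fixed tiny networks used across the test suite; returns
    ``(network, reference_input)``.

    - ``single_path``: one input wired to one output with weight 2, no bias.
    - ``two_input``: inputs with weights [1, 3] into one output, no bias.
    - ``fig3_style``: a synthetic 3-input / 2-hidden / 1-output ReLU net
      constructed so that the input with the largest mean-|w| outgoing
      weights (i2) has near-zero activation at the reference input while a
      modestly weighted input (i3) sits on a well-propagated path — hence
      WM ranks i2 first but LRP ranks i3 first.
    """
    if pattern == "single_path":
        net = MLPNetwork(weights=[np.array([[2.0]])], biases=[np.zeros(1)])
        return net, np.array([3.0])
    if pattern == "two_input":
        net = MLPNetwork(weights=[np.array([[1.0], [3.0]])], biases=[np.zeros(1)])
        return net, np.array([1.0, 1.0])
    if pattern == "fig3_style":
        w1 = np.array([
            [2.0, 0.1],   # i1: strong into h1, weak into h2 -> dead-end path
            [1.5, 1.3],   # i2: largest mean |w| but ~zero activation
            [0.2, 1.2],   # i3: modest weights on the well-propagated path
        ])
        w2 = np.array([[0.1], [3.0]])  # h1 barely reaches the output, h2 dominates
        net = MLPNetwork(weights=[w1, w2], biases=[np.zeros(2), np.zeros(1)])
        return net, np.array([2.0, 0.1, 2.0])
    raise ValueError(f"unknown toy pattern {pattern!r}; choose from {TOY_PATTERNS}")
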