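"""Hypergeometric over-representation analysis and the LRP-vs-WM ranking
comparison.

A query list of M genes drawn from a universe of N_G genes contains T
members of an annotation term of size N_term. Under the null that the list
is a uniform random draw, T follows a hypergeometric law

    p(t) = C(N_term, t) * C(N_G - N_term, M - t) / C(N_G, M)

and the term is over-represented when the upper tail P(t >= T) falls below
0.05 (raw p; a Benjamini-Hochberg column is available for modern practice).
Tail probabilities are computed in log space via log-gamma binomial
coefficients so universes of tens of thousands of genes do not overflow.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import gammaln, logsumexp

from .data_io import AnnotationDatabase, ExpressionDataset, ProbeAnnotation
from .interpretation import wm_scores
from .lrp import LRPConfig, relevance_from_output
from .mlp import MLPNetwork, forward_trace

__all__ = [
    "EnrichmentResult",
    "EnrichmentAnalysis",
    "RankingComparison",
    "hypergeom_tail",
    "enrich",
    "rank_genes_by_method",
    "compare_rankings",
]


def _log_binom(n: int, k: np.ndarray) -> np.ndarray:
    return gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)


def _log_pmf(t: np.ndarray, M: int, N_G: int, N_term: int) -> np.ndarray:
    """log p(t) over the support (no bounds checking)."""
    t = np.asarray(t)
    return (
        _log_binom(N_term, t)
        + _log_binom(N_G - N_term, M - t)
        - _log_binom(N_G, np.array(M))
    )


def hypergeom_tail(T: int, M: int, N_G: int, N_term: int) -> float:
    """Upper-tail probability P(t >= T) of the hypergeometric law.

    ``T`` observed overlap, ``M`` query-list size, ``N_G`` universe size,
    ``N_term`` term size within the universe. The sum runs over the
    support t in [max(0, M - (N_G - N_term)), min(M, N_term)]; if ``T``
    exceeds the support maximum the sum is empty and 0.0 is returned.
    """
    for name, v in (("T", T), ("M", M), ("N_G", N_G), ("N_term", N_term)):
        if int(v) != v or v < 0:
            raise ValueError(f"{name} must be a non-negative integer, got {v!r}")
    T, M, N_G, N_term = int(T), int(M), int(N_G), int(N_term)
    if M > N_G:
        raise ValueError(f"query size M={M} exceeds universe N_G={N_G}")
    if N_term > N_G:
        raise ValueError(f"term size N_term={N_term} exceeds universe N_G={N_G}")
    t_max = min(M, N_term)
    support_min = max(M - (N_G - N_term), 0)
    if T <= support_min:
        return 1.0  # the tail covers the whole support: a certain event
    if T > t_max:
        return 0.0  # empty sum: an impossible event
    t = np.arange(T, t_max + 1)
    return float(min(1.0, np.exp(logsumexp(_log_pmf(t, M, N_G, N_term)))))


@dataclass
class EnrichmentResult:
    term_id: str
    term_name: str
    T: int            # overlap between query and term (within universe)
    M: int            # effective query size
    N_G: int          # universe size
    N_term: int       # term size restricted to the universe
    p_raw: float
    p_adjusted: float | None
    significant: bool


@dataclass
class EnrichmentAnalysis:
    """Results of testing one gene list against every database term,
    sorted by raw p-value; ``n_dropped`` counts off-universe query genes."""

    results: list[EnrichmentResult]
    n_dropped: int
    alpha: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([
            {
                "term_id": r.term_id, "term_name": r.term_name, "T": r.T,
                "M": r.M, "N_term": r.N_term, "N_G": r.N_G, "p_raw": r.p_raw,
                "p_bh": r.p_adjusted, "significant": r.significant,
            }
            for r in self.results
        ])

    @property
    def top_term(self) -> str:
        return self.results[0].term_id


def _bh_adjust(p: np.ndarray) -> np.ndarray:
    m = len(p)
    order = np.argsort(p, kind="stable")
    adj = np.empty(m)
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, p[i] * m / rank)
        adj[i] = running
    return adj


def enrich(gene_list, database: AnnotationDatabase, alpha: float = 0.05,
           adjust: bool = True) -> EnrichmentAnalysis:
    """Hypergeometric over-representation of every term in a gene list.

    Query genes outside the universe are dropped (their count is reported
    in the result). Significance follows the raw p < alpha convention; the
    BH-adjusted column is informational unless you threshold it yourself.
    """
    if database.universe is None:
        raise ValueError("database has no gene universe; call with_universe() first")
    universe = database.universe
    query = [g for g in dict.fromkeys(gene_list)]
    effective = [g for g in query if g in universe]
    n_dropped = len(query) - len(effective)
    if not effective:
        raise ValueError("gene list is empty after restricting to the universe")
    qset = set(effective)
    M, N_G = len(effective), len(universe)
    rows = []
    for term in database.terms:
        in_universe = term.genes & universe
        N_term = len(in_universe)
        T = len(qset & in_universe)
        p = hypergeom_tail(T, M, N_G, N_term)
        rows.append((term, T, N_term, p))
    p_raw = np.array([r[3] for r in rows])
    p_adj = _bh_adjust(p_raw) if adjust else [None] * len(rows)
    results = [
        EnrichmentResult(
            term_id=term.term_id, term_name=term.name, T=T, M=M, N_G=N_G,
            N_term=N_term, p_raw=p,
            p_adjusted=(float(a) if a is not None else None),
            significant=bool(p < alpha),
        )
        for (term, T, N_term, p), a in zip(rows, p_adj)
    ]
    results.sort(key=lambda r: (r.p_raw, r.term_id))
    return EnrichmentAnalysis(results=results, n_dropped=n_dropped, alpha=alpha)


# ---------------------------------------------------------------------------
# LRP vs WM gene rankings


def _aggregate_probe_scores(scores: np.ndarray, probe_ids, annotation: ProbeAnnotation,
                            agg: str) -> pd.Series:
    mapped: dict[str, list[float]] = {}
    for pid, s in zip(probe_ids, scores):
        g = annotation.get(pid)
        if g is not None:
            mapped.setdefault(g, []).append(float(s))
    if agg == "max":
        vals = {g: max(v) for g, v in mapped.items()}
    elif agg == "mean":
        vals = {g: float(np.mean(v)) for g, v in mapped.items()}
    else:
        raise ValueError(f"unknown aggregation {agg!r}")
    return pd.Series(vals)


def rank_genes_by_method(network: MLPNetwork, dataset: ExpressionDataset,
                         class_k: int, method: str, annotation: ProbeAnnotation,
                         lrp_config: LRPConfig | None = None,
                         wm_variant: str = "mean_abs_outgoing",
                         agg: str = "max") -> pd.DataFrame:
    """Rank genes by input importance under LRP or the WM baseline.

    LRP: absolute class-averaged input relevance (over samples predicted as
    class k). WM: input-layer weight-magnitude score, which ignores the
    data entirely. Probe scores are aggregated per gene (max by default);
    ties break deterministically by gene id. Returns a DataFrame with
    columns ``gene`` and ``score``, best first.
    """
    if method == "LRP":
        lrp_config = lrp_config or LRPConfig()
        trace = forward_trace(network, dataset.X)
        preds = trace.a[network.L].argmax(axis=1)
        idx = np.flatnonzero(preds == class_k)
        if len(idx) == 0:
            raise ValueError(f"no samples predicted as class {class_k}")
        rvec = relevance_from_output(network, trace.subset(idx), class_k, lrp_config)
        probe_scores = np.abs(rvec.input_relevances().mean(axis=0))
    elif method == "WM":
        probe_scores = np.abs(wm_scores(network, 0, wm_variant).scores)
    else:
        raise ValueError(f"method must be 'LRP' or 'WM', got {method!r}")
    gene_scores = _aggregate_probe_scores(probe_scores, dataset.probe_ids,
                                          annotation, agg)
    df = gene_scores.rename_axis("gene").reset_index(name="score")
    df = df.sort_values(["score", "gene"], ascending=[False, True],
                        kind="stable").reset_index(drop=True)
    return df


@dataclass
class RankingComparison:
    """Enrichment p-value of one term on the top-k genes of each method."""

    term_id: str
    k_grid: list[int]
    p_values: dict[str, list[float]]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for method, ps in self.p_values.items():
            for k, p in zip(self.k_grid, ps):
                rows.append({"method": method, "k": k, "p_value": p})
        return pd.DataFrame(rows)


def compare_rankings(network: MLPNetwork, dataset: ExpressionDataset, class_k: int,
                     database: AnnotationDatabase, term_id: str, k_grid,
                     annotation: ProbeAnnotation,
                     lrp_config: LRPConfig | None = None,
                     wm_variant: str = "mean_abs_outgoing") -> RankingComparison:
    """For each k, the hypergeometric p of ``term_id`` on the top-k genes
    selected by LRP and by WM (the experiment behind the p-value curves)."""
    if database.universe is None:
        raise ValueError("database has no gene universe; call with_universe() first")
    term = database.term(term_id)
    universe = database.universe
    in_universe = term.genes & universe
    N_G, N_term = len(universe), len(in_universe)
    k_grid = sorted(int(k) for k in k_grid)
    if any(k <= 0 for k in k_grid):
        raise ValueError("k values must be positive")
    if k_grid[-1] > N_G:
        warnings.warn(
            f"k values above the universe size ({N_G}) truncated", stacklevel=2
        )
        k_grid = [min(k, N_G) for k in k_grid]
        k_grid = sorted(dict.fromkeys(k_grid))
    p_values: dict[str, list[float]] = {}
    for method in ("LRP", "WM"):
        ranking = rank_genes_by_method(network, dataset, class_k, method,
                                       annotation, lrp_config, wm_variant)
        genes = [g for g in ranking["gene"] if g in universe]
        ps = []
        for k in k_grid:
            top = set(genes[:k])
            T = len(top & in_universe)
            ps.append(hypergeom_tail(T, len(top), N_G, N_term))
        p_values[method] = ps
    return RankingComparison(term_id=term_id, k_grid=k_grid, p_values=p_values)
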