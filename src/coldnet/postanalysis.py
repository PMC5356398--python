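"""Network statistics, enrichment, annotation transfer and marker ranking.

Operates on the inferred edge list (treated as an undirected simple graph for
topology statistics), gene clusters from the triclustering stage, and
gene -> term annotation sets (GMT-style).
"""

from __future__ import annotations

import numpy as np
import networkx as nx
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "clustering_coefficient",
    "degree_distribution_fit",
    "enrich_terms",
    "transfer_annotations",
    "rank_candidate_markers",
    "compare_gene_lists",
]


def _to_graph(edges) -> nx.Graph:
    g = nx.Graph()
    if isinstance(edges, pd.DataFrame):
        pairs = edges[["tf", "gene"]].itertuples(index=False)
    else:
        pairs = edges
    for u, v in pairs:
        if u != v:  # self-loops dropped
            g.add_edge(u, v)
    return g


def clustering_coefficient(edges, nodes=None) -> tuple[dict, float]:
    """Local clustering coefficients and their mean over a node subset.

    The edge list is treated as undirected and simple; the local coefficient
    is 2*triangles / (deg*(deg-1)), defined as 0 for degree < 2.  ``nodes``
    defaults to every node in the graph.
    """
    g = _to_graph(edges)
    subset = list(nodes) if nodes is not None else list(g.nodes)
    if not subset:
        raise ValueError("empty node subset")
    coeffs = {n: (nx.clustering(g, n) if n in g else 0.0) for n in subset}
    return coeffs, float(np.mean(list(coeffs.values())))


def degree_distribution_fit(edges) -> tuple[float, float]:
    """Log-log least-squares fit of the degree distribution.

    Returns (slope, R^2) of log10(frequency) on log10(degree) over the
    distinct positive degrees; a scale-free network shows slope < 0 with high
    R^2 (the power-law exponent is -slope).  Requires >= 5 distinct degrees.
    """
    g = _to_graph(edges)
    degrees = np.array([d for _, d in g.degree() if d > 0])
    distinct, counts = np.unique(degrees, return_counts=True)
    if len(distinct) < 5:
        raise ValueError(
            f"only {len(distinct)} distinct degrees; skip the scale-free fit"
        )
    lx = np.log10(distinct.astype(float))
    ly = np.log10(counts.astype(float))
    slope, intercept = np.polyfit(lx, ly, 1)
    pred = slope * lx + intercept
    ss_res = float(((ly - pred) ** 2).sum())
    ss_tot = float(((ly - ly.mean()) ** 2).sum())
    r2 = 1.0 if ss_tot == 0 else 1.0 - ss_res / ss_tot
    return float(slope), r2


def enrich_terms(
    gene_set,
    universe,
    terms: dict[str, set[str]],
    correction: str = "fdr_bh",
) -> pd.DataFrame:
    """Hypergeometric term over-representation with BH adjustment.

    For each term: N = |universe|, K = term genes in the universe, n =
    |gene_set|, k = overlap; p = P(X >= k).  Returns term, k, K, n, N, p,
    p_adj sorted by p.
    """
    universe = set(universe)
    gene_set = set(gene_set)
    if not universe:
        raise ValueError("empty universe")
    if not gene_set <= universe:
        raise ValueError("gene set must be a subset of the universe")
    n_univ, n_set = len(universe), len(gene_set)
    rows = []
    for term in sorted(terms):
        in_univ = terms[term] & universe
        big_k = len(in_univ)
        k = len(in_univ & gene_set)
        p = float(stats.hypergeom.sf(k - 1, n_univ, big_k, n_set)) if big_k else 1.0
        rows.append((term, k, big_k, n_set, n_univ, p))
    df = pd.DataFrame(rows, columns=["term", "k", "K", "n", "N", "p"])
    if len(df):
        df["p_adj"] = multipletests(df["p"], method=correction)[1]
    else:
        df["p_adj"] = []
    return df.sort_values(["p", "term"]).reset_index(drop=True)


def transfer_annotations(
    clusters: dict[str, set[str]],
    terms: dict[str, set[str]],
    universe,
    p_threshold: float = 0.05,
) -> pd.DataFrame:
    """Guilt-by-association labels for unannotated genes.

    For each cluster enriched for a term (BH-adjusted p < threshold), every
    unannotated member (a gene in no term set) receives a putative (term,
    cluster, evidence p) label; a gene may collect several labels, and genes
    already carrying any annotation are never re-labeled.
    """
    annotated = set().union(*terms.values()) if terms else set()
    rows = []
    for cid, genes in sorted(clusters.items()):
        genes_in = set(genes) & set(universe)
        if not genes_in:
            continue
        enr = enrich_terms(genes_in, universe, terms)
        for _, r in enr[enr["p_adj"] < p_threshold].iterrows():
            for gene in sorted(genes_in - annotated):
                rows.append((gene, r["term"], cid, float(r["p_adj"])))
    return pd.DataFrame(rows, columns=["gene", "term", "cluster", "evidence_p"])


def rank_candidate_markers(
    divergent,
    terms: dict[str, set[str]],
    universe,
    cold_terms,
    w1: float = 1.0,
    w2: float = 1.0,
    enrich_threshold: float = 0.05,
) -> pd.DataFrame:
    """Composite ranking of divergence-based candidate markers.

    Per gene in any divergent cluster:
    score = -log10(pattern p-value)
          + w1 * [its cluster is enriched for a designated cold term]
          + w2 * (-log10 best adjusted enrichment p of its cluster).
    Genes in several clusters keep their best-scoring membership; ties break
    by gene id.  Returns gene, score, components and 1-based rank.
    """
    cold_terms = set(cold_terms)
    best: dict[str, dict] = {}
    for ci, cl in enumerate(divergent):
        genes_in = set(cl.genes) & set(universe)
        if not genes_in:
            continue
        enr = enrich_terms(genes_in, universe, terms)
        sig = enr[enr["p_adj"] < enrich_threshold]
        cold_flag = bool(set(sig["term"]) & cold_terms)
        best_padj = float(sig["p_adj"].min()) if len(sig) else 1.0
        pat_p = max(cl.pvalue, 1e-300)
        score = (
            -np.log10(pat_p)
            + w1 * float(cold_flag)
            + w2 * (-np.log10(max(best_padj, 1e-300)))
        )
        for g in cl.genes:
            if g not in best or score > best[g]["score"]:
                best[g] = {
                    "gene": g,
                    "score": float(score),
                    "pattern_p": float(cl.pvalue),
                    "cold_cluster": cold_flag,
                    "best_enrichment_p_adj": best_padj,
                    "cluster": ci,
                }
    df = pd.DataFrame(sorted(best.values(), key=lambda r: (-r["score"], r["gene"])))
    if len(df):
        df["rank"] = np.arange(1, len(df) + 1)
    return df


def compare_gene_lists(list_a, list_b, universe) -> dict:
    """Overlap statistics for two gene lists drawn from a shared universe."""
    universe = set(universe)
    if not universe:
        raise ValueError("empty universe")
    a, b = set(list_a), set(list_b)
    if not (a <= universe and b <= universe):
        raise ValueError("lists must be subsets of the universe")
    inter = a & b
    union = a | b
    p = float(stats.hypergeom.sf(len(inter) - 1, len(universe), len(a), len(b)))
    return {
        "n_a": len(a),
        "n_b": len(b),
        "n_overlap": len(inter),
        "jaccard": len(inter) / len(union) if union else 1.0,
        "pvalue": p,
    }
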