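"""Independent brute-force oracles used by the test-suite and acceptance checks.

Everything here is deliberately naive: exhaustive enumeration, rational
arithmetic, O(n^3) loops.  None of it shares code with the package paths it
checks.
"""

import itertools
from fractions import Fraction

import numpy as np

from coldnet.tricluster import discretize_series


def hypergeom_sf_exact(k: int, n_total: int, n_success: int, n_draw: int) -> Fraction:
    """P(X >= k) for a hypergeometric draw, in exact rational arithmetic."""
    from math import comb

    denom = comb(n_total, n_draw)
    num = sum(
        comb(n_success, j) * comb(n_total - n_success, n_draw - j)
        for j in range(k, min(n_success, n_draw) + 1)
    )
    return Fraction(num, denom)


def binom_sf_exact(k: int, n: int, q: Fraction) -> Fraction:
    """P(X >= k) for X ~ Binomial(n, q), exact."""
    from math import comb

    return sum(
        Fraction(comb(n, j)) * q**j * (1 - q) ** (n - j) for j in range(k, n + 1)
    )


def bh_adjust_exact(pvals):
    """Benjamini-Hochberg step-up, written directly from the definition."""
    m = len(pvals)
    order = sorted(range(m), key=lambda i: pvals[i])
    adj = [0.0] * m
    running = 1.0
    for rank_from_top in range(m, 0, -1):
        i = order[rank_from_top - 1]
        running = min(running, pvals[i] * m / rank_from_top)
        adj[i] = running
    return adj


def clustering_coefficients_bruteforce(edge_list):
    """Per-node local clustering coefficient by cubic triangle counting."""
    nodes = sorted({u for e in edge_list for u in e if e[0] != e[1]})
    idx = {n: i for i, n in enumerate(nodes)}
    n = len(nodes)
    adj = np.zeros((n, n), dtype=bool)
    for u, v in edge_list:
        if u != v:
            adj[idx[u], idx[v]] = adj[idx[v], idx[u]] = True
    coeffs = {}
    for i, node in enumerate(nodes):
        neigh = [j for j in range(n) if adj[i, j]]
        d = len(neigh)
        if d < 2:
            coeffs[node] = 0.0
            continue
        tri = 0
        for a in range(d):
            for b in range(a + 1, d):
                if adj[neigh[a], neigh[b]]:
                    tri += 1
        coeffs[node] = 2.0 * tri / (d * (d - 1))
    return coeffs


def brute_force_conserved(x, cfg):
    """All maximal conserved triclusters by exhaustive (subset, window) scan."""
    genes, genotypes, times = x.genes, x.genotypes, x.times
    m = len(times)
    prof = {
        g: x.values[
            x.samples.loc[x.columns_for(g)].sort_values("time").index
        ].to_numpy(dtype=float)
        for g in genotypes
    }
    lo = max(2, cfg.min_window) if cfg.min_window else m
    cands = []
    for a in range(m):
        for b in range(a + lo - 1, m):
            for r in range(2, len(genotypes) + 1):
                for subset in itertools.combinations(range(len(genotypes)), r):
                    groups = {}
                    for gi, gene in enumerate(genes):
                        pats = {
                            discretize_series(prof[genotypes[j]][gi, a : b + 1], cfg.delta)
                            for j in subset
                        }
                        if len(pats) == 1:
                            groups.setdefault(pats.pop(), []).append(gene)
                    for pat, gs in groups.items():
                        cands.append(
                            (
                                frozenset(gs),
                                frozenset(genotypes[j] for j in subset),
                                (a, b),
                                pat,
                            )
                        )
    out = set()
    for c in cands:
        dominated = False
        for d in cands:
            if c == d:
                continue
            if (
                d[0] >= c[0]
                and d[1] >= c[1]
                and d[2][0] <= c[2][0]
                and d[2][1] >= c[2][1]
                and d[3][c[2][0] - d[2][0] : c[2][1] - d[2][0]] == c[3]
                and (d[0], d[1], d[2]) != (c[0], c[1], c[2])
            ):
                dominated = True
                break
        if not dominated and len(c[0]) >= cfg.min_genes:
            out.add(c)
    return out
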