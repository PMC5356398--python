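"""Order-preserving triclustering over genes x genotypes x time.

Each gene's per-genotype time course is discretized into a qualitative
pattern string over consecutive intervals (U = up by more than ``delta`` log2
units, D = down, N = no change).  Conserved triclusters are maximal gene sets
whose pattern strings are identical across a genotype subset over a time
window; divergent calls flag genes whose pattern in a genotype subset differs
from the complementary genotypes (unique patterns, sign-flipped responses, or
the same response delayed by a few time steps).  Cluster significance comes
from a binomial null on pattern co-occurrence.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator

from .expression import ExpressionMatrix

__all__ = [
    "Tricluster",
    "OrderPreservingTricluster",
    "discretize_series",
    "find_conserved",
    "find_divergent",
    "pattern_pvalue",
    "genotype_overlap_summary",
]


@dataclass(frozen=True)
class Tricluster:
    """One conserved or divergent pattern call.

    ``window`` is an inclusive (start, end) pair of time indices; ``pattern``
    has one symbol per consecutive interval (length = window length - 1).
    For divergent calls ``other_pattern`` is the complementary genotypes'
    pattern ("*" when they disagree among themselves) and ``shift`` is the
    detected activation delay in time steps (positive: the named subset lags
    the complement; negative: it leads; 0: no delay structure).
    """

    genes: tuple[str, ...]
    genotypes: tuple[str, ...]
    window: tuple[int, int]
    pattern: str
    kind: str                       # "conserved" | "divergent"
    pvalue: float = float("nan")
    other_pattern: str | None = None
    shift: int = 0

    def __post_init__(self) -> None:
        if len(self.pattern) != self.window[1] - self.window[0]:
            raise ValueError("pattern length must equal window length - 1")


def discretize_series(values, delta: float) -> str:
    """Encode a log2 time profile as a U/D/N string over consecutive intervals."""
    v = np.asarray(values, dtype=float)
    if v.ndim != 1 or len(v) < 2:
        raise ValueError("need a 1-D profile with >= 2 time points")
    if not np.all(np.isfinite(v)):
        raise ValueError("non-finite value in profile")
    diffs = np.diff(v)
    return "".join("U" if d > delta else "D" if d < -delta else "N" for d in diffs)


def _pattern_table(
    x: ExpressionMatrix, delta: float
) -> tuple[list[str], list[str], np.ndarray, dict[str, np.ndarray]]:
    """Per-gene, per-genotype full-course patterns as a gene x genotype array."""
    if x.has_replicates:
        raise ValueError("triclustering expects replicate-averaged data")
    genotypes = x.genotypes
    times = x.times
    grids = {}
    for g in genotypes:
        block = x.samples.loc[x.columns_for(g)].sort_values("time")
        grids[g] = list(block["time"])
        if grids[g] != times:
            raise ValueError("genotypes must share a common time grid")
    genes = x.genes
    profiles = {
        g: x.values[
            x.samples.loc[x.columns_for(g)].sort_values("time").index
        ].to_numpy(dtype=float)
        for g in genotypes
    }
    pats = np.empty((len(genes), len(genotypes)), dtype=object)
    for j, g in enumerate(genotypes):
        diffs = np.diff(profiles[g], axis=1)
        sym = np.where(diffs > delta, "U", np.where(diffs < -delta, "D", "N"))
        pats[:, j] = ["".join(row) for row in sym]
    return genes, genotypes, pats, profiles


def _windows(m: int, min_window: int | None) -> list[tuple[int, int]]:
    if min_window is None:
        return [(0, m - 1)]
    lo = max(2, min_window)
    return [
        (a, b)
        for a in range(m)
        for b in range(a + lo - 1, m)
    ]


@dataclass(frozen=True)
class TriConfig:
    """Triclustering controls: discretization band, size cutoffs and null."""

    delta: float = 0.5
    min_genes: int = 5
    min_window: int | None = None     # None: full time course only
    pvalue_cutoff: float = 1e-4
    symbol_null: str = "uniform"      # "uniform" | "empirical"
    max_shift: int = 1

    def __post_init__(self) -> None:
        if self.delta < 0:
            raise ValueError("delta must be >= 0")
        if self.min_genes < 1:
            raise ValueError("min_genes must be >= 1")


def _symbol_frequencies(pats: np.ndarray) -> dict[str, float]:
    counts = {s: 0 for s in "UDN"}
    total = 0
    for pat in pats.ravel():
        for s in pat:
            counts[s] += 1
            total += 1
    return {s: c / total for s, c in counts.items()} if total else {s: 1 / 3 for s in "UDN"}


def pattern_pvalue(
    cluster: Tricluster,
    n_genes: int,
    background: dict[str, float] | None = None,
) -> float:
    """Binomial tail p-value for a cluster of its size under a symbol null.

    The null probability q that one gene shows the cluster's pattern in every
    genotype of its subset is ``(1/3)^(L * |S'|)`` under the uniform null, or
    the product of observed symbol frequencies under the empirical null.
    p = P(X >= |genes|) with X ~ Binomial(n_genes, q).
    """
    length = len(cluster.pattern)
    n_geno = len(cluster.genotypes)
    if background is None:
        q = (1.0 / 3.0) ** (length * n_geno)
    else:
        if not np.isclose(sum(background.values()), 1.0):
            raise ValueError("background frequencies must sum to 1")
        q_single = float(np.prod([background[s] for s in cluster.pattern]))
        q = q_single**n_geno
    observed = len(cluster.genes)
    if observed == 0:
        return 1.0
    if q == 0.0:
        warnings.warn("null pattern probability is 0 for a nonempty cluster; p set to 0")
        return 0.0
    return float(stats.binom.sf(observed - 1, n_genes, q))


def find_conserved(x: ExpressionMatrix, cfg: TriConfig = TriConfig()) -> list[Tricluster]:
    """Maximal conserved triclusters (identical patterns across >= 2 genotypes).

    Maximality holds in all three dimensions: no gene, genotype, or window
    extension preserves the agreement.  Single-genotype input yields an empty
    list with a warning.
    """
    genes, genotypes, pats, profiles = _pattern_table(x, cfg.delta)
    if len(genotypes) < 2:
        warnings.warn("conserved patterns need >= 2 genotypes; returning empty list")
        return []
    background = _symbol_frequencies(pats) if cfg.symbol_null == "empirical" else None
    m = len(x.times)
    candidates: list[Tricluster] = []
    for a, b in _windows(m, cfg.min_window)[::-1]:
        # per-gene per-genotype pattern restricted to the window's intervals
        win = np.empty_like(pats)
        for j in range(len(genotypes)):
            win[:, j] = [p[a:b] for p in pats[:, j]]
        # block: for each gene, maximal genotype sets with identical pattern
        per_key: dict[tuple[frozenset[int], str], list[int]] = {}
        blocks: list[dict[str, frozenset[int]]] = []
        for gi in range(len(genes)):
            by_pat: dict[str, list[int]] = {}
            for j in range(len(genotypes)):
                by_pat.setdefault(win[gi, j], []).append(j)
            gene_blocks = {p: frozenset(js) for p, js in by_pat.items()}
            blocks.append(gene_blocks)
            for p, js in gene_blocks.items():
                if len(js) >= 2:
                    per_key.setdefault((js, p), []).append(gi)
        for (js, p), members in per_key.items():
            # all genes whose same-pattern block contains js
            full = [gi for gi in range(len(genes)) if blocks[gi].get(p, frozenset()) >= js]
            inter = frozenset.intersection(*(blocks[gi][p] for gi in full))
            if inter != js:
                continue  # dominated by the larger-genotype-set cluster
            if len(full) < cfg.min_genes:
                continue
            cl = Tricluster(
                genes=tuple(sorted(genes[gi] for gi in full)),
                genotypes=tuple(genotypes[j] for j in sorted(js)),
                window=(a, b),
                pattern=p,
                kind="conserved",
            )
            cl = _with_pvalue(cl, len(genes), background)
            candidates.append(cl)
    return _prune_window_dominated(candidates)


def _with_pvalue(cl: Tricluster, n_genes: int, background) -> Tricluster:
    p = pattern_pvalue(cl, n_genes, background)
    return Tricluster(
        genes=cl.genes, genotypes=cl.genotypes, window=cl.window,
        pattern=cl.pattern, kind=cl.kind, pvalue=p,
        other_pattern=cl.other_pattern, shift=cl.shift,
    )


def _prune_window_dominated(clusters: list[Tricluster]) -> list[Tricluster]:
    """Drop clusters strictly contained in another (genes, genotypes, window)."""
    out = []
    for c in clusters:
        dominated = False
        for d in clusters:
            if d is c:
                continue
            if (
                set(d.genes) >= set(c.genes)
                and set(d.genotypes) >= set(c.genotypes)
                and d.window[0] <= c.window[0]
                and d.window[1] >= c.window[1]
                and d.pattern[c.window[0] - d.window[0] : c.window[1] - d.window[0]]
                == c.pattern
                and (d.genes, d.genotypes, d.window) != (c.genes, c.genotypes, c.window)
            ):
                dominated = True
                break
        if not dominated:
            out.append(c)
    return sorted(out, key=lambda c: (c.window, c.genotypes, c.pattern))


def find_divergent(x: ExpressionMatrix, cfg: TriConfig = TriConfig()) -> list[Tricluster]:
    """Genotype-subset-specific pattern calls, grouped by (subset, pattern pair).

    A gene is divergent on subset S' when its (identical within S') pattern
    differs from every complementary genotype's pattern; only the minority
    side of each partition is reported (the genotype-specific behavior).  When the complement
    shares one pattern, a shift annotation is attached if one side's pattern
    is the other's delayed by up to ``max_shift`` steps (positive shift: S'
    lags the complement).
    """
    genes, genotypes, pats, _ = _pattern_table(x, cfg.delta)
    if len(genotypes) < 2:
        warnings.warn("divergent patterns need >= 2 genotypes; returning empty list")
        return []
    background = _symbol_frequencies(pats) if cfg.symbol_null == "empirical" else None
    m = len(x.times)
    a, b = 0, m - 1
    groups: dict[tuple[frozenset[int], str, str, int], list[int]] = {}
    for gi in range(len(genes)):
        by_pat: dict[str, list[int]] = {}
        for j in range(len(genotypes)):
            by_pat.setdefault(pats[gi, j], []).append(j)
        if len(by_pat) < 2:
            continue
        for p, js in by_pat.items():
            comp = [j for j in range(len(genotypes)) if j not in js]
            if len(js) > len(comp):
                continue  # report the minority side of the partition only
            comp_pats = {pats[gi, j] for j in comp}
            if p in comp_pats:
                continue
            other = comp_pats.pop() if len(comp_pats) == 1 else "*"
            shift = _detect_shift(p, other, cfg.max_shift) if other != "*" else 0
            groups.setdefault((frozenset(js), p, other, shift), []).append(gi)
    out = []
    for (js, p, other, shift), members in groups.items():
        if len(members) < cfg.min_genes:
            continue
        cl = Tricluster(
            genes=tuple(sorted(genes[gi] for gi in members)),
            genotypes=tuple(genotypes[j] for j in sorted(js)),
            window=(a, b),
            pattern=p,
            kind="divergent",
            other_pattern=other,
            shift=shift,
        )
        out.append(_with_pvalue(cl, len(genes), background))
    return sorted(out, key=lambda c: (c.genotypes, c.pattern))


def _detect_shift(pattern: str, other: str, max_shift: int) -> int:
    """Delay between two equal-length patterns: +d if ``pattern`` lags ``other``."""
    for d in range(1, max_shift + 1):
        if len(pattern) > d and pattern == "N" * d + other[: len(other) - d]:
            return d
        if len(other) > d and other == "N" * d + pattern[: len(pattern) - d]:
            return -d
    return 0


def genotype_overlap_summary(
    conserved: list[Tricluster],
    universe: list[str],
    divergent: list[Tricluster] | None = None,
) -> pd.DataFrame:
    """Per-genotype-combination sharing table.

    For each genotype combination (size >= 2): the percentage of universe
    genes in some conserved cluster of exactly that combination.  Singleton
    rows report uniquely-changed gene counts from divergent calls with a
    single-genotype subset (0 when no divergent list is given).
    """
    n_universe = len(universe)
    if n_universe == 0:
        raise ValueError("empty universe")
    combos: dict[tuple[str, ...], set[str]] = {}
    all_genotypes: list[str] = []
    for cl in conserved:
        combos.setdefault(cl.genotypes, set()).update(cl.genes)
        for g in cl.genotypes:
            if g not in all_genotypes:
                all_genotypes.append(g)
    singles: dict[str, set[str]] = {}
    if divergent:
        for cl in divergent:
            for g in cl.genotypes:
                if g not in all_genotypes:
                    all_genotypes.append(g)
            if len(cl.genotypes) == 1:
                singles.setdefault(cl.genotypes[0], set()).update(cl.genes)
    rows = []
    for size in range(len(all_genotypes), 1, -1):
        for combo in itertools.combinations(all_genotypes, size):
            genes = combos.get(tuple(combo), set())
            rows.append(
                ("+".join(combo), size, len(genes), 100.0 * len(genes) / n_universe)
            )
    for g in all_genotypes:
        genes = singles.get(g, set())
        rows.append((g, 1, len(genes), 100.0 * len(genes) / n_universe))
    return pd.DataFrame(rows, columns=["combination", "size", "n_genes", "percent"])


def clusters_to_tsv(clusters: list[Tricluster], path) -> None:
    rows = []
    for c in clusters:
        rows.append(
            {
                "kind": c.kind,
                "genotypes": "+".join(c.genotypes),
                "window_start": c.window[0],
                "window_end": c.window[1],
                "pattern": c.pattern,
                "other_pattern": c.other_pattern or "",
                "shift": c.shift,
                "n_genes": len(c.genes),
                "pvalue": c.pvalue,
                "genes": ";".join(c.genes),
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, float_format="%.6g")


class OrderPreservingTricluster(BaseEstimator):
    """Estimator wrapper: fit() mines conserved and divergent triclusters.

    Attributes after fit: ``conserved_``, ``divergent_`` (lists of
    :class:`Tricluster`, significant ones only per ``pvalue_cutoff`` for the
    conserved branch), ``summary_`` (genotype-combination sharing table).
    """

    def __init__(
        self,
        delta: float = 0.5,
        min_genes: int = 5,
        min_window: int | None = None,
        pvalue_cutoff: float = 1e-4,
        symbol_null: str = "uniform",
        max_shift: int = 1,
    ):
        self.delta = delta
        self.min_genes = min_genes
        self.min_window = min_window
        self.pvalue_cutoff = pvalue_cutoff
        self.symbol_null = symbol_null
        self.max_shift = max_shift

    def _config(self) -> TriConfig:
        return TriConfig(
            delta=self.delta, min_genes=self.min_genes, min_window=self.min_window,
            pvalue_cutoff=self.pvalue_cutoff, symbol_null=self.symbol_null,
            max_shift=self.max_shift,
        )

    def fit(self, X: ExpressionMatrix, y=None):
        cfg = self._config()
        self.conserved_ = find_conserved(X, cfg)
        self.divergent_ = find_divergent(X, cfg)
        self.summary_ = genotype_overlap_summary(
            [c for c in self.conserved_ if c.pvalue < self.pvalue_cutoff],
            X.genes,
            self.divergent_,
        )
        return self
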