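"""Prior-seeded linear-model inference of TF-target regulation.

Expression is modeled as ``A = Lambda F + E``: A (n x M) the combined log2
expression matrix, Lambda (n x k) the signed connectivity from k TFs to n
genes, F (k x M) the latent TF activity (TFA) profiles and E Gaussian error.
The algorithm has three steps:

1. *Initialization* — the candidate signed support ``Lambda0`` combines a
   literature prior (entries in {-1, 0, +1}) with expression-derived edges:
   ``sign(rho)`` for TF-gene pairs whose Pearson correlation across the M
   columns clears a threshold, literature winning conflicts.
2. *Alternating least squares* — gene rows of Lambda (restricted to their
   candidate TF sets) and F are updated by exact ridge solves until the sum
   of squared changes of F falls below ``epsilon``.
3. *Refinement* — per-gene elastic-net re-estimation sparsifies the support;
   permutation (or t-approximation) p-values are attached to surviving edges
   and edges with p >= p0 are removed.

All of this is wrapped in the sklearn-style estimator :class:`NetworkALS`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator
from sklearn.linear_model import ElasticNet, ElasticNetCV

__all__ = [
    "PriorNetwork",
    "FitResult",
    "NetworkALS",
    "init_connectivity",
    "init_activity",
    "als_fit",
    "elastic_net_refine",
    "edge_pvalues",
    "enet_solve",
]


@dataclass
class PriorNetwork:
    """Signed literature connectivity over (TF, gene) pairs.

    ``matrix`` is k x n with entries in {-1, 0, +1}; a TF id may also occur
    among the gene ids (TF-TF regulation).
    """

    tfs: list[str]
    genes: list[str]
    matrix: np.ndarray

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix)
        if self.matrix.shape != (len(self.tfs), len(self.genes)):
            raise ValueError("prior matrix shape does not match tf/gene ids")
        if not np.isin(self.matrix, (-1, 0, 1)).all():
            raise ValueError("prior entries must be in {-1, 0, +1}")

    @classmethod
    def empty(cls, tfs: list[str], genes: list[str]) -> "PriorNetwork":
        return cls(tfs, genes, np.zeros((len(tfs), len(genes)), dtype=np.int8))

    @classmethod
    def from_edges(
        cls, edges, tfs: list[str] | None = None, genes: list[str] | None = None
    ) -> "PriorNetwork":
        """Build from an iterable of (tf, gene, sign) triples."""
        edges = list(edges)
        tfs = tfs if tfs is not None else sorted({e[0] for e in edges})
        genes = genes if genes is not None else sorted({e[1] for e in edges})
        ti = {t: i for i, t in enumerate(tfs)}
        gi = {g: i for i, g in enumerate(genes)}
        m = np.zeros((len(tfs), len(genes)), dtype=np.int8)
        for tf, gene, sign in edges:
            m[ti[tf], gi[gene]] = int(sign)
        return cls(tfs, genes, m)

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("tf\tgene\tsign\n")
            for i, j in zip(*np.nonzero(self.matrix)):
                fh.write(f"{self.tfs[i]}\t{self.genes[j]}\t{int(self.matrix[i, j])}\n")

    @classmethod
    def read_tsv(cls, path) -> "PriorNetwork":
        df = pd.read_csv(path, sep="\t")
        return cls.from_edges(df[["tf", "gene", "sign"]].itertuples(index=False))


@dataclass
class FitResult:
    """Output of the three-step fit.

    ``lambda_hat`` is oriented genes x TFs (the n x k connectivity as it
    multiplies F in A = Lambda F); ``edge_pvalues`` holds NaN where
    ``lambda_hat`` is zero.
    """

    genes: list[str]
    tfs: list[str]
    lambda_hat: np.ndarray            # n x k
    f_hat: np.ndarray                 # k x M
    residual: np.ndarray              # n x M
    candidate_support: np.ndarray     # n x k bool
    objective_trace: list[float]
    converged: bool
    n_iter: int
    edge_pvalues: np.ndarray | None = None   # n x k, NaN off-support

    def edges(self) -> pd.DataFrame:
        """Long-format edge table: tf, gene, weight, sign, pvalue."""
        rows = []
        for g, t in zip(*np.nonzero(self.lambda_hat)):
            w = self.lambda_hat[g, t]
            p = float(self.edge_pvalues[g, t]) if self.edge_pvalues is not None else np.nan
            rows.append((self.tfs[t], self.genes[g], float(w), int(np.sign(w)), p))
        return pd.DataFrame(rows, columns=["tf", "gene", "weight", "sign", "pvalue"])

    def to_tsv(self, path) -> None:
        self.edges().to_csv(path, sep="\t", index=False, float_format="%.6g")

    def to_sif(self, path) -> None:
        with open(path, "w") as fh:
            for _, row in self.edges().iterrows():
                fh.write(f"{row.tf}\tregulates\t{row.gene}\n")


# ---------------------------------------------------------------------------
# step 1: initialization


def init_connectivity(
    prior: PriorNetwork,
    values: np.ndarray,
    gene_ids: list[str],
    expr_init_threshold: float = 0.8,
) -> np.ndarray:
    """Candidate signed support Lambda0 (n x k) from prior + TF expression.

    Expression-derived entries are ``sign(rho)`` where ``|rho| >=
    expr_init_threshold`` for the Pearson correlation between the TF's own
    expression row and the gene row across the M columns; literature entries
    win conflicts.  TFs whose expression row is absent contribute literature
    entries only; zero-variance TF rows are excluded with a warning.
    """
    values = np.asarray(values, dtype=float)
    n = len(gene_ids)
    k = len(prior.tfs)
    gi = {g: i for i, g in enumerate(gene_ids)}
    lam0 = np.zeros((n, k), dtype=np.int8)

    centered = values - values.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(centered, axis=1)
    for t, tf in enumerate(prior.tfs):
        row = gi.get(tf)
        if row is None:
            continue
        if norms[row] == 0:
            warnings.warn(f"TF {tf} has zero-variance expression; excluded from Lambda_T")
            continue
        with np.errstate(invalid="ignore"):
            rho = (centered @ centered[row]) / (norms * norms[row])
        rho[norms == 0] = 0.0
        rho[row] = 0.0  # no self-edge from autocorrelation
        hits = np.abs(rho) >= expr_init_threshold
        lam0[hits, t] = np.sign(rho[hits]).astype(np.int8)

    # literature overlay wins conflicts
    for t in range(k):
        for j, gene in enumerate(prior.genes):
            v = prior.matrix[t, j]
            if v != 0 and gene in gi:
                lam0[gi[gene], t] = v
    return lam0


def init_activity(lambda0: np.ndarray, values: np.ndarray, ridge: float = 1e-6) -> np.ndarray:
    """Ridge least-squares TFA initialization: argmin ||A - L0 F||^2 + ridge ||F||^2."""
    lam = np.asarray(lambda0, dtype=float)
    if not np.any(lam):
        raise ValueError("all-zero candidate connectivity: cannot initialize F")
    k = lam.shape[1]
    gram = lam.T @ lam + ridge * np.eye(k)
    return np.linalg.solve(gram, lam.T @ np.asarray(values, dtype=float))


# ---------------------------------------------------------------------------
# step 2: alternating least squares


def _objective(a: np.ndarray, lam: np.ndarray, f: np.ndarray, ridge: float) -> float:
    resid = a - lam @ f
    return float((resid**2).sum() + ridge * ((lam**2).sum() + (f**2).sum()))


def _update_lambda(
    a: np.ndarray, f: np.ndarray, support: np.ndarray, ridge: float
) -> np.ndarray:
    """Exact per-gene ridge solve restricted to each gene's candidate TF set."""
    n, k = support.shape
    lam = np.zeros((n, k))
    # genes sharing a support pattern share the normal equations matrix
    patterns: dict[bytes, list[int]] = {}
    for g in range(n):
        patterns.setdefault(support[g].tobytes(), []).append(g)
    for patt, rows in patterns.items():
        s = np.frombuffer(patt, dtype=bool)
        if not s.any():
            continue
        fs = f[s]                     # |s| x M
        gram = fs @ fs.T + ridge * np.eye(int(s.sum()))
        coef = np.linalg.solve(gram, fs @ a[rows].T)   # |s| x len(rows)
        lam[np.ix_(rows, np.flatnonzero(s))] = coef.T
    return lam


def als_fit(
    values: np.ndarray,
    lambda0: np.ndarray,
    *,
    ridge: float = 1e-6,
    epsilon: float = 1e-6,
    max_iter: int = 500,
) -> tuple[np.ndarray, np.ndarray, list[float], bool, int]:
    """Alternate exact ridge solves for Lambda (on its candidate support) and F.

    Stops when the sum of squared changes of F drops below ``epsilon`` or at
    ``max_iter`` (returned with ``converged=False``, never an exception).  The
    recorded penalized objective ``||A - Lambda F||^2 + ridge(||Lambda||^2 +
    ||F||^2)`` is non-increasing at every half-step because each half-step
    minimizes it exactly in its own block.  On return, rows of F are rescaled
    to unit RMS with the inverse factor absorbed into Lambda (a pure
    reparameterization: Lambda F, the residual and the objective are
    unchanged).
    """
    a = np.asarray(values, dtype=float)
    support = np.asarray(lambda0) != 0
    lam = np.asarray(lambda0, dtype=float).copy()
    f = init_activity(lambda0, a, ridge)
    trace = [_objective(a, lam, f, ridge)]
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        lam = _update_lambda(a, f, support, ridge)
        trace.append(_objective(a, lam, f, ridge))
        f_new = init_activity(lam, a, ridge)
        trace.append(_objective(a, lam, f_new, ridge))
        delta = float(((f_new - f) ** 2).sum())
        f = f_new
        if delta < epsilon:
            converged = True
            break
    lam, f = _rescale(lam, f)
    return lam, f, trace, converged, it


def _rescale(lam: np.ndarray, f: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Unit-RMS convention on F rows; inverse factor absorbed into Lambda."""
    rms = np.sqrt((f**2).mean(axis=1))
    scale = np.where(rms > 0, rms, 1.0)
    return lam * scale[None, :], f / scale[:, None]


def _align_signs(lam: np.ndarray, f: np.ndarray, lam0: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Resolve the per-TF sign indeterminacy (Lambda F == (-Lambda)(-F)).

    Each TF's (Lambda column, F row) pair is flipped when the majority of its
    fitted signs disagree with the signed candidate support Lambda0, anchoring
    the convention to the prior/initialization signs.
    """
    lam = lam.copy()
    f = f.copy()
    for t in range(lam.shape[1]):
        anchored = np.flatnonzero(lam0[:, t] * lam[:, t])
        if len(anchored) == 0:
            continue
        agreement = np.sign(lam[anchored, t]) * np.sign(lam0[anchored, t])
        if agreement.sum() < 0:
            lam[:, t] *= -1.0
            f[t] *= -1.0
    return lam, f


# ---------------------------------------------------------------------------
# step 3: refinement and p-values


def enet_solve(x: np.ndarray, y: np.ndarray, l1: float, l2: float) -> np.ndarray:
    """Naive elastic net: argmin 1/2 ||y - X b||^2 + l1 ||b||_1 + l2/2 ||b||^2.

    For orthonormal X this is the soft-threshold closed form
    ``S(b_ols, l1) / (1 + l2)``.  Delegates to sklearn's coordinate descent
    via an exact penalty re-parameterization; plain least squares when both
    penalties are zero.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if l1 == 0.0 and l2 == 0.0:
        return np.linalg.lstsq(x, y, rcond=None)[0]
    n_samples = x.shape[0]
    total = l1 + l2
    alpha = total / n_samples
    l1_ratio = l1 / total
    model = ElasticNet(
        alpha=alpha, l1_ratio=l1_ratio, fit_intercept=False,
        max_iter=100000, tol=1e-12,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model.fit(x, y)
    return model.coef_


def elastic_net_refine(
    lam: np.ndarray,
    f: np.ndarray,
    values: np.ndarray,
    *,
    enet_alpha: float = 0.5,
    enet_lambda: float | str = 0.01,
    seed: int = 0,
) -> np.ndarray:
    """Per-gene elastic-net re-estimation on the fitted TFA design.

    ``enet_alpha`` mixes the l1/l2 penalties (1 = lasso); ``enet_lambda`` is
    the total penalty, or ``"cv"`` for per-gene cross-validation.  Zeroed
    coefficients leave the support.  Genes whose candidate set has fewer than
    2 TFs are skipped with a warning (their ALS coefficients are kept).
    """
    a = np.asarray(values, dtype=float)
    out = np.zeros_like(lam)
    skipped = 0
    for g in range(lam.shape[0]):
        s = np.flatnonzero(lam[g])
        if len(s) == 0:
            continue
        if len(s) < 2:
            out[g, s] = lam[g, s]
            skipped += 1
            continue
        design = f[s].T                       # M x |s|
        if enet_lambda == "cv":
            model = ElasticNetCV(
                l1_ratio=enet_alpha, fit_intercept=False, cv=3,
                random_state=seed, max_iter=50000,
            )
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                model.fit(design, a[g])
            coef = model.coef_
        else:
            pen = float(enet_lambda)
            coef = enet_solve(design, a[g], pen * enet_alpha, pen * (1 - enet_alpha))
        out[g, s] = coef
    if skipped:
        warnings.warn(f"elastic-net refinement skipped {skipped} single-TF genes")
    return out


def edge_pvalues(
    lam: np.ndarray,
    f: np.ndarray,
    values: np.ndarray,
    *,
    method: str = "permutation",
    n_permutations: int = 1999,
    ridge: float = 1e-6,
    seed: int = 0,
    support: np.ndarray | None = None,
) -> np.ndarray:
    """Per-edge significance of the fitted coefficients.

    permutation (default): a conditional permutation test per edge.  For gene
    g and TF j, the observed statistic is the fitted |w_gj|; the null
    distribution is the partial-regression coefficient of a column-permuted
    copy of TF j's activity profile, with the gene's other candidate TFs (and
    an intercept) projected out, over B random permutations.  The edge's p is
    ``(1 + #{|null| >= |w_gj|}) / (B + 1)``, so the smallest attainable p is
    1/(B+1).  Permuting only the tested profile keeps the rest of the gene's
    regulatory signal in the model, which preserves power for weak edges on
    genes that also carry strong ones.
    t-approx: two-sided t-test p-values from the per-gene OLS fit on the
    final support.  Returns an n x k array with NaN off-support.
    """
    a = np.asarray(values, dtype=float)
    n, k = lam.shape
    m = a.shape[1]
    mask = (lam != 0) if support is None else np.asarray(support, dtype=bool)
    pvals = np.full((n, k), np.nan)
    if method == "t-approx":
        for g in range(n):
            s = np.flatnonzero(mask[g])
            if len(s) == 0:
                continue
            design = f[s].T
            coef, *_ = np.linalg.lstsq(design, a[g], rcond=None)
            resid = a[g] - design @ coef
            df = m - len(s)
            if df <= 0:
                pvals[g, s] = 1.0
                continue
            sigma2 = (resid**2).sum() / df
            cov = sigma2 * np.linalg.inv(design.T @ design)
            with np.errstate(divide="ignore", invalid="ignore"):
                tstat = coef / np.sqrt(np.diag(cov))
            pvals[g, s] = 2 * stats.t.sf(np.abs(tstat), df)
        return pvals
    if method != "permutation":
        raise ValueError(f"unknown p-value method {method!r}")
    b = int(n_permutations)
    if b < 19:
        raise ValueError("n_permutations must be >= 19 to resolve p < 0.05")
    rng = np.random.default_rng(seed)
    perms = np.array([rng.permutation(m) for _ in range(b)])
    ones = np.ones((m, 1))
    for g in range(n):
        s = np.flatnonzero(mask[g])
        if len(s) == 0:
            continue
        y = a[g]
        for j in s:
            obs = abs(lam[g, j])
            if obs == 0.0:
                pvals[g, j] = 1.0
                continue
            others = [t for t in s if t != j]
            basis = np.hstack([ones, f[others].T]) if others else ones
            q, _ = np.linalg.qr(basis)
            my = y - q @ (q.T @ y)
            xp = f[j][perms]                          # B x M permuted profile
            qtx = q.T @ xp.T                          # rank x B
            num = xp @ my
            den = (xp**2).sum(axis=1) - (qtx**2).sum(axis=0) + ridge
            null = np.abs(num / den)
            pvals[g, j] = (1.0 + int((null >= obs).sum())) / (b + 1.0)
    return pvals


# ---------------------------------------------------------------------------
# estimator


class NetworkALS(BaseEstimator):
    """Sklearn-style estimator for the three-step TF-target inference.

    Parameters
    ----------
    ridge : float
        L2 stabilization used in every ALS solve.
    epsilon : float
        Convergence cutoff on the sum of squared changes of F.
    max_iter : int
        ALS iteration cap (non-convergence is flagged, not raised).
    enet_alpha, enet_lambda
        Elastic-net mixing in [0, 1] and total penalty (or ``"cv"``).
    p0 : float
        Edge retention threshold: edges with p >= p0 are removed (strict
        "lower than" rule).
    pvalue_method : {"permutation", "t-approx"}
    n_permutations : int
        Permutation count B; the smallest attainable p is 1/(B+1).
    expr_init_threshold : float
        |Pearson r| cutoff for expression-derived candidate edges.
    center : bool
        Row-center the expression matrix before fitting (removes per-gene
        baselines, which the bilinear model does not represent).
    refine : bool
        Run the elastic-net refinement step.
    seed : int
        Seed for permutations and cross-validation.

    Attributes (after fit)
    ----------------------
    connectivity_ : n x k fitted weights; activities_ : k x M TFA profiles;
    residual_; candidate_support_; edge_pvalues_; objective_trace_;
    converged_; n_iter_; result_ : the full :class:`FitResult`.
    """

    def __init__(
        self,
        ridge: float = 1e-6,
        epsilon: float = 1e-6,
        max_iter: int = 500,
        enet_alpha: float = 0.5,
        enet_lambda: float | str = 0.01,
        p0: float = 1e-3,
        pvalue_method: str = "permutation",
        n_permutations: int = 1999,
        expr_init_threshold: float = 0.8,
        center: bool = True,
        refine: bool = True,
        seed: int = 0,
    ):
        self.ridge = ridge
        self.epsilon = epsilon
        self.max_iter = max_iter
        self.enet_alpha = enet_alpha
        self.enet_lambda = enet_lambda
        self.p0 = p0
        self.pvalue_method = pvalue_method
        self.n_permutations = n_permutations
        self.expr_init_threshold = expr_init_threshold
        self.center = center
        self.refine = refine
        self.seed = seed

    def _validate(self) -> None:
        if not self.epsilon > 0:
            raise ValueError("epsilon must be > 0")
        if not 0 < self.p0 < 1:
            raise ValueError("p0 must be in (0, 1)")
        if not 0 <= self.enet_alpha <= 1:
            raise ValueError("enet_alpha must be in [0, 1]")
        if self.ridge < 0:
            raise ValueError("ridge must be >= 0")

    def fit(self, X, y=None, *, prior: PriorNetwork, gene_ids: list[str] | None = None):
        """Fit on a combined genes x M matrix (array or ExpressionMatrix)."""
        self._validate()
        from .expression import ExpressionMatrix

        if isinstance(X, ExpressionMatrix):
            gene_ids = X.genes
            values = X.values.to_numpy(dtype=float)
        else:
            values = np.asarray(X, dtype=float)
            if gene_ids is None:
                gene_ids = [f"g{i}" for i in range(values.shape[0])]
        if values.ndim != 2:
            raise ValueError("expression must be 2-D (genes x samples)")

        a = values - values.mean(axis=1, keepdims=True) if self.center else values
        lam0 = init_connectivity(prior, a, gene_ids, self.expr_init_threshold)
        lam, f, trace, converged, n_iter = als_fit(
            a, lam0, ridge=self.ridge, epsilon=self.epsilon, max_iter=self.max_iter
        )
        lam, f = _align_signs(lam, f, lam0)
        if self.refine:
            lam = elastic_net_refine(
                lam, f, a,
                enet_alpha=self.enet_alpha, enet_lambda=self.enet_lambda,
                seed=self.seed,
            )
        pvals = edge_pvalues(
            lam, f, a,
            method=self.pvalue_method, n_permutations=self.n_permutations,
            ridge=self.ridge, seed=self.seed,
        )
        drop = np.isfinite(pvals) & (pvals >= self.p0)
        lam = np.where(drop, 0.0, lam)
        pvals = np.where(lam != 0, pvals, np.nan)

        self.result_ = FitResult(
            genes=list(gene_ids),
            tfs=list(prior.tfs),
            lambda_hat=lam,
            f_hat=f,
            residual=a - lam @ f,
            candidate_support=lam0 != 0,
            objective_trace=trace,
            converged=converged,
            n_iter=n_iter,
            edge_pvalues=pvals,
        )
        self.connectivity_ = lam
        self.activities_ = f
        self.residual_ = self.result_.residual
        self.candidate_support_ = self.result_.candidate_support
        self.edge_pvalues_ = pvals
        self.objective_trace_ = trace
        self.converged_ = converged
        self.n_iter_ = n_iter
        return self

    def edges(self) -> pd.DataFrame:
        return self.result_.edges()
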