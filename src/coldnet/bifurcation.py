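"""Dynamic regulatory maps: tree-structured temporal paths with TF splits.

Genes' log2 fold-change profiles (relative to the first time point) are fit
with a tree of Gaussian path models: all genes start at a common root (mean
exactly 0 at time 0); at each subsequent time point a node may bifurcate into
at most ``max_children`` branches when a 1-D Gaussian-mixture split of that
time's residuals improves BIC.  After the tree shape is fixed by this greedy
growth, soft gene-to-path assignment and per-node means/SDs are refined by EM
(log-likelihood non-decreasing), and genes receive their maximum-posterior
path.  Each split is then annotated with the transcription factors whose
inferred targets are over-represented in one branch (hypergeometric
upper-tail test against the genes at the split), keeping TFs below a split
cutoff score (default 0.005).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator
from sklearn.mixture import GaussianMixture

from .expression import ExpressionMatrix

__all__ = [
    "RegulatoryMapModel",
    "SplitAnnotation",
    "to_fold_change",
    "score_tf_splits",
    "export_map",
    "load_map",
]


def to_fold_change(x: ExpressionMatrix, genotype: str) -> pd.DataFrame:
    """Gene x time log2 fold-change profiles relative to the first time point.

    Expects replicate-averaged data; the baseline column is identically 0 and
    the operation is idempotent.
    """
    cols = x.samples.loc[x.columns_for(genotype)].sort_values("time")
    if len(cols) == 0:
        raise ValueError(f"genotype {genotype!r} not present")
    times = list(cols["time"])
    block = x.values[list(cols.index)].to_numpy(dtype=float)
    fc = block - block[:, [0]]
    return pd.DataFrame(fc, index=x.genes, columns=times)


@dataclass(frozen=True)
class SplitAnnotation:
    """A TF significantly associated with one branch of a bifurcation."""

    node: int
    time_index: int
    branch: str                 # "up" | "down" (child mean vs parent mean)
    tf: str
    pvalue: float
    targets_in_branch: int      # k
    branch_size: int            # n
    targets_in_universe: int    # K
    universe_size: int          # N


class RegulatoryMapModel(BaseEstimator):
    """Greedy-BIC tree growth plus EM refinement of temporal paths.

    Parameters
    ----------
    max_children : int
        Maximum branches per split (2 = binary bifurcations).
    min_branch : int
        Smallest admissible branch size; prevents spurious splits.
    min_bic_improvement : float
        A split is accepted only when it lowers BIC by at least this margin;
        guards against noise-driven bifurcations on small branches.
    max_iter, tol
        EM iteration cap and log-likelihood convergence tolerance.
    var_floor : float
        Variance floor (applied with a warning on degenerate nodes).
    random_state : int
        Seeds the mixture proposals.

    Attributes after fit
    --------------------
    nodes_ : list of dicts (id, time, mean, sd, parent);
    paths_ : list of root-to-leaf node-id tuples;
    labels_ : per-gene path index; assignment_ : gene id -> path index;
    splits_ : list of (node id, child ids) with >= 2 children;
    loglik_trace_ : EM log-likelihood per iteration (non-decreasing).
    """

    def __init__(
        self,
        max_children: int = 2,
        min_branch: int = 10,
        max_iter: int = 200,
        tol: float = 1e-8,
        var_floor: float = 1e-4,
        min_bic_improvement: float = 10.0,
        random_state: int = 0,
    ):
        self.max_children = max_children
        self.min_branch = min_branch
        self.min_bic_improvement = min_bic_improvement
        self.max_iter = max_iter
        self.tol = tol
        self.var_floor = var_floor
        self.random_state = random_state

    # -- fitting -------------------------------------------------------------
    def fit(self, X, y=None, gene_ids: list[str] | None = None):
        """Fit on a genes x times fold-change array or DataFrame."""
        if isinstance(X, pd.DataFrame):
            gene_ids = list(X.index)
            values = X.to_numpy(dtype=float)
        else:
            values = np.asarray(X, dtype=float)
            if gene_ids is None:
                gene_ids = [f"g{i}" for i in range(values.shape[0])]
        n, m = values.shape
        if n < self.min_branch:
            raise ValueError("need at least min_branch genes")
        if m < 3:
            raise ValueError("need >= 3 time points")

        nodes, children, node_members = self._grow_tree(values)
        paths = _enumerate_paths(children)
        self._run_em(values, nodes, paths)
        self.nodes_ = nodes
        self.children_ = children
        self.paths_ = paths
        self.splits_ = [
            (nid, tuple(ch)) for nid, ch in children.items() if len(ch) >= 2
        ]
        self.gene_ids_ = list(gene_ids)
        self.assignment_ = {g: int(p) for g, p in zip(gene_ids, self.labels_)}
        return self

    def _grow_tree(self, values: np.ndarray):
        n, m = values.shape
        rng = np.random.RandomState(self.random_state)
        nodes = [{"id": 0, "time": 0, "mean": 0.0, "sd": 0.0, "parent": None}]
        children: dict[int, list[int]] = {0: []}
        leaf_members: dict[int, np.ndarray] = {0: np.arange(n)}
        for t in range(1, m):
            new_members: dict[int, np.ndarray] = {}
            for leaf, members in leaf_members.items():
                v = values[members, t]
                parts = self._propose_split(v, rng)
                for mean, sd, sel in parts:
                    nid = len(nodes)
                    nodes.append(
                        {"id": nid, "time": t, "mean": float(mean),
                         "sd": float(sd), "parent": leaf}
                    )
                    children[leaf].append(nid)
                    children[nid] = []
                    new_members[nid] = members[sel]
            leaf_members = new_members
        return nodes, children, leaf_members

    def _propose_split(self, v: np.ndarray, rng) -> list[tuple[float, float, np.ndarray]]:
        """1-D Gaussian mixture split accepted when BIC improves."""
        nb = len(v)
        single = [(v.mean(), max(v.std(), np.sqrt(self.var_floor)), np.ones(nb, bool))]
        if nb < 2 * self.min_branch or self.max_children < 2:
            return single
        var1 = max(v.var(), self.var_floor)
        ll1 = stats.norm.logpdf(v, v.mean(), np.sqrt(var1)).sum()
        bic1 = -2 * ll1 + 2 * np.log(nb)
        best = single
        best_bic = bic1
        for n_comp in range(2, self.max_children + 1):
            gm = GaussianMixture(
                n_components=n_comp, random_state=rng.randint(2**31 - 1),
                n_init=2, reg_covar=self.var_floor,
            )
            gm.fit(v.reshape(-1, 1))
            labels = gm.predict(v.reshape(-1, 1))
            sizes = np.bincount(labels, minlength=n_comp)
            if sizes.min() < self.min_branch:
                continue
            bic = gm.bic(v.reshape(-1, 1)) + self.min_bic_improvement
            if bic < best_bic:
                best_bic = bic
                order = np.argsort(-gm.means_.ravel())  # children sorted high->low
                best = [
                    (
                        float(gm.means_.ravel()[c]),
                        float(np.sqrt(gm.covariances_.ravel()[c])),
                        labels == c,
                    )
                    for c in order
                ]
        return best

    def _run_em(self, values: np.ndarray, nodes: list[dict], paths: list[tuple[int, ...]]):
        n, m = values.shape
        n_paths = len(paths)
        means = np.array([[nodes[nid]["mean"] for nid in p] for p in paths])  # P x m
        vars_ = np.array(
            [[max(nodes[nid]["sd"] ** 2, self.var_floor) for nid in p] for p in paths]
        )
        weights = np.full(n_paths, 1.0 / n_paths)
        trace: list[float] = []
        resp = np.full((n, n_paths), 1.0 / n_paths)
        floored = False
        for _ in range(self.max_iter):
            # E-step; the root column (fold change identically 0) carries no
            # information and is excluded from the likelihood
            logp = np.zeros((n, n_paths))
            for p in range(n_paths):
                logp[:, p] = stats.norm.logpdf(
                    values[:, 1:], means[p, 1:], np.sqrt(vars_[p, 1:])
                ).sum(axis=1) + np.log(weights[p])
            mx = logp.max(axis=1, keepdims=True)
            lse = mx[:, 0] + np.log(np.exp(logp - mx).sum(axis=1))
            trace.append(float(lse.sum()))
            resp = np.exp(logp - lse[:, None])
            if len(trace) >= 2 and trace[-1] - trace[-2] < self.tol:
                break
            # M-step on shared nodes: aggregate responsibility through each node
            node_w = {nd["id"]: 0.0 for nd in nodes}
            node_s = {nd["id"]: 0.0 for nd in nodes}
            node_ss = {nd["id"]: 0.0 for nd in nodes}
            for p, path in enumerate(paths):
                for t, nid in enumerate(path):
                    if t == 0:
                        continue
                    w = resp[:, p]
                    node_w[nid] += w.sum()
                    node_s[nid] += (w * values[:, t]).sum()
                    node_ss[nid] += (w * values[:, t] ** 2).sum()
            for nd in nodes:
                nid = nd["id"]
                if nd["parent"] is None:
                    nd["mean"], nd["sd"] = 0.0, 0.0  # root anchored at 0
                    continue
                if node_w[nid] <= 0:
                    continue
                mu = node_s[nid] / node_w[nid]
                var = node_ss[nid] / node_w[nid] - mu**2
                if var < self.var_floor:
                    var = self.var_floor
                    floored = True
                nd["mean"], nd["sd"] = float(mu), float(np.sqrt(var))
            weights = resp.sum(axis=0) / n
            weights = np.clip(weights, 1e-12, None)
            weights /= weights.sum()
            means = np.array([[nodes[nid]["mean"] for nid in p] for p in paths])
            vars_ = np.array(
                [[max(nodes[nid]["sd"] ** 2, self.var_floor) for nid in p] for p in paths]
            )
        if floored:
            warnings.warn("degenerate node variance floored")
        self.loglik_trace_ = trace
        self.weights_ = weights
        self.labels_ = resp.argmax(axis=1)
        self.responsibilities_ = resp

    # -- queries -------------------------------------------------------------
    def predict(self, X) -> np.ndarray:
        """Maximum-posterior path index for new fold-change profiles."""
        values = np.asarray(X, dtype=float)
        logp = np.zeros((values.shape[0], len(self.paths_)))
        for p, path in enumerate(self.paths_):
            mu = np.array([self.nodes_[nid]["mean"] for nid in path])
            sd = np.array(
                [max(self.nodes_[nid]["sd"], np.sqrt(self.var_floor)) for nid in path]
            )
            logp[:, p] = stats.norm.logpdf(values[:, 1:], mu[1:], sd[1:]).sum(axis=1)
            logp[:, p] += np.log(self.weights_[p])
        return logp.argmax(axis=1)

    def genes_through(self, node: int) -> set[str]:
        """Genes whose assigned path passes through ``node``."""
        hit = {p for p, path in enumerate(self.paths_) if node in path}
        return {g for g, p in self.assignment_.items() if p in hit}


def _enumerate_paths(children: dict[int, list[int]]) -> list[tuple[int, ...]]:
    paths: list[tuple[int, ...]] = []

    def walk(nid: int, acc: tuple[int, ...]) -> None:
        acc = acc + (nid,)
        if not children.get(nid):
            paths.append(acc)
            return
        for c in children[nid]:
            walk(c, acc)

    walk(0, ())
    return paths


def score_tf_splits(
    model: RegulatoryMapModel,
    edges: pd.DataFrame,
    cutoff: float = 0.005,
) -> list[SplitAnnotation]:
    """Hypergeometric TF-branch association at every bifurcation.

    For each split node and branch: with N genes at the split, K of them
    targets of the TF, and a branch of n genes containing k targets, the
    score is P(X >= k) for X ~ Hypergeom(N, K, n).  Annotations with score
    < ``cutoff`` are retained; TFs with no targets at the split are skipped.
    """
    targets: dict[str, set[str]] = {}
    for _, row in edges.iterrows():
        targets.setdefault(row["tf"], set()).add(row["gene"])
    out: list[SplitAnnotation] = []
    for nid, childs in model.splits_:
        universe = model.genes_through(nid)
        n_univ = len(universe)
        if n_univ == 0:
            continue
        parent_mean = model.nodes_[nid]["mean"]
        for child in childs:
            branch_genes = model.genes_through(child) & universe
            nb = len(branch_genes)
            if nb == 0:
                continue
            label = "up" if model.nodes_[child]["mean"] >= parent_mean else "down"
            for tf, tgts in sorted(targets.items()):
                in_univ = tgts & universe
                big_k = len(in_univ)
                if big_k == 0:
                    continue
                k = len(tgts & branch_genes)
                p = float(stats.hypergeom.sf(k - 1, n_univ, big_k, nb))
                if p < cutoff:
                    out.append(
                        SplitAnnotation(
                            node=nid,
                            time_index=model.nodes_[child]["time"],
                            branch=label,
                            tf=tf,
                            pvalue=p,
                            targets_in_branch=k,
                            branch_size=nb,
                            targets_in_universe=big_k,
                            universe_size=n_univ,
                        )
                    )
    return out


def annotations_to_tsv(annotations: list[SplitAnnotation], path) -> None:
    rows = [asdict(a) for a in annotations]
    cols = [
        "time_index", "node", "branch", "tf", "pvalue",
        "targets_in_branch", "branch_size", "targets_in_universe", "universe_size",
    ]
    pd.DataFrame(rows, columns=cols).to_csv(path, sep="\t", index=False, float_format="%.6g")


def export_map(
    model: RegulatoryMapModel,
    annotations: list[SplitAnnotation],
    json_path,
    dot_path=None,
) -> None:
    """Serialize a fitted map to JSON (and optionally Graphviz DOT).

    The DOT rendering follows the usual regulatory-map style: node label =
    mean fold change to 3 decimals, node size proportional to SD, split edges
    labeled with the retained TFs.
    """
    payload = {
        "nodes": model.nodes_,
        "paths": [list(p) for p in model.paths_],
        "assignment": model.assignment_,
        "weights": list(map(float, model.weights_)),
        "loglik_trace": model.loglik_trace_,
        "annotations": [asdict(a) for a in annotations],
    }
    with open(json_path, "w") as fh:
        json.dump(payload, fh, indent=1)
    if dot_path is None:
        return
    by_child: dict[int, list[str]] = {}
    for a in annotations:
        # attach TF labels to the branch edge leading into the branch's child
        for nid, childs in model.splits_:
            if a.node == nid:
                for c in childs:
                    lbl = "up" if model.nodes_[c]["mean"] >= model.nodes_[nid]["mean"] else "down"
                    if lbl == a.branch:
                        by_child.setdefault(c, []).append(a.tf)
    lines = ["digraph regulatory_map {", "  rankdir=LR;"]
    for nd in model.nodes_:
        size = 0.3 + nd["sd"]
        lines.append(
            f'  n{nd["id"]} [label="{nd["mean"]:.3f}", shape=circle, '
            f"width={size:.3f}, fixedsize=true];"
        )
    for nd in model.nodes_:
        if nd["parent"] is not None:
            tfs = ",".join(dict.fromkeys(by_child.get(nd["id"], [])))
            lbl = f' [label="{tfs}"]' if tfs else ""
            lines.append(f'  n{nd["parent"]} -> n{nd["id"]}{lbl};')
    lines.append("}")
    with open(dot_path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def load_map(json_path) -> dict:
    with open(json_path) as fh:
        return json.load(fh)
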