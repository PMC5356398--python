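"""Seeded synthetic multi-genotype cold-stress time series with planted truth.

The generator emulates the structure of crown-tissue microarray time courses:
l genotypes x m time points x r replicates on a log2 scale, a sparse signed
TF->gene connectivity (~2.5% dense), latent TF activity profiles that rise or
fall transiently after the onset of stress, genotype-conserved and
genotype-divergent temporal patterns, and path bifurcations at chosen time
points.  Every planted structure is recorded in :class:`GroundTruth` so that
each downstream stage can be scored against what was actually simulated.

Model per replicate (log2 scale):

    A_rep = Lambda^T F + planted pattern/path offsets + N(0, noise_sd^2)

where ``Lambda`` (k x n) is the signed TF->gene weight matrix and ``F``
(k x l*m) the per-genotype TF activity profiles.  TF mRNA rows (a noisy proxy
of the activity profile) are appended to the matrix so that expression-based
connectivity initialization has TF profiles to correlate against.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .expression import ExpressionMatrix
from .netinfer import PriorNetwork
from .tricluster import discretize_series

SYMBOLS = ("U", "D", "N")

#: log2 step planted per U/D interval symbol.  A 4-fold swing per interval is
#: typical of strongly cold-responsive transcripts and keeps planted patterns
#: well clear of the default 0.5 no-change band after replicate averaging.
PATTERN_STEP = 2.0


class ConfigError(ValueError):
    """Invalid generator configuration."""


@dataclass(frozen=True)
class GenConfig:
    """Study conditions for one simulated dataset.

    Defaults mirror a 4-cultivar, 8-time-point, 3-replicate cold-acclimation
    design with ~2.5% dense signed TF-gene connectivity.
    """

    n_genes: int = 300
    n_tfs: int = 12
    genotypes: tuple[str, ...] = ("wM", "wN", "sM", "sN")
    time_points: tuple[float, ...] = (0, 2, 14, 21, 35, 42, 56, 70)
    replicates: int = 3
    edge_density: float = 0.025
    prior_coverage: float = 0.6
    prior_noise: float = 0.1
    noise_sd: float = 0.25
    n_conserved: int = 2
    n_divergent: int = 2
    set_size: int = 10
    n_path_genes: int = 40
    split_spec: tuple[tuple[int, float], ...] = ((2, 2.0),)
    conserved_subsets: tuple[tuple[str, ...], ...] | None = None
    include_tf_rows: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_tfs >= self.n_genes:
            raise ConfigError("n_tfs must be smaller than n_genes")
        if list(self.time_points) != sorted(set(self.time_points)):
            raise ConfigError("time_points must be strictly increasing")
        for name in ("edge_density", "prior_coverage", "prior_noise"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name}={v} outside [0, 1]")
        if self.edge_density == 0.0:
            raise ConfigError("edge_density must be in (0, 1]")
        if self.noise_sd < 0:
            raise ConfigError("noise_sd must be non-negative")
        if self.replicates < 1:
            raise ConfigError("replicates must be >= 1")
        planted = (self.n_conserved + self.n_divergent) * self.set_size + self.n_path_genes
        if planted > self.n_genes:
            raise ConfigError("planted gene sets exceed n_genes")
        for t_idx, _ in self.split_spec:
            if not 1 <= t_idx < len(self.time_points):
                raise ConfigError(f"split time index {t_idx} out of range")

    @property
    def n_times(self) -> int:
        return len(self.time_points)

    @property
    def n_samples(self) -> int:
        return len(self.genotypes) * self.n_times


@dataclass(frozen=True)
class PlantedSet:
    """One planted conserved or divergent gene set."""

    name: str
    genes: tuple[str, ...]
    genotypes: tuple[str, ...]            # subset carrying ``pattern``
    pattern: str                          # U/D/N string over m-1 intervals
    kind: str                             # conserved | sign_flip | delay
    other_pattern: str | None = None      # complement genotypes' pattern
    shift: int = 0                        # delay (time steps) for kind="delay"


@dataclass
class GroundTruth:
    """Everything the simulator planted, for scoring downstream stages."""

    config: GenConfig
    gene_ids: list[str]
    tf_ids: list[str]
    true_lambda: np.ndarray               # k x n signed weights
    true_f: np.ndarray                    # k x (l*m) activities
    offsets: np.ndarray                   # n x (l*m) planted pattern offsets
    conserved_sets: list[PlantedSet]
    divergent_sets: list[PlantedSet]
    path_membership: dict[str, str]       # gene -> planted path id
    term_map: dict[str, set[str]]

    @property
    def noiseless(self) -> np.ndarray:
        """Gene-row block of the noise-free expression matrix."""
        return self.true_lambda.T @ self.true_f + self.offsets

    def sample_keys(self) -> list[str]:
        cfg = self.config
        return [f"{g}:{t:g}" for g in cfg.genotypes for t in cfg.time_points]


# ---------------------------------------------------------------------------
# activity profile library


def _tfa_profile(rng: np.random.Generator, m: int) -> tuple[str, dict]:
    # transient pulses dominate: cold-response TF activity is mostly
    # transient, and localized pulses keep planted programs distinguishable
    family = rng.choice(["step", "pulse", "ramp"], p=[0.2, 0.6, 0.2])
    params = {
        "onset": int(rng.integers(1, max(2, m - 1))),
        "width": float(rng.uniform(0.5, 1.2)),
        "amplitude": float(rng.uniform(1.0, 3.0) * rng.choice([-1.0, 1.0])),
    }
    return str(family), params


def _eval_profile(family: str, params: dict, m: int, jitter: dict) -> np.ndarray:
    idx = np.arange(m, dtype=float)
    a = params["amplitude"] * jitter["amp"]
    onset = params["onset"] + jitter["onset"]
    if family == "step":
        prof = np.where(idx >= onset, a, 0.0)
    elif family == "pulse":
        prof = a * np.exp(-0.5 * ((idx - onset) / params["width"]) ** 2)
    else:  # ramp
        prof = a * np.clip((idx - onset) / max(1.0, m - 1 - onset), 0.0, 1.0)
    return prof


# ---------------------------------------------------------------------------
# planted patterns


def _pattern_offsets(pattern: str, shift: int = 0) -> np.ndarray:
    """Cumulative log2 offset profile realizing a U/D/N interval pattern."""
    steps = {"U": PATTERN_STEP, "D": -PATTERN_STEP, "N": 0.0}
    diffs = np.array([steps[s] for s in pattern])
    prof = np.concatenate([[0.0], np.cumsum(diffs)])
    if shift:
        prof = np.concatenate([np.zeros(shift), prof[:-shift]])
    return prof


def _shifted_pattern(pattern: str, shift: int) -> str:
    return "N" * shift + pattern[: len(pattern) - shift]


def _draw_pattern(rng: np.random.Generator, length: int, forbidden: set[str]) -> str:
    """Random dynamic (U/D-only) pattern avoiding collisions with ``forbidden``."""
    for _ in range(1000):
        pat = "".join(rng.choice(["U", "D"], size=length))
        if pat not in forbidden:
            return pat
    raise RuntimeError("could not draw a collision-free planted pattern")


# ---------------------------------------------------------------------------
# generator


def generate_truth(config: GenConfig) -> GroundTruth:
    """Draw the planted regulatory structure for one simulated study.

    Fully determined by ``config`` (including its seed): same config twice
    gives identical output.
    """
    rng = np.random.default_rng(config.seed)
    cfg = config
    n, k, m, l = cfg.n_genes, cfg.n_tfs, cfg.n_times, len(cfg.genotypes)
    gene_ids = [f"G{i + 1:04d}" for i in range(n)]
    tf_ids = [f"TF{i + 1:02d}" for i in range(k)]

    # -- planted gene allocation (planted genes carry no TF edges) ----------
    n_planted = (cfg.n_conserved + cfg.n_divergent) * cfg.set_size + cfg.n_path_genes
    planted_idx = rng.choice(n, size=n_planted, replace=False)
    background_idx = np.setdiff1d(np.arange(n), planted_idx)

    # -- connectivity --------------------------------------------------------
    n_edges = int(round(cfg.edge_density * k * n))
    true_lambda = np.zeros((k, n))
    flat_bg = np.array(
        [tf * n + g for tf in range(k) for g in background_idx], dtype=int
    )
    if n_edges > len(flat_bg):
        raise ConfigError("edge_density too high for the non-planted gene pool")
    chosen = rng.choice(flat_bg, size=n_edges, replace=False)
    signs = np.ones(n_edges)
    signs[: n_edges // 2] = -1.0
    rng.shuffle(signs)
    weights = signs * rng.uniform(0.5, 1.5, size=n_edges)
    true_lambda.flat[chosen] = weights

    # -- TF activities: smooth transient profiles, jittered per genotype ----
    # distinct regulatory programs: base profiles are redrawn until their
    # pairwise correlation stays moderate, so planted TFs are identifiable
    true_f = np.zeros((k, l * m))
    base_profiles: list[np.ndarray] = []
    neutral = {"amp": 1.0, "onset": 0.0}
    for i in range(k):
        best: tuple[float, str, dict] | None = None
        for _ in range(300):
            family, params = _tfa_profile(rng, m)
            cand = _eval_profile(family, params, m, neutral)
            cc = cand - cand.mean()
            norm = np.linalg.norm(cc)
            if norm == 0:
                continue
            worst = max(
                (
                    abs(np.dot(cc, bp) / (norm * np.linalg.norm(bp)))
                    for bp in base_profiles
                ),
                default=0.0,
            )
            if best is None or worst < best[0]:
                best = (worst, family, params)
            if worst <= 0.7:
                break
        assert best is not None
        _, family, params = best
        base = _eval_profile(family, params, m, neutral)
        base_profiles.append(base - base.mean())
        for j in range(l):
            jitter = {
                "amp": float(rng.uniform(0.8, 1.2)),
                "onset": float(rng.uniform(-0.5, 0.5)),
            }
            true_f[i, j * m : (j + 1) * m] = _eval_profile(family, params, m, jitter)

    # -- background patterns, for collision-free planted pattern draws ------
    base = true_lambda.T @ true_f
    forbidden: set[str] = set()
    for g in background_idx:
        for j in range(l):
            forbidden.add(discretize_series(base[g, j * m : (j + 1) * m], 0.5))

    offsets = np.zeros((n, l * m))
    conserved_sets: list[PlantedSet] = []
    divergent_sets: list[PlantedSet] = []
    cursor = 0
    geno_index = {g: j for j, g in enumerate(cfg.genotypes)}

    def take(count: int) -> np.ndarray:
        nonlocal cursor
        sel = planted_idx[cursor : cursor + count]
        cursor += count
        return sel

    for s in range(cfg.n_conserved):
        subset = (
            cfg.conserved_subsets[s % len(cfg.conserved_subsets)]
            if cfg.conserved_subsets
            else cfg.genotypes
        )
        pat = _draw_pattern(rng, m - 1, forbidden)
        forbidden.add(pat)
        idx = take(cfg.set_size)
        prof = _pattern_offsets(pat)
        for g in subset:
            j = geno_index[g]
            offsets[np.ix_(idx, range(j * m, (j + 1) * m))] = prof
        conserved_sets.append(
            PlantedSet(
                name=f"conserved_{s}",
                genes=tuple(gene_ids[i] for i in sorted(idx)),
                genotypes=tuple(subset),
                pattern=pat,
                kind="conserved",
            )
        )

    for s in range(cfg.n_divergent):
        kind = "sign_flip" if s % 2 == 0 else "delay"
        size = int(rng.integers(1, max(2, l // 2 + 1)))
        subset = tuple(
            cfg.genotypes[j] for j in sorted(rng.choice(l, size=size, replace=False))
        )
        complement = tuple(g for g in cfg.genotypes if g not in subset)
        pat = _draw_pattern(rng, m - 1, forbidden)
        forbidden.add(pat)
        idx = take(cfg.set_size)
        if kind == "sign_flip":
            other = pat.translate(str.maketrans("UD", "DU"))
            shift = 0
            sub_prof, comp_prof = _pattern_offsets(pat), _pattern_offsets(other)
        else:
            shift = 1
            other = pat
            # the subset is delayed relative to the complement
            sub_prof = _pattern_offsets(pat, shift=shift)
            comp_prof = _pattern_offsets(pat)
            pat = _shifted_pattern(other, shift)
        forbidden.update({pat, other})
        for g in cfg.genotypes:
            j = geno_index[g]
            prof = sub_prof if g in subset else comp_prof
            offsets[np.ix_(idx, range(j * m, (j + 1) * m))] = prof
        divergent_sets.append(
            PlantedSet(
                name=f"divergent_{s}",
                genes=tuple(gene_ids[i] for i in sorted(idx)),
                genotypes=subset,
                pattern=pat,
                kind=kind,
                other_pattern=other,
                shift=shift,
            )
        )

    # -- bifurcation paths: identical in every genotype ----------------------
    path_membership: dict[str, str] = {}
    if cfg.n_path_genes and cfg.split_spec:
        per_split = cfg.n_path_genes // len(cfg.split_spec)
        for t_idx, effect in cfg.split_spec:
            idx = take(per_split)
            half = per_split // 2
            for branch, rows in (("up", idx[:half]), ("down", idx[half:])):
                sign = 1.0 if branch == "up" else -1.0
                prof = np.zeros(m)
                prof[t_idx:] = sign * effect
                for j in range(l):
                    offsets[np.ix_(rows, range(j * m, (j + 1) * m))] += prof
                for i in rows:
                    path_membership[gene_ids[i]] = f"split{t_idx}_{branch}"

    # -- annotation terms: ~70% of each planted set annotated ----------------
    term_map: dict[str, set[str]] = {}
    all_sets = conserved_sets + divergent_sets
    for ps in all_sets:
        n_annot = int(np.ceil(0.7 * len(ps.genes)))
        term_map[f"T:{ps.name}"] = set(ps.genes[:n_annot])
    cold = set()
    for ps in conserved_sets:
        cold |= term_map[f"T:{ps.name}"]
    if cold:
        term_map["T:cold_response"] = cold
    for b in range(3):
        pool = rng.choice(background_idx, size=min(15, len(background_idx)), replace=False)
        term_map[f"T:background_{b}"] = {gene_ids[i] for i in pool}

    return GroundTruth(
        config=cfg,
        gene_ids=gene_ids,
        tf_ids=tf_ids,
        true_lambda=true_lambda,
        true_f=true_f,
        offsets=offsets,
        conserved_sets=conserved_sets,
        divergent_sets=divergent_sets,
        path_membership=path_membership,
        term_map=term_map,
    )


def generate_expression(truth: GroundTruth, config: GenConfig | None = None) -> ExpressionMatrix:
    """Simulate the replicated log2 expression matrix for a drawn truth.

    Gene rows follow ``Lambda^T F + offsets + N(0, noise_sd^2)`` per replicate;
    TF mRNA rows (activity proxy, same noise) are appended when
    ``config.include_tf_rows`` is set.
    """
    cfg = config or truth.config
    rng = np.random.default_rng([cfg.seed, 7919])
    clean = truth.noiseless
    rows = list(truth.gene_ids)
    blocks = [clean]
    if cfg.include_tf_rows:
        rows += list(truth.tf_ids)
        blocks.append(truth.true_f)
    clean_all = np.vstack(blocks)

    cols, data = [], []
    keys = truth.sample_keys()
    for rep in range(1, cfg.replicates + 1):
        noise = rng.normal(0.0, cfg.noise_sd, size=clean_all.shape) if cfg.noise_sd else 0.0
        data.append(clean_all + noise)
        cols.extend(f"{key}:{rep}" for key in keys)
    # interleave so columns group by replicate within (genotype, time)
    stacked = np.concatenate(data, axis=1)
    values = pd.DataFrame(stacked, index=rows, columns=cols)
    order = [f"{key}:{rep}" for key in keys for rep in range(1, cfg.replicates + 1)]
    return ExpressionMatrix(values[order])


def generate_prior(truth: GroundTruth, config: GenConfig | None = None) -> PriorNetwork:
    """Expose a noisy, partial view of the true connectivity as the prior.

    ``round(prior_coverage * E)`` true edges keep their correct sign;
    ``round(prior_noise * E)`` spurious edges with random signs are added at
    zero positions of the truth.
    """
    cfg = config or truth.config
    rng = np.random.default_rng([cfg.seed, 104729])
    k, n = truth.true_lambda.shape
    matrix = np.zeros((k, n), dtype=np.int8)
    true_pos = np.flatnonzero(truth.true_lambda)
    n_true = len(true_pos)
    n_expose = int(round(cfg.prior_coverage * n_true))
    if n_expose:
        keep = rng.choice(true_pos, size=n_expose, replace=False)
        matrix.flat[keep] = np.sign(truth.true_lambda.flat[keep]).astype(np.int8)
    n_spurious = int(round(cfg.prior_noise * n_true))
    if n_spurious:
        zero_pos = np.flatnonzero(truth.true_lambda == 0)
        fake = rng.choice(zero_pos, size=n_spurious, replace=False)
        matrix.flat[fake] = rng.choice([-1, 1], size=n_spurious).astype(np.int8)
    return PriorNetwork(tfs=list(truth.tf_ids), genes=list(truth.gene_ids), matrix=matrix)


# ---------------------------------------------------------------------------
# fixture I/O


def write_fixture(
    truth: GroundTruth,
    expression: ExpressionMatrix,
    prior: PriorNetwork,
    out_dir,
) -> dict[str, Path]:
    """Write expression TSV, prior TSV, GMT term map and a JSON truth manifest."""
    out = Path(out_dir)
    try:
        out.mkdir(parents=True, exist_ok=True)
        paths = {
            "expression": out / "expression.tsv",
            "prior": out / "prior.tsv",
            "terms": out / "terms.gmt",
            "manifest": out / "truth.json",
        }
        expression.to_tsv(paths["expression"])
        prior.to_tsv(paths["prior"])
        write_gmt(truth.term_map, paths["terms"])
        manifest = {
            "seed": truth.config.seed,
            "config": {
                f: getattr(truth.config, f)
                for f in truth.config.__dataclass_fields__
            },
            "true_edges": [
                {
                    "tf": truth.tf_ids[i],
                    "gene": truth.gene_ids[j],
                    "weight": float(truth.true_lambda[i, j]),
                }
                for i, j in zip(*np.nonzero(truth.true_lambda))
            ],
            "conserved_sets": [vars(s) for s in truth.conserved_sets],
            "divergent_sets": [vars(s) for s in truth.divergent_sets],
            "path_membership": truth.path_membership,
        }
        paths["manifest"].write_text(json.dumps(manifest, indent=1, default=list))
    except OSError as exc:
        raise OSError(f"writing fixture under {out}: {exc}") from exc
    return paths


def write_gmt(term_map: dict[str, set[str]], path) -> None:
    with open(path, "w") as fh:
        for term in sorted(term_map):
            genes = "\t".join(sorted(term_map[term]))
            fh.write(f"{term}\t{term}\t{genes}\n")


def read_gmt(path) -> dict[str, set[str]]:
    term_map: dict[str, set[str]] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                warnings.warn(f"skipping short GMT line in {path}")
                continue
            term_map[parts[0]] = set(parts[2:])
    return term_map
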