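"""End-to-end orchestration: simulate -> preprocess -> infer -> {tricluster,
map} -> analyze, driven by one YAML config with a single global seed.

Every stage writes plain-text outputs into the run directory and the manifest
records parameters, per-stage timing and SHA-256 checksums, so a rerun with
the same config and seed reproduces deterministic outputs byte for byte.
"""

from __future__ import annotations

import copy
import hashlib
import json
import logging
import time
from pathlib import Path

import numpy as np
import yaml

from . import bifurcation, netinfer, postanalysis, simulate, tricluster
from .expression import (
    ExpressionMatrix,
    anova_gxt,
    average_replicates,
    combine_genotypes,
    fold_change_filter,
    read_expression,
)

log = logging.getLogger("coldnet")

DEFAULT_CONFIG: dict = {
    "seed": 0,
    "stages": {
        "simulate": True,
        "preprocess": True,
        "infer": True,
        "tricluster": True,
        "map": True,
        "analyze": True,
    },
    "io": {"expression": None, "prior": None, "terms": None},
    "simulate": {},  # GenConfig overrides
    "preprocess": {"min_log2_range": 1.0, "scope": "any"},
    "infer": {
        "ridge": 1e-6,
        "epsilon": 1e-6,
        "max_iter": 500,
        "enet_alpha": 0.5,
        "enet_lambda": 0.01,
        "p0": 1e-3,
        "pvalue_method": "permutation",
        "n_permutations": 1999,
        "expr_init_threshold": 0.8,
    },
    "tricluster": {
        "delta": 0.5,
        "min_genes": 5,
        "pvalue_cutoff": 1e-4,
        "symbol_null": "uniform",
        "max_shift": 1,
    },
    "map": {
        "genotypes": None,  # None: first genotype only
        "max_children": 2,
        "min_branch": 10,
        "split_cutoff": 0.005,
    },
    "analyze": {
        "cold_terms": ["T:cold_response"],
        "transfer_p": 0.05,
        "w1": 1.0,
        "w2": 1.0,
        "anova_p": 1e-3,
    },
}


class ConfigError(ValueError):
    """Invalid pipeline configuration."""


class StageError(RuntimeError):
    """A pipeline stage failed; ``stage`` names it."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def _merge(base: dict, override: dict, path: str, strict: bool, errors: list[str]) -> dict:
    out = copy.deepcopy(base)
    for key, val in override.items():
        here = f"{path}.{key}" if path else key
        if key not in base:
            if strict and path != "simulate":
                errors.append(f"unknown key {here!r}")
                continue
            out[key] = val
        elif isinstance(base[key], dict) and isinstance(val, dict):
            out[key] = _merge(base[key], val, here, strict, errors)
        else:
            out[key] = val
    return out


def validate_config(source, strict: bool = True) -> dict:
    """Normalize a YAML path / dict into a full config, or raise ConfigError.

    Defaults are filled (p0=1e-3, split cutoff 0.005, 2-fold filter, ...),
    constraints checked, and all error messages collected into one report.
    """
    if isinstance(source, (str, Path)):
        with open(source) as fh:
            raw = yaml.safe_load(fh) or {}
    else:
        raw = copy.deepcopy(source) if source else {}
    if not isinstance(raw, dict):
        raise ConfigError("config must be a mapping")
    errors: list[str] = []
    cfg = _merge(DEFAULT_CONFIG, raw, "", strict, errors)

    inf = cfg["infer"]
    if not 0 < inf["p0"] < 1:
        errors.append(f"infer.p0={inf['p0']} must be in (0, 1)")
    if not inf["epsilon"] > 0:
        errors.append("infer.epsilon must be > 0")
    if not 0 <= inf["enet_alpha"] <= 1:
        errors.append("infer.enet_alpha must be in [0, 1]")
    if cfg["preprocess"]["min_log2_range"] < 0:
        errors.append("preprocess.min_log2_range must be >= 0")
    if cfg["tricluster"]["delta"] < 0:
        errors.append("tricluster.delta must be >= 0")
    if not 0 < cfg["map"]["split_cutoff"] <= 1:
        errors.append("map.split_cutoff must be in (0, 1]")
    if not cfg["stages"]["simulate"]:
        for item in ("expression", "prior"):
            path = cfg["io"][item]
            if path is None:
                errors.append(f"io.{item} required when the simulate stage is disabled")
            elif not Path(path).exists():
                errors.append(f"io.{item}={path} does not exist")
    if cfg["stages"]["simulate"]:
        try:
            simulate.GenConfig(**{**cfg["simulate"], "seed": cfg["seed"]})
        except (TypeError, simulate.ConfigError) as exc:
            errors.append(f"simulate: {exc}")
    if errors:
        raise ConfigError("invalid config:\n  " + "\n  ".join(errors))
    return cfg


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: dict | str | Path, out_dir) -> dict:
    """Execute the enabled stages, returning the manifest dict.

    Stage failures raise :class:`StageError` naming the stage; outputs of
    completed stages are retained in ``out_dir``.
    """
    cfg = validate_config(config)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = int(cfg["seed"])
    manifest: dict = {"seed": seed, "config": cfg, "stages": {}, "checksums": {}}
    outputs: list[Path] = []
    state: dict = {}

    def stage(name):
        enabled = cfg["stages"].get(name, False)

        def deco(fn):
            if not enabled:
                log.info("stage %s disabled", name)
                return
            t0 = time.perf_counter()
            log.info("stage %s: start (params=%s)", name, cfg.get(name, {}))
            try:
                fn()
            except Exception as exc:  # halt with stage context, keep outputs
                raise StageError(name, exc) from exc
            manifest["stages"][name] = {
                "seconds": round(time.perf_counter() - t0, 3),
                "params": cfg.get(name, {}),
            }
            log.info("stage %s: done", name)

        return deco

    @stage("simulate")
    def _simulate():
        gen = simulate.GenConfig(**{**cfg["simulate"], "seed": seed})
        truth = simulate.generate_truth(gen)
        expr = simulate.generate_expression(truth)
        prior = simulate.generate_prior(truth)
        paths = simulate.write_fixture(truth, expr, prior, out / "data")
        outputs.extend(paths.values())
        state["truth"] = truth
        cfg["io"] = {
            "expression": str(paths["expression"]),
            "prior": str(paths["prior"]),
            "terms": str(paths["terms"]),
        }

    @stage("preprocess")
    def _preprocess():
        raw = read_expression(cfg["io"]["expression"])
        avg = average_replicates(raw)
        filt, dropped = fold_change_filter(
            avg,
            cfg["preprocess"]["min_log2_range"],
            cfg["preprocess"]["scope"],
        )
        combined = combine_genotypes(filt)
        combined.to_tsv(out / "a_matrix.tsv")
        (out / "dropped_genes.txt").write_text("\n".join(dropped) + ("\n" if dropped else ""))
        outputs.extend([out / "a_matrix.tsv", out / "dropped_genes.txt"])
        if raw.has_replicates:
            rep = ExpressionMatrix(raw.values.loc[combined.genes], raw.samples.copy())
            anova = anova_gxt(rep)
            anova.to_csv(out / "anova.tsv", sep="\t", float_format="%.6g")
            outputs.append(out / "anova.tsv")
            state["anova"] = anova
        state["combined"] = combined

    @stage("infer")
    def _infer():
        prior = netinfer.PriorNetwork.read_tsv(cfg["io"]["prior"])
        model = netinfer.NetworkALS(seed=seed, **cfg["infer"])
        model.fit(state["combined"], prior=prior)
        model.result_.to_tsv(out / "edges.tsv")
        model.result_.to_sif(out / "network.sif")
        (out / "fit.json").write_text(
            json.dumps(
                {
                    "seed": seed,
                    "n_iter": model.n_iter_,
                    "converged": bool(model.converged_),
                    "objective_trace": model.objective_trace_,
                },
                indent=1,
            )
        )
        outputs.extend([out / "edges.tsv", out / "network.sif", out / "fit.json"])
        state["network"] = model

    @stage("tricluster")
    def _tricluster():
        model = tricluster.OrderPreservingTricluster(**cfg["tricluster"])
        model.fit(state["combined"])
        tricluster.clusters_to_tsv(
            model.conserved_ + model.divergent_, out / "clusters.tsv"
        )
        model.summary_.to_csv(out / "summary.tsv", sep="\t", index=False, float_format="%.6g")
        outputs.extend([out / "clusters.tsv", out / "summary.tsv"])
        state["tricluster"] = model

    @stage("map")
    def _map():
        combined = state["combined"]
        genos = cfg["map"]["genotypes"] or combined.genotypes[:1]
        edges = state["network"].edges() if "network" in state else None
        for geno in genos:
            fc = bifurcation.to_fold_change(combined, geno)
            model = bifurcation.RegulatoryMapModel(
                max_children=cfg["map"]["max_children"],
                min_branch=cfg["map"]["min_branch"],
                random_state=seed,
            )
            model.fit(fc)
            ann = (
                bifurcation.score_tf_splits(model, edges, cfg["map"]["split_cutoff"])
                if edges is not None
                else []
            )
            jpath = out / f"map_{geno}.json"
            dpath = out / f"map_{geno}.dot"
            bifurcation.export_map(model, ann, jpath, dpath)
            apath = out / f"map_{geno}_tfs.tsv"
            bifurcation.annotations_to_tsv(ann, apath)
            outputs.extend([jpath, dpath, apath])

    @stage("analyze")
    def _analyze():
        combined = state["combined"]
        universe = combined.genes
        terms = (
            simulate.read_gmt(cfg["io"]["terms"]) if cfg["io"].get("terms") else {}
        )
        stats_out: dict = {}
        if "network" in state:
            model = state["network"]
            lam = model.connectivity_
            stats_out["edge_density_percent"] = 100.0 * float(
                (lam != 0).mean()
            )
            edges = model.edges()
            if len(edges):
                _, mean_cc = postanalysis.clustering_coefficient(edges)
                stats_out["mean_clustering_coefficient"] = mean_cc
                try:
                    slope, r2 = postanalysis.degree_distribution_fit(edges)
                    stats_out["degree_fit_slope"] = slope
                    stats_out["degree_fit_r2"] = r2
                except ValueError as exc:
                    stats_out["degree_fit"] = str(exc)
        (out / "network_stats.json").write_text(json.dumps(stats_out, indent=1))
        outputs.append(out / "network_stats.json")
        if "tricluster" in state and terms:
            tri = state["tricluster"]
            clusters = {
                f"conserved_{i}": set(c.genes) & set(universe)
                for i, c in enumerate(tri.conserved_)
            }
            transfers = postanalysis.transfer_annotations(
                clusters, terms, universe, cfg["analyze"]["transfer_p"]
            )
            transfers.to_csv(out / "transfers.tsv", sep="\t", index=False, float_format="%.6g")
            markers = postanalysis.rank_candidate_markers(
                tri.divergent_, terms, universe,
                cfg["analyze"]["cold_terms"],
                w1=cfg["analyze"]["w1"], w2=cfg["analyze"]["w2"],
            )
            markers.to_csv(out / "markers.tsv", sep="\t", index=False, float_format="%.6g")
            outputs.extend([out / "transfers.tsv", out / "markers.tsv"])
        if "anova" in state and "network" in state:
            anova = state["anova"]
            sig = set(anova.index[anova["p_interaction"] < cfg["analyze"]["anova_p"]])
            targets = set(state["network"].edges()["gene"])
            comparison = postanalysis.compare_gene_lists(
                sig & set(universe), targets & set(universe), universe
            )
            (out / "comparison.json").write_text(json.dumps(comparison, indent=1))
            outputs.append(out / "comparison.json")

    for path in outputs:
        manifest["checksums"][str(path.relative_to(out))] = _sha256(path)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, default=str))
    return manifest
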