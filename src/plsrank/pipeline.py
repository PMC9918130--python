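"""End-to-end orchestration of the candidate-gene prioritization run.

One config drives the whole analysis: simulate (or read) a three-group
FPKM matrix, preprocess and ordinate the samples, call DEGs for the
three pairwise contrasts, rank genes by PLS-DA Axis-1 correlation for
the two control contrasts, classify DEG trajectories across the
timeline, screen coexpression partners of the key candidate genes, and
run an over-representation test.  Every stage's output is written as
TSV next to a JSON manifest recording versions, seed and config hash,
so a rerun with the same config and seed is bit-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .coexpression import coexpressed_partners, propagate_terms
from .de import call_degs
from .enrichment import overrepresentation
from .io import (
    ConfigurationError,
    ExpressionMatrix,
    GeneSetCollection,
    read_expression,
    write_expression,
)
from .plsda import axis1_correlations, bin_abs_correlations, fit_plsda, make_dummy, select_candidates
from .preprocess import pcoa, preprocess
from .simulate import SyntheticConfig, annotation_from_truth, generate_experiment, write_truth
from .trajectory import classify_trajectory

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Run configuration; either simulate or read the expression input."""

    out_dir: str = "plsrank_run"
    seed: int = 0
    # input: paths take precedence over simulation when both are given
    matrix_path: str | None = None
    design_path: str | None = None
    annotation_path: str | None = None
    gmt_path: str | None = None
    simulation: SyntheticConfig | None = None
    # analysis parameters
    contrasts: tuple[tuple[str, str], ...] = (("C", "A20"), ("C", "AD"))
    alpha: float = 0.05
    pseudocount: float = 1.0
    n_axes: int = 2
    r_threshold: float = 0.90
    coexpr_alpha: float = 0.001
    coexpr_groups: tuple[str, str] = ("C", "AD")
    key_genes: tuple[str, ...] | None = None
    top_k: int = 10

    def validate(self) -> None:
        if not 0 < self.alpha < 1:
            raise ConfigurationError("alpha must be in (0, 1)")
        if not 0 < self.coexpr_alpha < 1:
            raise ConfigurationError("coexpr_alpha must be in (0, 1)")
        if not 0 < self.r_threshold <= 1:
            raise ConfigurationError("r_threshold must be in (0, 1]")
        if self.matrix_path is None and self.simulation is None:
            raise ConfigurationError("either input paths or a simulation config required")
        for pair in self.contrasts:
            if len(pair) != 2 or pair[0] == pair[1]:
                raise ConfigurationError(f"bad contrast {pair!r}")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        sim = raw.pop("simulation", None)
        cfg = cls(**{k: _tuplify(v) for k, v in raw.items()})
        if sim is not None:
            cfg.simulation = SyntheticConfig(**{k: _tuplify(v) for k, v in sim.items()})
        return cfg


def _tuplify(v):
    if isinstance(v, list):
        return tuple(_tuplify(x) for x in v)
    return v


def _config_hash(config: PipelineConfig) -> str:
    blob = json.dumps(asdict(config), sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def _contrast_name(pair: tuple[str, str]) -> str:
    return f"{pair[0]}_{pair[1]}"


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage; returns a report dict of output paths and frames."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {"outputs": {}, "timings": {}}

    def _stage(name):
        class _Timer:
            def __enter__(self):
                self.t0 = time.perf_counter()
                logger.info("stage %s ...", name)
                return self

            def __exit__(self, exc_type, exc, tb):
                dt = time.perf_counter() - self.t0
                report["timings"][name] = round(dt, 4)
                if exc is not None:
                    logger.error("stage %s failed: %s", name, exc)
                    raise ConfigurationError(f"stage {name} failed: {exc}") from exc
                logger.info("stage %s done in %.2fs", name, dt)
                return False

        return _Timer()

    def _write(name, df, **kw):
        path = out / name
        df.to_csv(path, sep="\t", **kw)
        report["outputs"][name] = str(path)

    annotation = None
    gene_sets = None

    with _stage("input"):
        if config.matrix_path is not None:
            matrix = read_expression(config.matrix_path, config.design_path)
            truth = None
        else:
            sim = config.simulation
            if sim.seed != config.seed:
                sim = SyntheticConfig(**{**asdict(sim), "seed": config.seed})
            matrix, truth = generate_experiment(sim)
            write_expression(matrix, out / "matrix.tsv", out / "design.tsv")
            report["outputs"]["matrix.tsv"] = str(out / "matrix.tsv")
            report["outputs"]["design.tsv"] = str(out / "design.tsv")
            write_truth(truth, out / "truth.tsv")
            report["outputs"]["truth.tsv"] = str(out / "truth.tsv")
            annotation = annotation_from_truth(truth)
        if config.annotation_path is not None:
            from .io import read_annotation

            annotation = read_annotation(config.annotation_path)
        if config.gmt_path is not None:
            from .io import load_gene_sets

            gene_sets = load_gene_sets(config.gmt_path)

    with _stage("preprocess"):
        processed = preprocess(matrix, pseudocount=config.pseudocount)

    with _stage("ordination"):
        ordination = pcoa(processed, n_axes=config.n_axes)
        coords = ordination.coordinates.copy()
        _write("coords.tsv", coords)

    deg_tables = {}
    with _stage("differential_expression"):
        groups = matrix.groups
        all_pairs = {tuple(c) for c in config.contrasts}
        # trajectory classification needs all three pairwise contrasts
        if len(groups) == 3:
            g1, g2, g3 = groups
            all_pairs |= {(g1, g2), (g1, g3), (g2, g3)}
        for pair in sorted(all_pairs):
            name = _contrast_name(pair)
            deg = call_degs(matrix, pair, alpha=config.alpha, pseudocount=config.pseudocount)
            deg_tables[name] = deg
            _write(f"deg_{name}.tsv", deg.table)

    rankings = {}
    with _stage("plsda_ranking"):
        for pair in config.contrasts:
            name = _contrast_name(tuple(pair))
            dummy = make_dummy(matrix.design, tuple(pair))
            model = fit_plsda(processed, dummy, n_axes=config.n_axes)
            ranking = axis1_correlations(processed, model, r_threshold=config.r_threshold)
            rankings[name] = ranking
            _write(f"scores_{name}.tsv", model.scores)
            _write(f"ranking_{name}.tsv", ranking.table)
            degs = deg_tables[name].significant_genes
            bins = bin_abs_correlations(ranking, annotation=annotation, genes=degs)
            _write(f"bins_{name}.tsv", bins)
            cand = select_candidates(ranking, annotation=annotation, genes=degs)
            cand = cand.copy()
            if "behavior_terms" in cand.columns:
                cand["behavior_terms"] = [
                    "|".join(sorted(t)) for t in cand["behavior_terms"]
                ]
            _write(f"candidates_{name}.tsv", cand)

    with _stage("trajectory"):
        if len(matrix.groups) == 3:
            g1, g2, g3 = matrix.groups
            calls = classify_trajectory(
                deg_tables[_contrast_name((g1, g2))],
                deg_tables[_contrast_name((g1, g3))],
                deg_tables[_contrast_name((g2, g3))],
            )
            _write("trajectory.tsv", calls)
            report["trajectory"] = calls
        else:
            logger.info("trajectory skipped: need exactly three groups")

    with _stage("coexpression"):
        cname = _contrast_name(tuple(config.coexpr_groups))
        if cname in deg_tables:
            deg_genes = deg_tables[cname].significant_genes
            key_genes = list(config.key_genes) if config.key_genes else []
            if not key_genes and cname in rankings and annotation is not None:
                cand = select_candidates(
                    rankings[cname],
                    annotation=annotation,
                    genes=deg_genes,
                    require_neurogenesis=True,
                    require_terms=True,
                )
                key_genes = list(cand.index[:3])
            results = []
            for key in key_genes:
                res = coexpressed_partners(
                    key,
                    deg_genes,
                    matrix,
                    groups=tuple(config.coexpr_groups),
                    alpha=config.coexpr_alpha,
                    pseudocount=config.pseudocount,
                )
                results.append(res)
                _write(f"coexpr_{key}.tsv", res.table.iloc[: config.top_k])
            if results and annotation is not None:
                hyp = propagate_terms(results, annotation)
                _write("coexpr_hypotheses.tsv", hyp, index=False)
            report["key_genes"] = key_genes

    with _stage("enrichment"):
        universe = matrix.gene_ids
        first = _contrast_name(tuple(config.contrasts[0]))
        query = deg_tables[first].significant_genes
        if gene_sets is None and annotation is not None:
            sets = {}
            neuro = set(annotation.index[annotation["is_neurogenesis"]]) & set(universe)
            tf = set(annotation.index[annotation["is_tf"]]) & set(universe)
            if neuro:
                sets["neurogenesis"] = neuro
            if tf:
                sets["transcription_factors"] = tf
            gene_sets = GeneSetCollection(sets) if sets else None
        if gene_sets is not None and query:
            enr = overrepresentation(query, universe, gene_sets, alpha=config.alpha)
            _write("enrichment.tsv", enr)
        else:
            logger.info("enrichment skipped: no gene sets or no DEGs")

    manifest = {
        "package": "plsrank",
        "version": __version__,
        "seed": config.seed,
        "config_hash": _config_hash(config),
        "config": json.loads(json.dumps(asdict(config), default=str)),
        "outputs": sorted(report["outputs"]),
        "timings": report["timings"],
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    report["outputs"]["manifest.json"] = str(out / "manifest.json")
    report["manifest"] = manifest
    report["deg_tables"] = deg_tables
    report["rankings"] = rankings
    return report
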