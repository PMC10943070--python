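"""End-to-end orchestration: preprocess -> score -> map -> maturation ->
overlap -> network (-> enrichment), driven by a single config mapping and
emitting a machine-readable run summary with every headline count.

Three input modes:

``simulate``
    generate a synthetic experiment from a :class:`SimulationConfig`;
``tables``
    read an intensity table + sample design from files;
``prescored``
    consume an already-scored interaction table (e.g. exported from external
    scoring software) and skip the preprocessing/scoring stages.
"""

from __future__ import annotations

import json
import logging
from contextlib import contextmanager
from pathlib import Path

import yaml

from . import __version__
from .errors import ConfigurationError, DesmoproxError
from .enrichment import AnnotationTable, enrich
from .maturation import (
    PG_TERMINI,
    binarize_profiles,
    categorize_maturation,
    cluster_preys,
    heatmap_matrix,
    write_heatmap,
)
from .network import annotate_string_edges, bioid_edge_count, build_network, export_network, read_string_table
from .orthologs import OrthologTable, default_groups, expand_protein_groups, map_orthologs, parse_groups
from .overlap import bait_overlap_stats, pg_termini_overlap, read_symbol_list
from .quant_io import SampleDesign, filter_contaminants, median_center, read_protein_table, write_protein_table
from .scoring import ScoringParams, read_scores, score_experiment, write_scores
from .simulate import SimulationConfig, simulate_experiment, write_experiment

logger = logging.getLogger(__name__)

MODES = ("simulate", "tables", "prescored")


def load_config(source) -> dict:
    if isinstance(source, dict):
        return source
    with open(source) as handle:
        cfg = yaml.safe_load(handle)
    if not isinstance(cfg, dict):
        raise ConfigurationError("pipeline config must be a mapping")
    return cfg


def _validate_config(cfg: dict) -> None:
    mode = cfg.get("mode")
    if mode not in MODES:
        raise ConfigurationError(f"mode must be one of {MODES}, got {mode!r}")
    if mode == "tables":
        inputs = cfg.get("inputs", {})
        for key in ("intensities", "design"):
            if key not in inputs:
                raise ConfigurationError(f"tables mode requires inputs.{key}")
    if mode == "prescored" and "scores" not in cfg.get("inputs", {}):
        raise ConfigurationError("prescored mode requires inputs.scores")


@contextmanager
def _stage(name):
    """Failures inside a stage abort with the stage name attached."""
    try:
        yield
    except DesmoproxError as exc:
        raise DesmoproxError(f"stage {name!r} failed: {exc}") from exc


def run_pipeline(config, outdir=None) -> dict:
    """Execute all stages; returns the run summary (also written as JSON).

    Stage outputs are pure functions of (inputs, config, seed): rerunning the
    same config reproduces every artifact and the summary bit-for-bit.
    """
    cfg = load_config(config)
    _validate_config(cfg)
    mode = cfg["mode"]
    analysis = cfg.get("analysis", {})
    threshold = float(analysis.get("bfdr_threshold", 0.05))
    outdir = Path(outdir or cfg.get("output", {}).get("dir", "desmoprox_out"))
    outdir.mkdir(parents=True, exist_ok=True)
    artifacts: dict = {}
    seed = None

    if mode == "prescored":
        with _stage("load_scores"):
            scores = read_scores(cfg["inputs"]["scores"], threshold)
        logger.info("stage load_scores: %d records", len(scores))
        baits = analysis.get("baits") or list(dict.fromkeys(scores["bait"]))
        conditions = analysis.get("conditions") or list(dict.fromkeys(scores["condition"]))
    else:
        if mode == "simulate":
            sim_cfg = SimulationConfig(**cfg.get("simulate", {}))
            seed = sim_cfg.seed
            matrix, design, truth = simulate_experiment(sim_cfg)
            artifacts.update(write_experiment(outdir / "simulated", matrix, design, truth))
            logger.info("stage simulate: %d proteins x %d samples", *matrix.values.shape)
        else:
            design = SampleDesign.from_csv(cfg["inputs"]["design"])
            matrix = read_protein_table(cfg["inputs"]["intensities"], design)
            logger.info("stage read: %d proteins x %d samples", *matrix.values.shape)

        contam = cfg.get("contaminants", {})
        n_before = len(matrix.proteins)
        if contam.get("disabled") is not True:
            kwargs = {}
            if contam.get("ids") is not None:
                kwargs["contaminant_ids"] = contam["ids"]
            if contam.get("prefixes") is not None:
                kwargs["prefix_rules"] = contam["prefixes"]
            with _stage("filter_contaminants"):
                matrix = filter_contaminants(matrix, **kwargs)
        logger.info("stage filter_contaminants: %d -> %d rows", n_before, len(matrix.proteins))
        with _stage("median_center"):
            matrix = median_center(matrix)
        normalized_path = outdir / "normalized.tsv"
        write_protein_table(matrix, normalized_path)
        artifacts["normalized"] = str(normalized_path)

        params = ScoringParams(**cfg.get("scoring", {}))
        params.bfdr_threshold = threshold
        with _stage("score"):
            scores = score_experiment(matrix, design, params)
        logger.info("stage score: %d records, %d significant", len(scores), int(scores["significant"].sum()))
        baits, conditions = design.baits, design.conditions

        ortho_cfg = cfg.get("orthologs", {})
        if ortho_cfg.get("table"):
            table = OrthologTable.from_tsv(ortho_cfg["table"])
            unique_preys = list(dict.fromkeys(scores["prey"]))
            mapped, report = map_orthologs(unique_preys, table)
            rename = dict(zip(unique_preys, (table.mapping.get(p, p) for p in unique_preys)))
            scores = scores.assign(prey=scores["prey"].map(rename))
            scores = scores.sort_values("bfdr", kind="mergesort").drop_duplicates(
                ["bait", "condition", "prey"], keep="first"
            )
            logger.info("stage map_orthologs: %d unmapped", len(report.unmapped))

        scores_path = outdir / "scores.tsv"
        write_scores(scores, scores_path)
        artifacts["scores"] = str(scores_path)

    profiles = binarize_profiles(scores, threshold, baits, conditions)
    logger.info("stage binarize: %d profiled preys", len(profiles.preys))
    k = int(analysis.get("k", 11))
    clusters = cluster_preys(profiles, min(k, len(profiles.preys))) if len(profiles.preys) >= 2 else None
    calls = categorize_maturation(profiles, clusters)
    calls_path = outdir / "maturation_calls.tsv"
    calls.to_csv(calls_path, sep="\t", index=False)
    artifacts["maturation_calls"] = str(calls_path)
    if clusters is not None:
        heatmap_path = outdir / "heatmap.tsv"
        write_heatmap(heatmap_matrix(profiles, clusters), heatmap_path)
        artifacts["heatmap"] = str(heatmap_path)

    summary_stats = bait_overlap_stats(profiles, calls)
    pg_union = pg_both = None
    if all(b in baits for b in PG_TERMINI):
        pg_union, pg_both = pg_termini_overlap(profiles)

    net = build_network(profiles, calls)
    net_cfg = cfg.get("network", {})
    if net_cfg.get("string_table"):
        net = annotate_string_edges(
            net, read_string_table(net_cfg["string_table"]), float(net_cfg.get("cutoff", 0.7))
        )
    net_path = outdir / "network.tsv"
    export_network(net, net_path, "tsv")
    artifacts["network"] = str(net_path)

    enr_cfg = cfg.get("enrichment", {})
    if enr_cfg.get("annotation"):
        annotation = AnnotationTable.from_tsv(enr_cfg["annotation"])
        universe = read_symbol_list(enr_cfg["universe"]) if enr_cfg.get("universe") else None
        groups = parse_groups(open(enr_cfg["groups"])) if enr_cfg.get("groups") else default_groups()
        query, _ = expand_protein_groups(profiles.preys, groups)
        result = enrich(query, annotation, universe=universe, top_n=int(enr_cfg.get("top_n", 10)))
        enr_path = outdir / "enrichment.tsv"
        result.to_csv(enr_path, sep="\t", index=False)
        artifacts["enrichment"] = str(enr_path)

    category_counts = calls["category"].value_counts().to_dict()
    summary = {
        "version": __version__,
        "mode": mode,
        "seed": seed,
        "bfdr_threshold": threshold,
        "total_preys": summary_stats.total,
        "n_constant": int(category_counts.get("constant", 0)),
        "n_calcium_dependent": int(category_counts.get("calcium_dependent", 0)),
        "n_hyper_adhesive": int(category_counts.get("hyper_adhesive", 0)),
        "per_condition_enriched": summary_stats.per_condition,
        "per_bait": summary_stats.per_bait,
        "bait_unique": summary_stats.unique,
        "bait_shared": summary_stats.shared,
        "venn": summary_stats.venn,
        "pg_termini_union": pg_union,
        "pg_termini_both": pg_both,
        "n_bioid_edges": bioid_edge_count(net),
        "cluster_sizes": (
            {str(k): int(v) for k, v in clusters.sizes().items()}
            if clusters is not None
            else {}
        ),
        "artifacts": {k: str(v) for k, v in sorted(artifacts.items())},
        "config": _jsonable(cfg),
    }
    summary_path = outdir / "summary.json"
    with open(summary_path, "w") as handle:
        json.dump(summary, handle, indent=2, sort_keys=True, default=str)
    summary["summary_path"] = str(summary_path)
    return summary


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, Path):
        return str(obj)
    return obj
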