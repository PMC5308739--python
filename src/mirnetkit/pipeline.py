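"""End-to-end orchestration: average -> normalize -> screen -> unify ->
build network -> degree fit -> enrich -> pathway subnetwork.

Every stage writes its artifact under the configured output directory and
logs its counts, so the whole filtering funnel can be reconstructed from
the log alone. Identical configuration and seed give identical numerical
outputs; the run report isolates the timestamp in a single field.
"""

from __future__ import annotations

import logging
import time
from pathlib import Path

import pandas as pd

from . import __version__
from .config import CELL_LINES, PipelineConfig, FixtureConfig
from .enrichment import build_mirna_pathway_network, enrich
from .expression import average_replicates, concordant_differential, fold_changes, median_normalize
from .fixtures import (
    canonical_pancreatic_edge_list,
    generate_expression_fixture,
    generate_genesets,
    generate_interaction_db,
)
from .io import (
    read_expression,
    read_gmt,
    read_interactions,
    write_expression,
    write_gmt,
    write_graphml,
    write_interactions,
    write_report,
    write_sif,
    write_table,
)
from .network import build_network, degree_distribution, scale_free_fit, unify_interactions
from .subnetwork import compare_to_canonical, extract_subnetwork, summarize

logger = logging.getLogger(__name__)


class PipelineStageError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


def _stage(name: str):
    def deco(fn):
        def wrapper(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except PipelineStageError:
                raise
            except Exception as exc:  # noqa: BLE001 - re-raised with stage context
                raise PipelineStageError(name, exc) from exc
        return wrapper
    return deco


def run_all(config: PipelineConfig, pathway: str = "pancreatic cancer") -> dict:
    """Execute the full pipeline and return the structured run report.

    In fixture mode (``config.fixture`` set) synthetic inputs are generated
    and written first; otherwise ``expression_path``, ``interaction_paths``
    and ``gmt_path`` attributes must point at existing files in the dialects
    this package writes.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {
        "tool": "mirnetkit",
        "version": __version__,
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
        "parameters": {
            "tau": config.tau,
            "floor": config.floor,
            "alpha": config.alpha,
            "tail": config.tail,
            "degree_side": config.degree_side,
            "seed": config.seed,
        },
        "stages": {},
    }

    raw, sources, sets = _load_inputs(config, out, report)

    averaged = _do_average(raw)
    report["stages"]["average"] = {"probes_in": len(raw), "mirnas_out": len(averaged)}

    normalized = _do_normalize(averaged, config)
    write_expression(normalized, out / "expression_normalized.tsv", {"seed": config.seed})

    differential = _do_screen(normalized, config, out)
    n_up = int((differential["direction"] == "up").sum())
    n_down = int((differential["direction"] == "down").sum())
    report["stages"]["screen"] = {
        "differential": len(differential), "up": n_up, "down": n_down,
    }

    pairs = _do_unify(sources)
    write_table(pairs, out / "interactions_unified.tsv", {"seed": config.seed})
    report["stages"]["unify"] = {"unique_pairs": len(pairs)}

    net = _do_build(pairs, differential)
    frame = net.to_frame()
    write_table(frame, out / "network_edges.tsv", {"seed": config.seed})
    write_sif(net.graph, out / "network.sif")
    _write_net_graphml(net, out / "network.graphml")
    report["stages"]["network"] = {
        "edges": net.n_edges, "mirna_nodes": len(net.mirnas), "gene_nodes": len(net.genes),
    }

    fit_info = _do_fit(net, config)
    report["stages"]["degree_fit"] = fit_info

    results = _do_enrich(net, sets, config)
    write_table(results, out / "enrichment.tsv", {"alpha": config.alpha, "tail": config.tail})
    mp_net = build_mirna_pathway_network(results)
    n_mirna = sum(1 for _, t in mp_net.nodes(data="node_type") if t == "mirna")
    write_graphml(mp_net, out / "mirna_pathway_network.graphml")
    report["stages"]["enrichment"] = {
        "tested_pairs": len(results),
        "significant": int(results["significant"].sum()) if len(results) else 0,
        "interactions": mp_net.number_of_edges(),
        "mirnas": n_mirna,
        "pathways": mp_net.number_of_nodes() - n_mirna,
    }

    if pathway in sets.sets:
        sub = extract_subnetwork(net, sets.get(pathway), differential, pathway_name=pathway)
        write_table(sub.edges, out / "subnetwork.tsv", {"pathway": pathway})
        write_graphml(sub.to_graph(), out / "subnetwork.graphml")
        counts = summarize(sub)
        comparison = compare_to_canonical(sub, canonical_pancreatic_edge_list())
        (out / "subnetwork_comparison.txt").write_text(comparison.text_block() + "\n")
        report["stages"]["subnetwork"] = {
            "pathway": pathway, **counts,
            "precision_vs_canonical": comparison.precision,
            "recall_vs_canonical": comparison.recall,
        }
    else:
        logger.warning("pathway %r not in the collection; subnetwork stage skipped", pathway)

    write_report(report, out / "report.json")
    return report


@_stage("load-inputs")
def _load_inputs(config: PipelineConfig, out: Path, report: dict):
    if config.fixture is not None:
        fx: FixtureConfig = config.fixture
        raw, truth = generate_expression_fixture(fx)
        sources = generate_interaction_db(fx, truth)
        sets = generate_genesets(fx, truth)
        write_expression(raw, out / "expression_raw.tsv", {"seed": fx.seed, "fixture": "synthetic"})
        truth_frame = pd.DataFrame(
            {
                "mirna_id": list(truth.labels),
                "label": [truth.labels[m] for m in truth.labels],
                "ratio_line1": [truth.ratios[m][0] for m in truth.labels],
                "ratio_line2": [truth.ratios[m][1] for m in truth.labels],
            }
        )
        write_table(truth_frame, out / "truth.tsv", {"seed": fx.seed})
        write_interactions(sources, out)
        write_gmt(sets, out / "pathways.gmt")
        report["stages"]["simulate"] = {
            "probes": len(raw),
            "planted_up": fx.n_up,
            "planted_down": fx.n_down,
            "db_pairs": fx.db_n_pairs,
            "pathways": len(sets),
        }
        return raw, list(sources.values()), sets
    expr_path = getattr(config, "expression_path", None)
    inter_paths = getattr(config, "interaction_paths", None)
    gmt_path = getattr(config, "gmt_path", None)
    if not (expr_path and inter_paths and gmt_path):
        raise FileNotFoundError(
            "no fixture config and no input paths (expression_path, interaction_paths, gmt_path)"
        )
    return (
        read_expression(expr_path),
        read_interactions(inter_paths),
        read_gmt(gmt_path),
    )


@_stage("average-replicates")
def _do_average(raw):
    return average_replicates(raw)


@_stage("median-normalize")
def _do_normalize(averaged, config):
    return median_normalize(averaged, floor=config.floor)


@_stage("screen")
def _do_screen(normalized, config, out: Path):
    lines = _infer_lines(normalized)
    fc1 = fold_changes(normalized, lines[0], tau=config.tau)
    fc2 = fold_changes(normalized, lines[1], tau=config.tau)
    write_table(pd.concat([fc1, fc2], ignore_index=True), out / "fold_changes.tsv",
                {"tau": config.tau})
    differential = concordant_differential(fc1, fc2)
    write_table(differential, out / "differential.tsv", {"tau": config.tau})
    return differential


def _infer_lines(matrix) -> tuple[str, str]:
    lines: list[str] = []
    for col in matrix.columns:
        line = col.rpartition("__")[0]
        if line and line not in lines:
            lines.append(line)
    if len(lines) != 2:
        raise ValueError(f"expected exactly two cell lines in columns, found {lines}")
    return lines[0], lines[1]


@_stage("unify")
def _do_unify(sources):
    return unify_interactions(sources)


@_stage("build-network")
def _do_build(pairs, differential):
    return build_network(pairs, differential)


@_stage("degree-fit")
def _do_fit(net, config):
    if net.n_edges == 0:
        return {"skipped": "empty network"}
    dist = degree_distribution(net, side=config.degree_side)
    try:
        fit = scale_free_fit(dist)
    except Exception as exc:
        return {"skipped": str(exc)}
    return {
        "side": config.degree_side,
        "slope": fit.slope,
        "intercept": fit.intercept,
        "r_squared": fit.r_squared,
        "n_points": fit.n_points,
        "degenerate": fit.degenerate,
    }


@_stage("enrich")
def _do_enrich(net, sets, config):
    return enrich(net, sets, alpha=config.alpha, tail=config.tail)


def _write_net_graphml(net, path) -> None:
    g = net.graph.copy()
    for n in g.nodes:
        g.nodes[n]["degree"] = g.degree[n]
        g.nodes[n].setdefault("direction", "")
    write_graphml(g, path)
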