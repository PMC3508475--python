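"""Orchestrate the three analysis workflows: Analyze, Compare, Lesion.

analyze() runs the full pipeline on one raw matrix — threshold, weighting,
global metrics, community partition, nodal metrics, degree histogram, hub
ranking — and returns a pure-data, JSON-serializable report. compare() runs
two independent analyses side by side, attaching cross-modal statistics when
the node counts match. lesion_analysis() analyzes a network before and after
zeroing selected nodes' connections. All randomness flows from the single
config seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

from .bundle_io import ConnectivityMatrix
from .graph_build import AnalysisConfig, build_graph, lesion
from .metrics_global import (
    GlobalMetrics,
    ModulePartition,
    compute_global_metrics,
    modularity_partition,
)
from .metrics_nodal import (
    NodalMetrics,
    compute_nodal_metrics,
    degree_histogram,
    hub_combined_rank,
)
from .crossmodal_stats import CrossModalStats, compute_crossmodal_stats

__all__ = [
    "AnalysisReport",
    "ComparisonReport",
    "LesionReport",
    "analyze",
    "compare",
    "lesion_analysis",
    "export_report",
    "report_from_dict",
]

REGIONAL_REPORT_COLUMNS = (
    "region_name",
    "degree",
    "clustering_coefficient",
    "betweenness_centrality",
    "module_membership",
    "regional_efficiency",
    "participation_coefficient",
)


@dataclass
class AnalysisReport:
    """Complete result of one network analysis; pure data, JSON-round-trippable."""

    metadata: dict
    config: dict
    global_metrics: GlobalMetrics
    nodal_metrics: NodalMetrics
    partition: ModulePartition
    thresholded_edges: list[tuple[int, int, float]]
    degree_histogram: dict  # {"bin_edges": [...], "counts": [...]}
    hub_ranking: list[int]
    region_names: list[str]

    def to_dict(self) -> dict:
        return {
            "metadata": self.metadata,
            "config": self.config,
            "global_metrics": self.global_metrics.to_dict(),
            "nodal_metrics": self.nodal_metrics.to_dict(),
            "partition": list(self.partition.labels),
            "thresholded_edges": [[i, j, w] for i, j, w in self.thresholded_edges],
            "degree_histogram": self.degree_histogram,
            "hub_ranking": list(self.hub_ranking),
            "region_names": list(self.region_names),
        }


def report_from_dict(d: dict) -> AnalysisReport:
    """Rebuild an AnalysisReport from its JSON dict form."""
    return AnalysisReport(
        metadata=d["metadata"],
        config=d["config"],
        global_metrics=GlobalMetrics(**d["global_metrics"]),
        nodal_metrics=NodalMetrics(**d["nodal_metrics"]),
        partition=ModulePartition(tuple(d["partition"])),
        thresholded_edges=[(int(i), int(j), float(w)) for i, j, w in d["thresholded_edges"]],
        degree_histogram=d["degree_histogram"],
        hub_ranking=[int(x) for x in d["hub_ranking"]],
        region_names=list(d["region_names"]),
    )


@dataclass
class ComparisonReport:
    """Two side-by-side analyses, with cross-modal statistics when n matches."""

    report_a: AnalysisReport
    report_b: AnalysisReport
    crossmodal: CrossModalStats | None

    def to_dict(self) -> dict:
        return {
            "report_a": self.report_a.to_dict(),
            "report_b": self.report_b.to_dict(),
            "crossmodal": self.crossmodal.to_dict() if self.crossmodal else None,
        }


@dataclass
class LesionReport:
    """Unlesioned and lesioned analyses side by side."""

    unlesioned: AnalysisReport
    lesioned: AnalysisReport
    lesioned_nodes: list[int]

    def to_dict(self) -> dict:
        return {
            "unlesioned": self.unlesioned.to_dict(),
            "lesioned": self.lesioned.to_dict(),
            "lesioned_nodes": list(self.lesioned_nodes),
        }


def analyze(cm: ConnectivityMatrix, config: AnalysisConfig | None = None) -> AnalysisReport:
    """Run the full single-network analysis, deterministic given the seed."""
    if config is None:
        config = AnalysisConfig()
    g = build_graph(cm, config)
    # split the config seed into independent streams for the subsystems
    seeds = np.random.SeedSequence(config.seed).generate_state(2) % (2**31 - 1)
    partition, q = modularity_partition(g, seed=int(seeds[0]), method=config.community_method)
    global_metrics, partition = compute_global_metrics(
        cm,
        g,
        partition_q=(partition, q),
        n_null_networks=config.n_null_networks,
        swap_factor=config.swap_factor,
        seed=int(seeds[1]),
        community_method=config.community_method,
    )
    nodal = compute_nodal_metrics(g, partition)
    edges, counts = degree_histogram(g)
    return AnalysisReport(
        metadata=cm.metadata.to_dict(),
        config=config.to_dict(),
        global_metrics=global_metrics,
        nodal_metrics=nodal,
        partition=partition,
        thresholded_edges=list(g.edges),
        degree_histogram={"bin_edges": edges.tolist(), "counts": counts.tolist()},
        hub_ranking=hub_combined_rank(nodal),
        region_names=list(cm.regions.names),
    )


def compare(
    cm_a: ConnectivityMatrix,
    config_a: AnalysisConfig,
    cm_b: ConnectivityMatrix,
    config_b: AnalysisConfig,
) -> ComparisonReport:
    """Analyze two networks independently; attach cross-modal stats iff n matches.

    The cross-modal block (an extension over the side-by-side display) treats
    cm_b as the structural side for the existent-connection mask.
    """
    report_a = analyze(cm_a, config_a)
    report_b = analyze(cm_b, config_b)
    crossmodal = None
    if cm_a.n == cm_b.n:
        crossmodal = compute_crossmodal_stats(
            cm_a,
            cm_b,
            nodal_a=report_a.nodal_metrics,
            nodal_b=report_b.nodal_metrics,
            partition_a=report_a.partition,
            partition_b=report_b.partition,
        )
    return ComparisonReport(report_a, report_b, crossmodal)


def lesion_analysis(
    cm: ConnectivityMatrix, node_indices, config: AnalysisConfig | None = None
) -> LesionReport:
    """Analyze a network before and after lesioning the selected nodes.

    The lesioned raw matrix is re-thresholded at the same density percent,
    independently of the unlesioned network.
    """
    if config is None:
        config = AnalysisConfig()
    nodes = sorted(set(int(i) for i in node_indices))
    return LesionReport(
        unlesioned=analyze(cm, config),
        lesioned=analyze(lesion(cm, nodes), config),
        lesioned_nodes=nodes,
    )


def _regional_tsv(report: AnalysisReport) -> str:
    lines = ["\t".join(REGIONAL_REPORT_COLUMNS)]
    nm = report.nodal_metrics
    for i, name in enumerate(report.region_names):
        lines.append(
            "\t".join(
                [
                    name,
                    repr(nm.degree[i]),
                    repr(nm.clustering[i]),
                    repr(nm.betweenness[i]),
                    str(nm.module[i]),
                    repr(nm.regional_efficiency[i]),
                    repr(nm.participation[i]),
                ]
            )
        )
    return "\n".join(lines) + "\n"


def export_report(
    report: AnalysisReport | ComparisonReport | LesionReport, format: str
) -> str:
    """Serialize a report as JSON, or the nodal panel as the 7-column TSV."""
    if format == "json":
        return json.dumps(report.to_dict(), indent=2)
    if format == "regional_tsv":
        if not isinstance(report, AnalysisReport):
            raise ValueError("regional_tsv export applies to a single-network report")
        return _regional_tsv(report)
    raise ValueError(f"unknown report format {format!r}; use 'json' or 'regional_tsv'")
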