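"""End-to-end orchestration of the candidate-gene discovery analysis.

``run_pipeline`` chains the stages in the study's order: load -> FPKM (when
counts are supplied) -> class-specificity partition -> low-expression filter
-> two-step EB differential expression -> consistent DEGs -> alignment-hit
interval filtering -> candidate seeds -> coexpression network (Pearson, HRR,
HCCA) -> seed-neighborhood subnetwork -> GO enrichment of the consistent
DEGs and of the subnetwork members.  Every intermediate table is written to
the output directory with a config-hash header comment, along with a JSON
summary of all set sizes and a run log.

``make_fixtures`` writes a small fully synthetic bundle (default 2,000
transcripts, 6 genotypes x 3 clones, leaf tissue) with ground truth, used by
the test suite and the documentation examples.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import platform
import sys
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .coexnet import (extract_subnetwork, hcca_cluster, hrr_edges,
                      pearson_all_pairs, write_edge_list, write_graphml)
from .ebde import EBConfig, WorkflowConfig, de_called, two_step_workflow
from .enrichment import bonferroni, hypergeometric_enrich, read_annotation
from .expression import (ExpressionMatrix, classify_specific,
                         filter_low_expression, fpkm_from_counts,
                         read_lengths, read_metadata, venn_counts)
from .synteny import Interval, IntervalSet, build_candidates, filter_hits, parse_hits
from .synthetic import (SimulationParams, StudyDesign, generate_annotation_and_hits,
                        generate_counts, plant_modules)

logger = logging.getLogger("aponet")


@dataclass
class PipelineConfig:
    """Inputs, thresholds (the study's printed settings) and output location."""

    counts: str = "counts.tsv"
    lengths: str = "lengths.tsv"
    metadata: str = "metadata.tsv"
    go_map: str = "go_map.tsv"
    hits: str = "hits.tsv"
    intervals: str = "intervals.tsv"
    unit: str = "count"
    out_dir: str = "aponet_out"
    focus_class: str = "4X_apo"
    ppee: float = 0.95
    ppde: float = 0.95
    log2fc: float = 1.5
    r_cutoff: float = 0.8
    hrr_limit: int = 30
    nvn_steps: int = 3
    evalue: float = 1e-5
    theta: float = 0.5
    epsilon: float = 0.0
    s_min: int = 40
    s_max: int = 200
    bonferroni_alpha: float = 0.05
    seed: int = 1

    def __post_init__(self):
        checks = [
            0 <= self.ppee <= 1, 0 <= self.ppde <= 1, self.log2fc >= 0,
            -1 <= self.r_cutoff <= 1, self.hrr_limit >= 1, self.nvn_steps >= 1,
            self.evalue > 0, 0 <= self.theta <= 1, self.epsilon >= 0,
            1 <= self.s_min <= self.s_max, 0 < self.bonferroni_alpha <= 1,
        ]
        if not all(checks):
            raise ValueError("pipeline thresholds out of range")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @property
    def config_hash(self) -> str:
        # output location is not part of the analysis identity
        payload = {k: v for k, v in self.to_dict().items() if k != "out_dir"}
        return hashlib.sha1(
            json.dumps(payload, sort_keys=True).encode()).hexdigest()[:10]

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            payload = yaml.safe_load(fh) or {}
        return cls(**payload)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)


def _write_table(df: pd.DataFrame, path: Path, config_hash: str,
                 index: bool = False) -> None:
    with open(path, "w") as fh:
        fh.write(f"# config_hash={config_hash}\n")
        df.to_csv(fh, sep="\t", index=index)


def _write_ids(ids, path: Path, config_hash: str) -> None:
    with open(path, "w") as fh:
        fh.write(f"# config_hash={config_hash}\n")
        for t in sorted(ids):
            fh.write(f"{t}\n")


class StageError(RuntimeError):
    """Raised when a pipeline stage fails; earlier outputs stay on disk."""


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full analysis; returns (and writes) the summary."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    h = config.config_hash

    log_path = out / "run_log.txt"
    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)
    logger.info("aponet %s | python %s | %s", __version__,
                sys.version.split()[0], platform.platform())
    logger.info("config %s: %s", h, json.dumps(config.to_dict(), sort_keys=True))

    summary: dict = {"config_hash": h, "seed": config.seed}
    stage = "load"
    try:
        matrix = ExpressionMatrix.from_tsv(config.counts, unit=config.unit)
        meta = read_metadata(config.metadata)
        lengths = read_lengths(config.lengths)
        annot = read_annotation(config.go_map)
        hits = parse_hits(config.hits)
        intervals = IntervalSet.from_tsv(config.intervals)
        summary["n_transcripts"] = len(matrix.transcript_ids)
        summary["n_samples"] = len(matrix.sample_ids)

        stage = "fpkm"
        if matrix.unit == "count":
            fpkm = fpkm_from_counts(matrix, lengths)
            counts_for_de = matrix
        else:
            fpkm = matrix
            # count model needs integers: round FPKM to pseudo-counts
            counts_for_de = ExpressionMatrix(matrix.data.round(), unit="count")
        _write_table(fpkm.data.round(4), out / "fpkm.tsv", h, index=True)

        stage = "specificity"
        partition = classify_specific(fpkm, meta, epsilon=config.epsilon)
        _write_table(partition.to_frame(), out / "venn_partition.tsv", h)
        _write_table(venn_counts(partition), out / "venn_counts.tsv", h)
        summary["specific"] = {k: len(v) for k, v in partition.specific_sets.items()}
        summary["expressed"] = len(partition.expressed)

        stage = "low_expression_filter"
        filtered = filter_low_expression(fpkm, theta=config.theta)
        summary["n_after_low_expression_filter"] = len(filtered.transcript_ids)

        stage = "two_step_de"
        wf_config = WorkflowConfig(
            ppee_threshold=config.ppee, epsilon=config.epsilon,
            focus_class=config.focus_class,
            eb=EBConfig(ppde_threshold=config.ppde,
                        log2fc_threshold=config.log2fc))
        workflow = two_step_workflow(counts_for_de, meta, wf_config)
        for (a, b), table in workflow.comparisons.items():
            _write_table(table.rename_axis("transcript_id").round(6),
                         out / f"de_{a}_vs_{b}.tsv", h, index=True)
        summary["workflow"] = workflow.summary()

        stage = "consistent_degs"
        _write_ids(workflow.consistent_degs, out / "consistent_degs.txt", h)
        summary["consistent_degs"] = len(workflow.consistent_degs)

        stage = "hit_filtering"
        acr_set, per_interval = filter_hits(hits, intervals,
                                            evalue_cutoff=config.evalue)
        _write_ids(acr_set, out / "acr_transcripts.txt", h)
        summary["acr_transcripts"] = len(acr_set)
        summary["hits_per_interval"] = per_interval

        stage = "candidates"
        candidates = build_candidates(acr_set, partition, workflow)
        _write_table(candidates.to_frame(), out / "candidates.tsv", h)
        summary["seed_transcripts"] = len(candidates.seed_transcripts)

        stage = "network"
        edges = pearson_all_pairs(filtered, r_cutoff=config.r_cutoff)
        graph = hrr_edges(edges, hrr_limit=config.hrr_limit,
                          nodes=filtered.transcript_ids)
        write_edge_list(graph, out / "network_edges.tsv")
        write_graphml(graph, out / "network.graphml")
        summary["network"] = {"nodes": graph.number_of_nodes(),
                              "edges": graph.number_of_edges()}

        stage = "clustering"
        clusters = hcca_cluster(graph, nvn_steps=config.nvn_steps,
                                s_min=config.s_min, s_max=config.s_max)
        _write_table(clusters.membership_frame(), out / "clusters.tsv", h)
        summary["clusters"] = {"n_clusters": len(clusters.clusters),
                               "unassigned": len(clusters.unassigned)}

        stage = "subnetwork"
        sub = extract_subnetwork(graph, candidates.seed_transcripts
                                 & set(graph.nodes))
        _write_ids(sub.members, out / "subnetwork_members.txt", h)
        _write_table(sub.edge_frame(), out / "subnetwork_edges.tsv", h)
        write_graphml(sub.graph, out / "subnetwork.graphml")
        summary["subnetwork"] = {"seeds": len(sub.seeds),
                                 "members": len(sub.members),
                                 "edges": sub.graph.number_of_edges()}

        stage = "enrichment"
        universe = set(matrix.transcript_ids)
        deg_bg = workflow.common_expressed or universe
        enr_degs = bonferroni(
            hypergeometric_enrich(workflow.consistent_degs & deg_bg, deg_bg,
                                  annot, lengths=lengths),
            alpha=config.bonferroni_alpha)
        _write_table(enr_degs, out / "enrichment_consistent_degs.tsv", h)
        enr_sub = bonferroni(
            hypergeometric_enrich(sub.members & universe, universe, annot,
                                  lengths=lengths),
            alpha=config.bonferroni_alpha)
        _write_table(enr_sub, out / "enrichment_subnetwork.tsv", h)
        summary["enriched_terms"] = {
            "consistent_degs": int(enr_degs["enriched"].sum()) if len(enr_degs) else 0,
            "subnetwork": int(enr_sub["enriched"].sum()) if len(enr_sub) else 0,
        }
    except Exception as exc:
        logger.error("stage %s failed: %s", stage, exc)
        logger.removeHandler(handler)
        handler.close()
        raise StageError(f"pipeline stage {stage!r} failed: {exc}") from exc

    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=1, default=str)
    logger.info("pipeline complete: %s", json.dumps(
        {k: v for k, v in summary.items() if not isinstance(v, dict)}))
    logger.removeHandler(handler)
    handler.close()
    return summary


def default_intervals() -> IntervalSet:
    """Synthetic marker-delimited intervals used by the fixture bundle.

    The study delimits the ACR-syntenic segments by markers C560-C932 on rice
    chromosome 2 and C1069-C996 on chromosome 12 without printing base-pair
    coordinates; the fixture fabricates plausible spans for them.
    """
    return IntervalSet([
        Interval("chr2", 1_000_000, 1_400_000, "C560-C932"),
        Interval("chr12", 2_000_000, 2_300_000, "C1069-C996"),
    ])


def make_fixtures(
    out_dir,
    seed: int = 1,
    n_transcripts: int = 2000,
    design: StudyDesign | None = None,
    params: SimulationParams | None = None,
) -> PipelineConfig:
    """Write the synthetic bundle and a ready-to-run pipeline config.

    Emits counts, lengths, metadata, GO map, alignment hits, marker
    intervals, the ground-truth JSON and ``config.yaml``.  Cluster-size
    bounds in the emitted config are scaled to the bundle (10-100) rather
    than the large-network defaults.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    design = design or StudyDesign()
    params = params or SimulationParams(n_transcripts=n_transcripts, seed=seed)

    matrix, truth = generate_counts(design, params)
    matrix, truth = plant_modules(matrix, params, truth)
    intervals = default_intervals()
    go_map, hits = generate_annotation_and_hits(
        truth, n_go_terms=150, intervals=intervals, seed=params.seed + 2)

    rng = np.random.default_rng(params.seed + 3)
    lengths = pd.Series(rng.integers(300, 5000, size=len(matrix.transcript_ids)),
                        index=matrix.transcript_ids)

    matrix.to_tsv(out / "counts.tsv")
    lengths.rename("length").rename_axis("transcript_id").reset_index().to_csv(
        out / "lengths.tsv", sep="\t", index=False)
    design.metadata().to_csv(out / "metadata.tsv", sep="\t", index=False)
    go_map.to_csv(out / "go_map.tsv", sep="\t", index=False)
    hits.drop(columns=["minus_strand"], errors="ignore").to_csv(
        out / "hits.tsv", sep="\t", index=False, header=False)
    intervals.to_tsv(out / "intervals.tsv")
    truth.to_json(out / "truth.json")

    config = PipelineConfig(
        counts=str(out / "counts.tsv"), lengths=str(out / "lengths.tsv"),
        metadata=str(out / "metadata.tsv"), go_map=str(out / "go_map.tsv"),
        hits=str(out / "hits.tsv"), intervals=str(out / "intervals.tsv"),
        out_dir=str(out / "results"), seed=params.seed,
        s_min=10, s_max=100)
    config.to_yaml(out / "config.yaml")
    return config
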