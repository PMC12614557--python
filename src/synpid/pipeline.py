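"""End-to-end runs: node view -> information dissimilarity -> PAM ->
contingency / differential-expression / enrichment statistics.

A run is fully determined by (inputs, config, seed): every random stage
draws from a named substream of the single top-level seed, and all
artifacts are written with a config echo so a run can be regenerated
bit-identically.
"""

from __future__ import annotations

import dataclasses
import json
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .cluster import PAMedoids, to_dissimilarity
from .io import ExpressionCommunity, contingency, write_matrix, write_tensor
from .pid import average_over_targets, pairwise_mi_matrix, synergy_tensor
from .stats import (bootstrap_communities, dge_test, empirical_pvalues,
                    kruskal_wallis, ora_hypergeometric)

__all__ = ["RunConfig", "RunReport", "run_pipeline", "rng_for"]

#: above this node count the O(n^3) triplet sweep gets slow; warn.
TRIPLET_WARN_NODES = 300


def rng_for(seed: int, stage: str) -> np.random.Generator:
    """Named substream: independent generator per pipeline stage."""
    return np.random.default_rng(np.random.SeedSequence([seed, zlib.crc32(stage.encode())]))


@dataclass
class RunConfig:
    """All knobs of one pipeline run; defaults are the study settings
    (k searched over 2..10, |logFC| > 1.5 at 1% adjusted significance,
    1000 matched null subsets, 10 bootstrap resamples, ORA at 5%)."""

    orientation: str = "samples"
    metric: str = "synergy"
    diss_mode: str | None = None
    kmin: int = 2
    kmax: int = 10
    lfc_threshold: float = 1.5
    dge_alpha: float = 0.01
    kw_alpha: float = 0.01
    ora_correction: str = "fdr"
    ora_alpha: float = 0.05
    B: int = 1000
    n_boot: int = 10
    seed: int = 0
    bias_correct: bool = True

    def __post_init__(self):
        if self.orientation not in {"samples", "genes"}:
            raise ValueError("orientation must be 'samples' or 'genes'")
        if self.metric not in {"synergy", "mi"}:
            raise ValueError("metric must be 'synergy' or 'mi'")
        if self.kmin < 2:
            raise ValueError("kmin must be >= 2")
        if self.lfc_threshold <= 0 or not (0 < self.dge_alpha < 1):
            raise ValueError("thresholds must be positive")


@dataclass
class RunReport:
    config: RunConfig
    node_ids: list
    metric_matrix: np.ndarray
    dissimilarity: np.ndarray
    k: int
    labels: np.ndarray
    medoids: np.ndarray
    silhouette: float
    selection_trace: list
    contingency: pd.DataFrame | None = None
    cluster_dge: dict = field(default_factory=dict)
    cluster_empirical_p: dict = field(default_factory=dict)
    cluster_kw_significant: dict = field(default_factory=dict)
    cluster_genes: dict = field(default_factory=dict)
    cluster_ora: dict = field(default_factory=dict)
    bootstrap_sets: list = field(default_factory=list)
    tensor: object = None

    def cluster_members(self) -> dict:
        out = {}
        for c in sorted(set(self.labels.tolist())):
            out[int(c)] = [self.node_ids[i] for i in np.flatnonzero(self.labels == c)]
        return out

    def summary(self) -> dict:
        s = {
            "config": dataclasses.asdict(self.config),
            "n_nodes": len(self.node_ids),
            "k": int(self.k),
            "silhouette": float(self.silhouette),
            "cluster_sizes": {int(c): int((self.labels == c).sum())
                              for c in sorted(set(self.labels.tolist()))},
            "selection_trace": [
                {"k": int(k), "cost": float(c), "silhouette": float(s_)}
                for k, c, s_ in self.selection_trace],
        }
        if self.contingency is not None:
            s["contingency"] = {str(cls): {str(cl): int(v) for cl, v in row.items()}
                                for cls, row in self.contingency.iterrows()}
        if self.cluster_dge:
            s["dge_counts"] = {str(c): int(t.is_differential.sum())
                               for c, t in self.cluster_dge.items()}
        if self.cluster_kw_significant:
            s["kw_significant_counts"] = {str(c): int(v)
                                          for c, v in self.cluster_kw_significant.items()}
        if self.cluster_empirical_p:
            s["empirical_p_min"] = {str(c): float(t.empirical_p.min())
                                    for c, t in self.cluster_empirical_p.items()}
        if self.cluster_ora:
            s["ora_significant_counts"] = {str(c): int(t.significant.sum())
                                           for c, t in self.cluster_ora.items()}
        return s


def _dge_feasible(expr: ExpressionCommunity, subjects) -> bool:
    labels = expr.class_labels.loc[subjects]
    return (labels == expr.case_label).sum() >= 2 and (labels != expr.case_label).sum() >= 2


def run_pipeline(expr: ExpressionCommunity, config: RunConfig,
                 gene_sets: dict | None = None, out_dir=None,
                 progress=None) -> RunReport:
    """Run one orientation/metric configuration end to end.

    With ``out_dir`` every artifact (tensor, matrices, assignments,
    selection trace, statistics tables, report JSON) is written as TSV/JSON.
    """
    nodes = expr.to_node_matrix(config.orientation)
    if progress:
        n = nodes.n_nodes
        progress(f"stage=nodes orientation={config.orientation} n_nodes={n} "
                 f"n_triplets={n * (n - 1) // 2 * (n - 2)}")
        if n > TRIPLET_WARN_NODES and config.metric == "synergy":
            progress(f"warning: {n} nodes implies an O(n^3) triplet sweep")

    tensor = None
    try:
        if config.metric == "synergy":
            tensor = synergy_tensor(nodes, bias_correct=config.bias_correct)
            metric_matrix = average_over_targets(tensor)
        else:
            metric_matrix = pairwise_mi_matrix(nodes, bias_correct=config.bias_correct)
        mode = config.diss_mode or "max_minus"
        d = to_dissimilarity(metric_matrix, mode=mode)
    except Exception as exc:
        raise RuntimeError(f"stage=dissimilarity failed: {exc}") from exc

    try:
        pam_est = PAMedoids(n_clusters=None, k_min=config.kmin, k_max=config.kmax)
        pam_est.fit(d)
    except Exception as exc:
        raise RuntimeError(f"stage=clustering failed: {exc}") from exc
    if progress:
        progress(f"stage=clustering k={pam_est.n_clusters_} "
                 f"silhouette={pam_est.silhouette_:.4f}")

    report = RunReport(
        config=config, node_ids=list(nodes.node_ids),
        metric_matrix=metric_matrix, dissimilarity=d,
        k=pam_est.n_clusters_, labels=pam_est.labels_,
        medoids=pam_est.medoid_indices_, silhouette=pam_est.silhouette_,
        selection_trace=pam_est.selection_trace_)
    report.tensor = tensor

    members = report.cluster_members()
    if config.orientation == "samples":
        try:
            report.contingency = contingency(
                expr.class_labels,
                pd.Series(pam_est.labels_, index=expr.sample_ids))
            for c, subjects in members.items():
                if not _dge_feasible(expr, subjects):
                    continue
                tab = dge_test(expr, subjects, config.lfc_threshold, config.dge_alpha)
                kw_sig = 0
                for g in expr.gene_ids:
                    row = expr.matrix.loc[g, subjects]
                    lab = expr.class_labels.loc[subjects]
                    _, p = kruskal_wallis([row[lab == expr.case_label],
                                           row[lab != expr.case_label]])
                    kw_sig += p < config.kw_alpha
                report.cluster_dge[c] = tab
                report.cluster_kw_significant[c] = kw_sig
                if len(subjects) < len(expr.sample_ids):
                    report.cluster_empirical_p[c] = empirical_pvalues(
                        expr, subjects, B=config.B,
                        rng=rng_for(config.seed, f"empirical_p/cluster{c}"))
        except Exception as exc:
            raise RuntimeError(f"stage=downstream_samples failed: {exc}") from exc
    else:
        try:
            report.cluster_genes = members
            universe = set(expr.gene_ids)
            if gene_sets:
                for c, genes in members.items():
                    report.cluster_ora[c] = ora_hypergeometric(
                        genes, gene_sets, universe,
                        correction=config.ora_correction, alpha=config.ora_alpha)
            report.bootstrap_sets = bootstrap_communities(
                expr.gene_ids, n_boot=config.n_boot,
                rng=rng_for(config.seed, "bootstrap"))
        except Exception as exc:
            raise RuntimeError(f"stage=downstream_genes failed: {exc}") from exc

    if out_dir is not None:
        _write_report(report, expr, Path(out_dir))
    return report


def _write_report(report: RunReport, expr: ExpressionCommunity, out: Path):
    out.mkdir(parents=True, exist_ok=True)
    tag = f"{report.config.orientation}_{report.config.metric}"
    write_matrix(report.metric_matrix, report.node_ids, out / f"{tag}_metric.tsv")
    write_matrix(report.dissimilarity, report.node_ids, out / f"{tag}_dissimilarity.tsv")
    if report.tensor is not None:
        write_tensor(report.tensor, out / f"{tag}_synergy_tensor.tsv")
    pd.DataFrame({"node_id": report.node_ids, "cluster": report.labels}).to_csv(
        out / f"{tag}_clusters.tsv", sep="\t", index=False)
    pd.DataFrame(report.selection_trace, columns=["k", "cost", "silhouette"]).to_csv(
        out / f"{tag}_selection_trace.tsv", sep="\t", index=False)
    if report.contingency is not None:
        report.contingency.to_csv(out / f"{tag}_contingency.tsv", sep="\t")
    for c, tab in report.cluster_dge.items():
        tab.to_csv(out / f"{tag}_dge_cluster{c}.tsv", sep="\t")
    for c, tab in report.cluster_empirical_p.items():
        tab.to_csv(out / f"{tag}_empirical_p_cluster{c}.tsv", sep="\t")
    for c, tab in report.cluster_ora.items():
        tab.to_csv(out / f"{tag}_ora_cluster{c}.tsv", sep="\t")
    with open(out / f"{tag}_report.json", "w") as fh:
        json.dump(report.summary(), fh, indent=2, sort_keys=True)
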