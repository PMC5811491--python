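"""End-to-end comorbidity analysis pipeline.

Composes the stages in study order: load and compare the two disease gene
lists; run over-representation against each annotation collection for each
disease and compare the significant terms; clean the interaction network,
extract the two disease subnetworks, intersect them; and predict new
candidates by the degree-to-common-genes rule. Every stage writes a
deterministic table; a JSON report summarises all counts and is audited by
re-reading the emitted tables.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .catalog import (
    GeneSet,
    compare_sets,
    load_gene_list,
    write_overlap_report,
)
from .enrichment import (
    compare_enrichments,
    read_gmt,
    read_results,
    run_enrichment,
    write_comparison,
    write_gmt,
    write_results,
)
from .errors import PipelineStageError
from .network import (
    clean_network,
    extract_disease_subnetwork,
    intersect_subnetworks,
    predict_candidates,
    read_edge_list,
    write_edge_list,
)

logger = logging.getLogger(__name__)

__all__ = ["CollectionConfig", "PipelineConfig", "PipelineReport", "run_full_pipeline"]


@dataclass
class CollectionConfig:
    """One annotation collection to test, with its significance gate."""

    path: str
    category: str = "pathway"
    alpha: float = 0.01

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError(f"alpha must be in (0,1), got {self.alpha}")


@dataclass
class PipelineConfig:
    genes_a: str
    genes_b: str
    collections: list[CollectionConfig] = field(default_factory=list)
    ppi: str | None = None
    min_overlap: int = 2
    method: str = "hypergeometric"
    min_degree: int = 5
    edge_mode: str = "seed-incident"
    outdir: str = "results/pipeline"
    seed: int | None = None

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        payload = yaml.safe_load(Path(path).read_text()) or {}
        collections = [CollectionConfig(**c) for c in payload.pop("collections", [])]
        return cls(collections=collections, **payload)

    def to_dict(self) -> dict:
        return {
            "genes_a": self.genes_a,
            "genes_b": self.genes_b,
            "collections": [vars(c) for c in self.collections],
            "ppi": self.ppi,
            "min_overlap": self.min_overlap,
            "method": self.method,
            "min_degree": self.min_degree,
            "edge_mode": self.edge_mode,
            "outdir": self.outdir,
            "seed": self.seed,
        }


@dataclass
class PipelineReport:
    counts: dict
    manifest: dict[str, str]
    notices: list[str]
    config: dict
    version: str = __version__

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "version": self.version,
                    "counts": self.counts,
                    "manifest": self.manifest,
                    "notices": self.notices,
                    "config": self.config,
                },
                indent=2,
                sort_keys=True,
            )
            + "\n"
        )


def _stage(name: str):
    def deco(fn):
        def wrapped(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except PipelineStageError:
                raise
            except Exception as exc:  # noqa: BLE001 - re-raise with stage label
                raise PipelineStageError(f"[{name}] {exc}") from exc

        return wrapped

    return deco


@_stage("load")
def _load_sets(config: PipelineConfig) -> tuple[GeneSet, GeneSet]:
    a = load_gene_list(config.genes_a, name=Path(config.genes_a).stem)
    b = load_gene_list(config.genes_b, name=Path(config.genes_b).stem)
    return a, b


def run_full_pipeline(config: PipelineConfig) -> PipelineReport:
    """Execute all stages and write tables plus a JSON report under
    ``config.outdir``. Missing PPI input skips the network stages with an
    explicit notice; enrichment stages still complete."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, str] = {}
    notices: list[str] = []
    counts: dict = {}

    set_a, set_b = _load_sets(config)
    counts["n_genes_a"] = len(set_a)
    counts["n_genes_b"] = len(set_b)

    overlap = compare_sets(set_a, set_b)
    counts["n_shared_genes"] = overlap.n_shared
    counts["n_a_only_genes"] = len(overlap.a_only)
    counts["n_b_only_genes"] = len(overlap.b_only)
    path = outdir / "gene_overlap.tsv"
    write_overlap_report(overlap, path)
    manifest["gene_overlap"] = path.name

    counts["collections"] = {}
    for coll_cfg in config.collections:
        key = coll_cfg.category
        try:
            collection = read_gmt(coll_cfg.path, category=key)
            res_a = run_enrichment(
                set_a, collection, alpha=coll_cfg.alpha,
                min_overlap=config.min_overlap, method=config.method,
            )
            res_b = run_enrichment(
                set_b, collection, alpha=coll_cfg.alpha,
                min_overlap=config.min_overlap, method=config.method,
            )
        except Exception as exc:  # noqa: BLE001
            raise PipelineStageError(f"[enrich:{key}] {exc}") from exc
        logger.info(
            "enrich:%s: universe N=%d, BH family m=%d (A) / %d (B), alpha=%g",
            key, len(collection.universe), len(res_a), len(res_b), coll_cfg.alpha,
        )
        pa = outdir / f"enrichment_{key}_a.tsv"
        pb = outdir / f"enrichment_{key}_b.tsv"
        write_results(res_a, pa)
        write_results(res_b, pb)
        echo = outdir / f"tested_{key}.gmt"
        write_gmt(collection, echo)
        comparison = compare_enrichments(res_a, res_b)
        pc = outdir / f"comparison_{key}.tsv"
        pj = outdir / f"comparison_{key}.json"
        write_comparison(comparison, pc, pj)
        manifest[f"enrichment_{key}_a"] = pa.name
        manifest[f"enrichment_{key}_b"] = pb.name
        manifest[f"comparison_{key}"] = pc.name
        manifest[f"tested_{key}"] = echo.name
        counts["collections"][key] = {
            "n_terms": len(collection),
            "universe_size": len(collection.universe),
            "alpha": coll_cfg.alpha,
            "n_significant_a": sum(r.significant for r in res_a),
            "n_significant_b": sum(r.significant for r in res_b),
            "n_shared_terms": comparison.n_shared,
            "n_a_specific_terms": comparison.n_a_specific,
            "n_b_specific_terms": comparison.n_b_specific,
        }

    if config.ppi is None or not Path(config.ppi).exists():
        notices.append(
            "network stages skipped: no PPI edge list "
            f"({config.ppi!r})"
        )
    else:
        try:
            raw = read_edge_list(config.ppi)
            net = clean_network(raw)
            sub_a = extract_disease_subnetwork(net, set_a, edge_mode=config.edge_mode)
            sub_b = extract_disease_subnetwork(net, set_b, edge_mode=config.edge_mode)
            shared = intersect_subnetworks(sub_a, sub_b, set_a, set_b)
            common_genes = sorted(overlap.shared & net.nodes)
            ranking = predict_candidates(
                shared, common_genes, set_a, set_b, min_degree=config.min_degree
            )
        except Exception as exc:  # noqa: BLE001
            raise PipelineStageError(f"[network] {exc}") from exc
        logger.info(
            "network: %d nodes / %d edges after cleaning; edge_mode=%s; "
            "%d/%d common genes mapped",
            net.n_nodes, net.n_edges, config.edge_mode,
            len(common_genes), overlap.n_shared,
        )
        counts["network"] = {
            "n_raw_records": len(raw),
            "n_nodes": net.n_nodes,
            "n_edges": net.n_edges,
            "subnetwork_a": {
                "n_seeds": len(sub_a.seeds),
                "n_neighbors": len(sub_a.neighbors),
                "n_nodes": sub_a.n_nodes,
                "n_edges": sub_a.n_edges,
                "n_unmapped_seeds": len(sub_a.unmapped_seeds),
            },
            "subnetwork_b": {
                "n_seeds": len(sub_b.seeds),
                "n_neighbors": len(sub_b.neighbors),
                "n_nodes": sub_b.n_nodes,
                "n_edges": sub_b.n_edges,
                "n_unmapped_seeds": len(sub_b.unmapped_seeds),
            },
            "shared_subnetwork": {
                "n_nodes": shared.n_nodes,
                "n_edges": shared.n_edges,
                "role_counts": dict(sorted(shared.role_counts.items())),
            },
            "n_common_genes_in_network": len(common_genes),
            "min_degree": config.min_degree,
            "n_candidates": len(ranking),
        }
        pa = outdir / "subnetwork_a_edges.tsv"
        pb = outdir / "subnetwork_b_edges.tsv"
        ps = outdir / "shared_subnetwork_edges.tsv"
        write_edge_list(sub_a.edges, pa)
        write_edge_list(sub_b.edges, pb)
        write_edge_list(shared.shared_edges, ps)
        pcand = outdir / "candidates.tsv"
        pd.DataFrame(
            [
                {
                    "gene": c.gene,
                    "degree_to_common": c.degree_to_common,
                    "common_partners": ",".join(c.partners),
                }
                for c in ranking.candidates
            ],
            columns=["gene", "degree_to_common", "common_partners"],
        ).to_csv(pcand, sep="\t", index=False)
        manifest["subnetwork_a_edges"] = pa.name
        manifest["subnetwork_b_edges"] = pb.name
        manifest["shared_subnetwork_edges"] = ps.name
        manifest["candidates"] = pcand.name

    report = PipelineReport(
        counts=counts, manifest=manifest, notices=notices, config=config.to_dict()
    )
    _audit(report, outdir)
    report_path = outdir / "report.json"
    report.to_json(report_path)
    return report


def _audit(report: PipelineReport, outdir: Path) -> None:
    """Re-read emitted tables and assert the report counts match them."""
    overlap = pd.read_csv(outdir / report.manifest["gene_overlap"], sep="\t")
    by_cat = overlap["category"].value_counts().to_dict()
    checks = {
        "n_shared_genes": by_cat.get("shared", 0),
        "n_a_only_genes": by_cat.get("a_only", 0),
        "n_b_only_genes": by_cat.get("b_only", 0),
    }
    for key, observed in checks.items():
        if report.counts[key] != observed:
            raise PipelineStageError(
                f"[audit] {key}: report says {report.counts[key]}, table says {observed}"
            )
    for key, summary in report.counts.get("collections", {}).items():
        for side, count_key in (("a", "n_significant_a"), ("b", "n_significant_b")):
            table = read_results(outdir / report.manifest[f"enrichment_{key}_{side}"])
            n_sig = sum(r.significant for r in table)
            if n_sig != summary[count_key]:
                raise PipelineStageError(
                    f"[audit] {key}/{count_key}: report {summary[count_key]} != table {n_sig}"
                )
    if "network" in report.counts:
        cand = pd.read_csv(outdir / report.manifest["candidates"], sep="\t")
        if len(cand) != report.counts["network"]["n_candidates"]:
            raise PipelineStageError(
                f"[audit] candidate count: report "
                f"{report.counts['network']['n_candidates']} != table {len(cand)}"
            )
        edge_text = (outdir / report.manifest["shared_subnetwork_edges"]).read_text()
        n_edge_rows = sum(1 for line in edge_text.splitlines() if line.strip())
        if n_edge_rows != report.counts["network"]["shared_subnetwork"]["n_edges"]:
            raise PipelineStageError("[audit] shared edge count mismatch")
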